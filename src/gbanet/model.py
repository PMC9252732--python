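"""Classifier training, cross-validation and genome-wide scoring.

The classifier is an l2-regularized logistic regression with inverse
regularization strength ``C = 1`` (the standard convention: the penalized
objective is ``C * sum_i log(1 + exp(-y_i (w.x_i + b))) + ||w||^2 / 2``).
Only positive (P) and negative (N) genes enter the fit; unused (U) genes are
excluded from training but are scored like every other network gene, which is
precisely how novel candidates surface.

When the positive set has at least 15 genes the model is additionally
evaluated by stratified 3-fold cross-validation, reporting auPRC, auROC and
precision among the top-K predictions with K equal to the held-out fold's
positive count.  These metrics indicate whether the chosen network /
representation / negative-collection combination suits the gene set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import EmptyInputError, FingerprintMismatchError, ParameterError
from .features import FeatureMatrix
from .labels import LabeledSets

logger = logging.getLogger(__name__)

DEFAULT_INVERSE_REG = 1.0
CV_MIN_POSITIVES = 15
CV_FOLDS = 3
DISPLAY_LIMIT = 500
SOLVER_TOL = 1e-6

PREDICTION_COLUMNS = [
    "Entrez", "Symbol", "Name", "Probability", "Training-Label", "Known/Novel", "Rank"
]


@dataclass
class TrainedModel:
    """A fitted logistic-regression model plus its provenance."""

    weights: np.ndarray
    intercept: float
    feature_fingerprint: str
    label_counts: tuple[int, int]  # (n_pos, n_neg)
    settings: dict = field(default_factory=dict)

    def decision(self, values: np.ndarray) -> np.ndarray:
        return values @ self.weights + self.intercept

    def probabilities(self, values: np.ndarray) -> np.ndarray:
        z = self.decision(values)
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_fingerprint": self.feature_fingerprint,
            "label_counts": list(self.label_counts),
            "settings": self.settings,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            feature_fingerprint=d["feature_fingerprint"],
            label_counts=tuple(d["label_counts"]),
            settings=d.get("settings", {}),
        )


@dataclass(frozen=True)
class CVMetrics:
    """Per-fold and mean cross-validation metrics (all in [0, 1])."""

    n_folds: int
    auprc: tuple[float, ...]
    auroc: tuple[float, ...]
    p_at_topk: tuple[float, ...]

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.auprc))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc))

    @property
    def mean_p_at_topk(self) -> float:
        return float(np.mean(self.p_at_topk))

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "per_fold": {
                "auPRC": list(self.auprc),
                "auROC": list(self.auroc),
                "P@topK": list(self.p_at_topk),
            },
            "mean": {
                "auPRC": self.mean_auprc,
                "auROC": self.mean_auroc,
                "P@topK": self.mean_p_at_topk,
            },
        }


def _training_arrays(features: FeatureMatrix, labels: LabeledSets):
    idx, y = [], []
    for i, gene in enumerate(features.genes):
        if gene in labels.positives:
            idx.append(i)
            y.append(1)
        elif gene in labels.negatives:
            idx.append(i)
            y.append(0)
    return features.values[idx], np.asarray(y, dtype=int)


def train(
    features: FeatureMatrix,
    labels: LabeledSets,
    inverse_reg: float = DEFAULT_INVERSE_REG,
    settings: Mapping | None = None,
) -> TrainedModel:
    """Fit the l2 logistic regression on P vs N rows."""
    if inverse_reg <= 0:
        raise ParameterError(f"inverse_reg must be positive, got {inverse_reg}")
    X, y = _training_arrays(features, labels)
    if len(np.unique(y)) < 2:
        raise EmptyInputError(
            f"degenerate training set: {y.sum()} positives, {len(y) - y.sum()} negatives"
        )
    clf = LogisticRegression(
        C=inverse_reg, solver="lbfgs", tol=SOLVER_TOL, max_iter=10_000
    )
    clf.fit(X, y)
    return TrainedModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_fingerprint=features.params_fingerprint,
        label_counts=(int(y.sum()), int(len(y) - y.sum())),
        settings=dict(settings or {}),
    )


def precision_at_k(y_true: np.ndarray, scores: np.ndarray, k: int) -> float:
    """Fraction of positives among the k highest-scored items (stable order
    breaks score ties by input position)."""
    order = np.argsort(-scores, kind="stable")[:k]
    return float(np.mean(y_true[order]))


def cross_validate(
    features: FeatureMatrix,
    labels: LabeledSets,
    seed: int = 42,
    inverse_reg: float = DEFAULT_INVERSE_REG,
    min_positives: int = CV_MIN_POSITIVES,
    n_folds: int = CV_FOLDS,
) -> CVMetrics | None:
    """Stratified k-fold CV; returns None when positives are too few.

    Evaluation only runs when the positive set has at least ``min_positives``
    genes (default 15): below that, fold-level metrics are too unstable to
    guide parameter choice.
    """
    X, y = _training_arrays(features, labels)
    n_pos = int(y.sum())
    if n_pos < min_positives:
        logger.info(
            "skipping cross-validation: %d positives < %d required", n_pos, min_positives
        )
        return None
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    auprc, auroc, patk = [], [], []
    for train_idx, test_idx in skf.split(X, y):
        clf = LogisticRegression(
            C=inverse_reg, solver="lbfgs", tol=SOLVER_TOL, max_iter=10_000
        )
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.decision_function(X[test_idx])
        y_test = y[test_idx]
        auprc.append(float(average_precision_score(y_test, scores)))
        auroc.append(float(roc_auc_score(y_test, scores)))
        patk.append(precision_at_k(y_test, scores, k=int(y_test.sum())))
    return CVMetrics(
        n_folds=n_folds, auprc=tuple(auprc), auroc=tuple(auroc), p_at_topk=tuple(patk)
    )


def _entrez_sort_key(gene: str):
    return (0, int(gene)) if gene.isdigit() else (1, 0)


def predict_all(
    model: TrainedModel,
    features: FeatureMatrix,
    labels: LabeledSets,
    gene_annotations: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Score every network gene and build the ranked prediction table.

    One row per gene (P, N and U alike) with the model's predicted
    probability, the training label, Known/Novel status (Known = training
    positive) and the rank.  Ties in probability break by ascending numeric
    Entrez so tables are identical across runs.
    """
    if model.feature_fingerprint != features.params_fingerprint:
        raise FingerprintMismatchError(
            "model was trained on different features:\n"
            f"  model:    {model.feature_fingerprint}\n"
            f"  features: {features.params_fingerprint}"
        )
    probs = model.probabilities(features.values)
    annotations = gene_annotations or {}
    rows = []
    for gene, prob in zip(features.genes, probs):
        symbol, fullname = annotations.get(gene, (gene, ""))
        lab = labels.label_of(gene)
        rows.append(
            (gene, symbol, fullname, float(prob), lab, "Known" if lab == "P" else "Novel")
        )
    table = pd.DataFrame(
        rows, columns=["Entrez", "Symbol", "Name", "Probability", "Training-Label", "Known/Novel"]
    )
    order = sorted(
        range(len(table)),
        key=lambda i: (-table["Probability"].iat[i], _entrez_sort_key(table["Entrez"].iat[i])),
    )
    table = table.iloc[order].reset_index(drop=True)
    table["Rank"] = np.arange(1, len(table) + 1)
    return table


def truncate_for_display(table: pd.DataFrame, limit: int = DISPLAY_LIMIT) -> pd.DataFrame:
    """First ``min(limit, n)`` rows; the full table remains available for
    download separately."""
    return table.head(limit).reset_index(drop=True)


def write_prediction_table(table: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        Path(path).write_text(table.to_json(orient="records", indent=2))
    else:
        raise ParameterError(f"unknown format {fmt!r}")
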