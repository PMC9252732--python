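import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.metrics import average_precision_score, roc_auc_score

from gbanet.errors import EmptyInputError, FingerprintMismatchError
from gbanet.features import FeatureMatrix, adjacency_features
from gbanet.labels import LabeledSets
from gbanet.model import (
    TrainedModel,
    cross_validate,
    predict_all,
    train,
    truncate_for_display,
)
from gbanet.synthetic import (
    SyntheticSpec,
    block_assignment,
    generate_collection,
    generate_network,
)
from gbanet.labels import select_negatives


def make_features(values, genes=None, fingerprint="test"):
    values = np.asarray(values, dtype=float)
    genes = tuple(genes or (str(i + 1) for i in range(len(values))))
    return FeatureMatrix("adjacency", genes, values, fingerprint)


def make_labels(genes, pos, neg):
    pos, neg = frozenset(pos), frozenset(neg)
    return LabeledSets(pos, neg, frozenset(genes) - pos - neg)


def logistic_oracle(X, y, C=1.0):
    """Independent convex-optimizer oracle for the penalized objective
    C * sum log(1 + exp(-s_i (w.x + b))) + ||w||^2 / 2, intercept unpenalized."""
    s = 2.0 * y - 1.0

    def objective(theta):
        w, b = theta[:-1], theta[-1]
        z = s * (X @ w + b)
        return C * np.sum(np.logaddexp(0.0, -z)) + 0.5 * np.dot(w, w)

    res = minimize(objective, np.zeros(X.shape[1] + 1), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 5000})
    return res.x[:-1], res.x[-1]


SIX_POINT_X = np.array(
    [[0.0, 0.2], [0.3, -0.1], [0.1, 1.4], [1.0, 1.1], [1.3, 0.9], [0.9, -0.3]]
)
SIX_POINT_Y = np.array([0, 0, 0, 1, 1, 1])


def test_six_point_weights_match_convex_oracle():
    genes = [str(i + 1) for i in range(6)]
    fm = make_features(SIX_POINT_X, genes)
    labels = make_labels(genes, pos=genes[3:], neg=genes[:3])
    model = train(fm, labels, inverse_reg=1.0)
    w_ref, b_ref = logistic_oracle(SIX_POINT_X, SIX_POINT_Y, C=1.0)
    np.testing.assert_allclose(model.weights, w_ref, atol=1e-4)
    assert model.intercept == pytest.approx(b_ref, abs=1e-4)


def test_separating_coordinate_gets_dominant_positive_weight():
    X = np.array([[5.0, 0.1], [4.0, -0.2], [-5.0, 0.3], [-4.0, 0.0]])
    genes = ["1", "2", "3", "4"]
    model = train(make_features(X, genes), make_labels(genes, ["1", "2"], ["3", "4"]))
    assert model.weights[0] > 0
    assert abs(model.weights[0]) > abs(model.weights[1])


def test_uniform_duplication_equals_doubled_data_weight():
    """Duplicating every training row doubles the data term against the
    fixed l2 penalty, so the duplicated fit at C equals the original fit at
    2C; probabilities agree closely."""
    genes = [str(i + 1) for i in range(6)]
    fm = make_features(SIX_POINT_X, genes)
    labels = make_labels(genes, genes[3:], genes[:3])
    base_2c = train(fm, labels, inverse_reg=2.0)
    dup_genes = genes + [str(i + 10) for i in range(6)]
    dup_fm = make_features(np.vstack([SIX_POINT_X, SIX_POINT_X]), dup_genes)
    dup_labels = make_labels(dup_genes, genes[3:] + [str(i + 13) for i in range(3)],
                             genes[:3] + [str(i + 10) for i in range(3)])
    doubled = train(dup_fm, dup_labels, inverse_reg=1.0)
    p0 = base_2c.probabilities(SIX_POINT_X)
    p1 = doubled.probabilities(SIX_POINT_X)
    np.testing.assert_allclose(p0, p1, atol=1e-4)


def test_single_class_training_set_is_an_error():
    genes = ["1", "2"]
    fm = make_features([[0.0, 1.0], [1.0, 0.0]], genes)
    with pytest.raises(EmptyInputError):
        train(fm, make_labels(genes, pos=genes, neg=[]))


def brute_auprc(y, scores):
    """All-thresholds precision-recall step sum, computed from first principles."""
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y)[order]
    tp = fp = 0
    total_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    uniq_scores = scores[order]
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and uniq_scores[j] == uniq_scores[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def brute_auroc(y, scores):
    """Concordant-pair count (ties half weight) over all pos/neg pairs."""
    y = np.asarray(y)
    pos, neg = scores[y == 1], scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_metrics_match_brute_force_threshold_sweeps():
    rng = np.random.default_rng(0)
    y = np.array([1] * 7 + [0] * 13)
    scores = np.round(rng.normal(size=20) + y, 1)  # rounding forces some ties
    assert average_precision_score(y, scores) == pytest.approx(
        brute_auprc(y, scores), abs=1e-12
    )
    assert roc_auc_score(y, scores) == pytest.approx(brute_auroc(y, scores), abs=1e-12)


def _sbm_setup(n_pos, seed=0):
    spec = SyntheticSpec(seed=seed)
    net = generate_network(spec)
    blocks = block_assignment(spec)
    module = sorted(g for g in net.nodes if blocks[g] == 0)
    positives = frozenset(module[:n_pos])
    labels = select_negatives(positives, generate_collection(net, spec), net)
    return adjacency_features(net), labels


def test_cv_skipped_below_fifteen_positives():
    fm, labels = _sbm_setup(14)
    assert cross_validate(fm, labels, seed=0) is None


def test_cv_runs_three_folds_at_fifteen_positives():
    fm, labels = _sbm_setup(15)
    metrics = cross_validate(fm, labels, seed=0)
    assert metrics is not None and metrics.n_folds == 3
    assert len(metrics.auprc) == 3
    for vals in (metrics.auprc, metrics.auroc, metrics.p_at_topk):
        assert all(0.0 <= v <= 1.0 for v in vals)


def test_cv_auprc_beats_positive_prior_on_separable_module():
    """Strongly separable fixture: dense planted module, sparse background,
    and a negative collection drawn entirely outside the module, so P and N
    occupy different blocks.  Mean CV auPRC must beat the positive prior by
    at least 3x across 5 seeds."""
    from gbanet.labels import GeneSet, GeneSetCollection

    ratios = []
    for seed in range(5):
        spec = SyntheticSpec(p_within=0.6, p_between=0.005, seed=seed)
        net = generate_network(spec)
        blocks = block_assignment(spec)
        module = sorted(g for g in net.nodes if blocks[g] == 0)
        background = [g for g in net.nodes if blocks[g] == 1]
        rng = np.random.default_rng(seed)
        sets = tuple(
            GeneSet(f"S{k}", "clean negatives",
                    frozenset(rng.choice(background, size=20, replace=False)))
            for k in range(4)
        )
        labels = select_negatives(
            frozenset(module[:20]), GeneSetCollection("clean", sets), net
        )
        metrics = cross_validate(adjacency_features(net), labels, seed=seed)
        prior = len(labels.positives) / (len(labels.positives) + len(labels.negatives))
        ratios.append(metrics.mean_auprc / prior)
    assert np.mean(ratios) >= 3.0


def test_probabilities_are_closed_form_logistic():
    w, b = np.array([0.7, -1.2]), 0.3
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, -1.0], [-3.0, 0.5], [0.1, 0.9]])
    genes = [str(i + 1) for i in range(5)]
    fm = make_features(X, genes)
    model = TrainedModel(w, b, fm.params_fingerprint, (2, 3))
    labels = make_labels(genes, ["1"], ["2"])
    table = predict_all(model, fm, labels)
    expected = {g: 1.0 / (1.0 + np.exp(-(x @ w + b))) for g, x in zip(genes, X)}
    for _, row in table.iterrows():
        assert row["Probability"] == pytest.approx(expected[row["Entrez"]], abs=1e-10)


def test_tied_probabilities_rank_by_ascending_entrez():
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    genes = ["30", "4", "7"]
    fm = make_features(X, genes)
    model = TrainedModel(np.array([1.0, 0.0]), 0.0, fm.params_fingerprint, (1, 1))
    table = predict_all(model, fm, make_labels(genes, ["4"], ["7"]))
    tied = table[table["Probability"] == table["Probability"].max()]
    assert list(tied["Entrez"]) == ["4", "30"]
    assert list(table["Rank"]) == [1, 2, 3]


def test_known_novel_follows_training_label():
    X = np.eye(3)
    genes = ["1", "2", "3"]
    fm = make_features(X, genes)
    model = TrainedModel(np.ones(3), 0.0, fm.params_fingerprint, (1, 1))
    table = predict_all(model, fm, make_labels(genes, ["1"], ["2"]))
    status = dict(zip(table["Entrez"], table["Known/Novel"]))
    labels_out = dict(zip(table["Entrez"], table["Training-Label"]))
    assert status == {"1": "Known", "2": "Novel", "3": "Novel"}
    assert labels_out == {"1": "P", "2": "N", "3": "U"}


def test_fingerprint_mismatch_refuses_to_score():
    genes = ["1", "2"]
    fm = make_features(np.eye(2), genes, fingerprint="A")
    other = make_features(np.eye(2), genes, fingerprint="B")
    model = TrainedModel(np.ones(2), 0.0, "A", (1, 1))
    with pytest.raises(FingerprintMismatchError):
        predict_all(model, other, make_labels(genes, ["1"], ["2"]))


def test_probabilities_strictly_inside_unit_interval_and_rank_bijection():
    fm, labels = _sbm_setup(20)
    model = train(fm, labels)
    table = predict_all(model, fm, labels)
    assert ((table["Probability"] > 0) & (table["Probability"] < 1)).all()
    assert sorted(table["Rank"]) == list(range(1, len(table) + 1))
    assert table["Probability"].is_monotonic_decreasing


def test_identical_feature_rows_get_identical_probabilities():
    X = np.array([[0.5, 0.5], [0.5, 0.5], [0.1, 0.9], [0.9, 0.1]])
    genes = ["1", "2", "3", "4"]
    fm = make_features(X, genes)
    labels = make_labels(genes, ["1", "2"], ["3", "4"])
    model = train(fm, labels)
    table = predict_all(model, fm, labels).set_index("Entrez")
    assert table.loc["1", "Probability"] == table.loc["2", "Probability"]


def test_truncation_cap_and_prefix():
    fm, labels = _sbm_setup(20)
    model = train(fm, labels)
    table = predict_all(model, fm, labels)
    top = truncate_for_display(table, limit=30)
    assert len(top) == 30
    assert list(top["Rank"]) == list(range(1, 31))
    assert len(truncate_for_display(table, limit=10_000)) == len(table)


def test_model_save_load_round_trip(tmp_path):
    fm, labels = _sbm_setup(16)
    model = train(fm, labels, settings={"network_name": "sbm"})
    model.save(tmp_path / "m.json")
    back = TrainedModel.load(tmp_path / "m.json")
    np.testing.assert_array_equal(back.weights, model.weights)
    assert back.intercept == model.intercept
    assert back.feature_fingerprint == model.feature_fingerprint
    assert back.settings == model.settings
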