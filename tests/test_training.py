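import itertools
import math

import numpy as np
import pytest

from gep import training as tr
from gep.graph_models import IgepConfig, IGepModel
from gep.nn import Tensor


def mcc_closed_form(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


def brute_force_auc_roc(y, p):
    """Threshold-sweep trapezoid oracle."""
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(p))[::-1], [-np.inf]])
    tpr, fpr = [], []
    P, N = y.sum(), (1 - y).sum()
    for t in thresholds:
        pred = p >= t
        tpr.append((pred & (y == 1)).sum() / P)
        fpr.append((pred & (y == 0)).sum() / N)
    return float(np.trapezoid(tpr, fpr))


def brute_force_auc_pr(y, p):
    """Interpolation-free summation oracle: sum (R_k - R_{k-1}) P_k."""
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    P = y.sum()
    tp = fp = 0
    auc = prev_recall = 0.0
    i = 0
    n = len(y_sorted)
    while i < n:
        j = i
        while j < n and p_sorted[j] == p_sorted[i]:
            tp += y_sorted[j]
            fp += 1 - y_sorted[j]
            j += 1
        recall = tp / P
        precision = tp / (tp + fp)
        auc += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(auc)


class TestWeightedBCE:
    def test_perfect_predictions_near_zero(self):
        y = np.array([0, 1, 1, 0])
        loss = tr.weighted_bce(y.astype(float), y, "batch")
        assert float(loss.data) <= 1e-6

    def test_balanced_equals_unweighted(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 10)
        y = np.array([0, 1] * 5)
        got = float(tr.weighted_bce(p, y, "batch").data)
        want = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        assert got == pytest.approx(want, rel=1e-6)

    def test_hand_computed_value(self):
        # probs 0.5 everywhere, 1 positive / 3 negatives, batch weighting:
        # loss = -[3 ln(1/2) + 3 * ln(1/2)] / 4 = (6/4) ln 2
        p = np.full(4, 0.5)
        y = np.array([1, 0, 0, 0])
        got = float(tr.weighted_bce(p, y, "batch").data)
        assert got == pytest.approx(1.5 * math.log(2), rel=1e-9)

    def test_single_class_batch_falls_back_with_warning(self):
        p = np.full(3, 0.5)
        y = np.ones(3)
        with pytest.warns(UserWarning):
            loss = tr.weighted_bce(p, y, "batch", global_pos_weight=2.0)
        assert float(loss.data) == pytest.approx(2.0 * math.log(2), rel=1e-9)

    def test_gradient_survives_saturated_probabilities(self):
        from gep.nn import Parameter

        w = Parameter(np.array([30.0]))  # sigmoid(30) == 1.0 in float64
        p = w.sigmoid()
        loss = tr.weighted_bce(p, np.array([0]), "global", 1.0)
        loss.backward()
        assert w.grad is not None and w.grad[0] != 0.0


class TestAugmentRotation:
    def test_isometry_and_labels(self, synth_sample):
        out = tr.augment_rotation(synth_sample, seed=4)
        for attr in ("ab_graph", "ag_graph"):
            a = getattr(synth_sample, attr).node_coords
            b = getattr(out, attr).node_coords
            da = np.linalg.norm(a[:, None] - a[None, :], axis=2)
            db = np.linalg.norm(b[:, None] - b[None, :], axis=2)
            np.testing.assert_allclose(da, db, atol=1e-9)
        np.testing.assert_array_equal(
            out.ab_labels.per_residue, synth_sample.ab_labels.per_residue
        )
        np.testing.assert_array_equal(out.ab_graph.edges, synth_sample.ab_graph.edges)

    def test_deterministic_in_seed_and_actually_moves(self, synth_sample):
        a = tr.augment_rotation(synth_sample, seed=1)
        b = tr.augment_rotation(synth_sample, seed=1)
        np.testing.assert_array_equal(a.ag_graph.node_coords, b.ag_graph.node_coords)
        assert np.abs(a.ag_graph.node_coords - synth_sample.ag_graph.node_coords).max() > 0.1

    def test_rotation_is_proper_isometry(self, synth_sample):
        """The applied map preserves orientation (det +1), not a reflection."""
        out = tr.augment_rotation(synth_sample, seed=9)
        a = synth_sample.ag_graph.node_coords
        b = out.ag_graph.node_coords
        a0, b0 = a - a.mean(axis=0), b - b.mean(axis=0)
        rot, *_ = np.linalg.lstsq(a0, b0, rcond=None)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-6)


class TestEvaluate:
    def test_perfect_separation(self):
        rep = tr.evaluate(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert rep.mcc == pytest.approx(1.0)
        assert rep.auc_roc == pytest.approx(1.0)
        assert rep.auc_pr == pytest.approx(1.0)

    def test_contingency_table_example(self):
        # TP=2 TN=2 FP=1 FN=1 -> MCC = 3/9 = 1/3
        y = np.array([1, 1, 1, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.1, 0.9, 0.2, 0.1])
        rep = tr.evaluate(p, y)
        assert rep.mcc == pytest.approx(1 / 3, abs=1e-12)

    def test_single_class_flagged(self):
        rep = tr.evaluate(np.array([0.4, 0.6]), np.array([1, 1]))
        assert rep.single_class and rep.mcc == 0.0
        assert np.isnan(rep.auc_roc) and np.isnan(rep.auc_pr)

    def test_mcc_on_all_small_contingency_tables(self):
        for tp, tn, fp, fn in itertools.product(range(3), repeat=4):
            y = np.array([1] * (tp + fn) + [0] * (tn + fp))
            p = np.array([0.9] * tp + [0.1] * fn + [0.1] * tn + [0.9] * fp)
            if len(y) == 0 or y.min() == y.max():
                continue
            rep = tr.evaluate(p, y)
            assert rep.mcc == pytest.approx(
                mcc_closed_form(tp, tn, fp, fn), abs=1e-9
            ), (tp, tn, fp, fn)

    def test_auc_matches_brute_force_sweep(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            p = np.round(rng.random(n), 2)  # ties included
            rep = tr.evaluate(p, y)
            assert rep.auc_roc == pytest.approx(brute_force_auc_roc(y, p), abs=1e-9)
            assert rep.auc_pr == pytest.approx(brute_force_auc_pr(y, p), abs=1e-9)


class TestEnsemble:
    def test_mean_and_product_hand_values(self):
        assert tr.ensemble_combine(np.array([0.4]), np.array([0.6]), "mean")[0] == pytest.approx(0.5)
        assert tr.ensemble_combine(np.array([0.4]), np.array([0.6]), "product")[0] == pytest.approx(0.24)

    def test_product_never_exceeds_min(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(100), rng.random(100)
        prod = tr.ensemble_combine(a, b, "product")
        assert np.all(prod <= np.minimum(a, b) + 1e-15)
        mean = tr.ensemble_combine(a, b, "mean")
        assert np.all((mean >= 0) & (mean <= 1))

    def test_dict_alignment(self):
        a = {"antigen": np.array([0.2])}
        b = {"antibody": np.array([0.4])}
        with pytest.raises(ValueError):
            tr.ensemble_combine(a, b, "mean")
        c = tr.ensemble_combine(
            {"antigen": np.array([0.2])}, {"antigen": np.array([0.4])}, "mean"
        )
        assert c["antigen"][0] == pytest.approx(0.3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tr.ensemble_combine(np.zeros(3), np.zeros(4), "mean")


class TestAggregateSeeds:
    def test_identical_reports_zero_spread(self):
        r = tr.MetricsReport(mcc=0.5, auc_roc=0.8, auc_pr=0.6)
        agg = tr.aggregate_seeds([r, r, r])
        assert agg["mcc_mean"] == 0.5 and agg["mcc_std"] == 0.0

    def test_two_value_mean(self):
        rs = [
            tr.MetricsReport(mcc=0.4, auc_roc=0.0, auc_pr=0.0),
            tr.MetricsReport(mcc=0.6, auc_roc=0.0, auc_pr=0.0),
        ]
        agg = tr.aggregate_seeds(rs)
        assert agg["mcc_mean"] == pytest.approx(0.5)
        assert agg["mcc_std"] == pytest.approx(0.1)


class TestMetricShift:
    def test_identical_zero(self):
        assert tr.metric_shift([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == 0.0

    def test_point_masses(self):
        assert tr.metric_shift([0.0], [1.0]) == pytest.approx(1.0)

    def test_matches_sorted_sample_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random(int(rng.integers(2, 30)))
            b = rng.random(len(a))
            want = np.abs(np.sort(a) - np.sort(b)).mean()
            assert tr.metric_shift(a, b) == pytest.approx(want, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tr.metric_shift([], [0.5])


class TestTrainModel:
    def test_smoke_and_epoch1_determinism(self, small_dataset):
        train, val, _ = small_dataset
        cfg = tr.TrainConfig(lr=5e-3, epochs=2, seeds=[0])

        def build():
            return IGepModel(IgepConfig(hidden_dim=16), seed=0)

        _, hist1 = tr.train_model(build, train[:4], val, cfg)
        _, hist2 = tr.train_model(build, train[:4], val, cfg)
        assert hist1["seeds"][0][0]["loss"] == hist2["seeds"][0][0]["loss"]
        assert len(hist1["seeds"][0]) == 2
        assert "val_mcc" in hist1["seeds"][0][0]

    def test_loss_decreases_on_learnable_set(self, small_dataset):
        train, _, _ = small_dataset
        cfg = tr.TrainConfig(lr=5e-3, epochs=4, seeds=[1])

        def build():
            return IGepModel(IgepConfig(hidden_dim=16), seed=1)

        _, hist = tr.train_model(build, train, None, cfg)
        losses = [e["loss"] for e in hist["seeds"][1]]
        assert losses[-1] < losses[0]

    def test_augmentation_preserves_labels_and_topology(self, small_dataset):
        train, _, _ = small_dataset
        s = train[0]
        rotated = tr.augment_rotation(s, 123)
        np.testing.assert_array_equal(
            rotated.ag_labels.per_residue, s.ag_labels.per_residue
        )
        np.testing.assert_array_equal(rotated.ab_graph.edges, s.ab_graph.edges)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            tr.train_model(lambda: None, [], None, tr.TrainConfig(seeds=[0]))
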