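"""Metrics, bootstrap, corrected t-test, scenarios, and confusion scaling."""

import numpy as np
import pytest
from scipy import stats as sps

from trapod.evaluate import (
    aggregate_attention_report,
    bootstrap_metrics,
    compute_metrics,
    corrected_t_test,
    scale_confusion,
    threshold_scenarios,
)


def brute_force_auroc(scores, labels):
    """Pairwise concordance with ties counting one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_enumerated_example(self):
        m = compute_metrics([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert m.auroc == pytest.approx(0.75)

    def test_perfect_separation(self):
        m = compute_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m.auroc == 1.0 and m.auprc == 1.0

    def test_random_scores_auprc_approaches_prevalence(self):
        rng = np.random.default_rng(0)
        n = 20000
        y = (rng.random(n) < 0.2).astype(int)
        s = rng.random(n)
        m = compute_metrics(s, y)
        assert m.auprc == pytest.approx(0.2, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([0.3, 0.5], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_auroc_equals_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        # include ties via discretized scores
        s = np.round(rng.random(n), 1)
        m = compute_metrics(s, y)
        assert m.auroc == pytest.approx(brute_force_auroc(s, y), abs=1e-12)

    def test_precision_at_recall_is_max_feasible(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        labels = np.array([1, 0, 1, 1, 0, 0])
        m = compute_metrics(scores, labels, recall_level=0.8)
        # thresholds with recall >= 0.8 keep at least 3 of 3 positives... the
        # best is 3 positives among top-4 scores: precision 0.75
        assert m.precision_at_recall == pytest.approx(0.75)


class TestBootstrap:
    def test_perfect_classifier_degenerate_ci(self):
        scores = np.array([0.9, 0.95, 0.1, 0.2, 0.15, 0.05])
        labels = np.array([1, 1, 0, 0, 0, 0])
        b = bootstrap_metrics(scores, labels, B=50, seed=1)
        assert b.ci_low == b.ci_high == b.mean == 1.0

    def test_single_resample_mean(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        b = bootstrap_metrics(s, y, B=1, seed=3)
        assert b.mean == b.values[0]

    def test_same_seed_identical(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.random(40)
        a = bootstrap_metrics(s, y, B=100, seed=9)
        b = bootstrap_metrics(s, y, B=100, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_mean_converges_to_point_estimate(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 300)
        s = rng.random(300) + 0.3 * y
        point = compute_metrics(s, y).auroc
        b = bootstrap_metrics(s, y, B=2000, seed=0)
        assert abs(b.mean - point) < 0.01

    def test_invalid_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_metrics([0.1, 0.9], [0, 1], B=0)


class TestCorrectedTTest:
    def test_identical_vectors_give_t_zero_p_one(self):
        P = np.linspace(0.6, 0.8, 10)
        res = corrected_t_test(P, P, 100, 50)
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_literal_arithmetic_oracle(self):
        rng = np.random.default_rng(8)
        P0, P1 = rng.random(10), rng.random(10)
        n_train, n_test = 300, 100
        res = corrected_t_test(P0, P1, n_train, n_test)
        # independent step-by-step oracle
        D = np.abs(P0 - P1)
        d_bar = D.sum() / 10
        var = ((D - d_bar) ** 2).sum() / 9
        sigma2 = var * (1 / 10 + n_train / n_test)
        t = d_bar / np.sqrt(sigma2)
        p = 2 * (1 - sps.t.cdf(abs(t), 9))
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_t_strictly_decreasing_in_train_test_ratio(self):
        rng = np.random.default_rng(9)
        P0, P1 = rng.random(20), rng.random(20)
        ts = [corrected_t_test(P0, P1, n_train, 100).t
              for n_train in (50, 100, 200, 400)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_reduces_to_classical_paired_t_as_ratio_vanishes(self):
        rng = np.random.default_rng(10)
        P0, P1 = rng.random(15), rng.random(15)
        res = corrected_t_test(P0, P1, 1, 10**9)
        D = np.abs(P0 - P1)
        classical = D.mean() / (D.std(ddof=1) / np.sqrt(15))
        assert res.t == pytest.approx(classical, rel=1e-6)

    def test_ratio_orientation_flag(self):
        rng = np.random.default_rng(11)
        P0, P1 = rng.random(10), rng.random(10)
        a = corrected_t_test(P0, P1, 400, 100, ratio="train_over_test")
        b = corrected_t_test(P0, P1, 400, 100, ratio="test_over_train")
        assert abs(b.t) > abs(a.t)  # smaller correction -> larger statistic

    def test_zero_variance_nonzero_mean(self):
        res = corrected_t_test([0.7] * 5, [0.6] * 5, 10, 10)
        assert res.t == np.inf and res.p == 0.0


class TestScenarios:
    def test_perfect_classifier_scenario_a(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1, 0.15, 0.05])
        labels = np.array([1, 1, 0, 0, 0, 0])
        scen = threshold_scenarios(scores, labels)
        assert scen["A"].sensitivity == 1.0 and scen["A"].specificity == 1.0

    def test_matches_exhaustive_sweep_oracle(self):
        scores = np.array([0.9, 0.7, 0.65, 0.4, 0.3, 0.1])
        labels = np.array([1, 0, 1, 1, 0, 0])
        scen = threshold_scenarios(scores, labels)
        # brute force over all cut points
        best_a, best_b = None, None
        for thr in np.unique(scores):
            pred = scores >= thr
            tp = (pred & (labels == 1)).sum()
            fp = (pred & (labels == 0)).sum()
            sens = tp / 3
            spec = ((~pred) & (labels == 0)).sum() / 3
            prec = tp / max(tp + fp, 1)
            if best_a is None or sens + spec > best_a[0]:
                best_a = (sens + spec, thr)
            if best_b is None or prec + sens > best_b[0]:
                best_b = (prec + sens, thr)
        assert scen["A"].sensitivity + scen["A"].specificity == pytest.approx(best_a[0])
        assert scen["B"].precision + scen["B"].recall == pytest.approx(best_b[0])

    def test_scenario_c_pins_recall(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 200)
        s = rng.random(200) + 0.4 * y
        scen = threshold_scenarios(s, y, recall_target=0.8)
        assert scen["C"].recall >= 0.8

    def test_unreachable_recall_errors(self):
        with pytest.raises(ValueError, match="unreachable"):
            threshold_scenarios([0.9, 0.1], [0, 1], recall_target=2.0)


class TestScaleConfusion:
    def test_printed_scenario_c_numbers(self):
        # recall 0.8, precision 0.163, 100 surgeries at 9% prevalence
        assert scale_confusion(0.8, 0.163, 100, 0.09) == (7, 36, 55, 2)

    def test_perfect_operating_point(self):
        assert scale_confusion(1.0, 1.0, 100, 0.09) == (9, 0, 91, 0)

    def test_scenario_b_floor_convention(self):
        tp, *_ = scale_confusion(0.974, 0.108, 100, 0.09)
        assert tp == 8

    def test_caseload_decomposition(self):
        tp, fp, tn, fn = scale_confusion(0.5, 0.5, 100, 0.09)
        assert tp + fn == 9 and tn + fp == 91

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            scale_confusion(0.0, 0.5)


class TestAttentionReport:
    def _att(self, saliency, received=None):
        from trapod.models import AttentionMatrix

        k, n = saliency.shape
        return AttentionMatrix(
            attention=np.full((n, n), 1 / n),
            saliency=saliency,
            per_time_mean=saliency.mean(axis=0),
            channel_names=[f"c{i}" for i in range(k)],
            per_surgery_received=received,
        )

    def test_uniform_saliency_flat_profile(self):
        rep = aggregate_attention_report(self._att(np.full((3, 5), 0.2)), B=0)
        assert len(set(np.round(rep["time_profile"], 12))) == 1

    def test_row_sums_match_brute_force(self):
        rng = np.random.default_rng(13)
        s = rng.random((4, 6))
        rep = aggregate_attention_report(self._att(s), B=0)
        for i in range(4):
            assert rep["feature_sums"][i] == pytest.approx(sum(s[i]), abs=1e-12)

    def test_bootstrap_ci_brackets_mean(self):
        rng = np.random.default_rng(14)
        received = rng.random((50, 6))
        rep = aggregate_attention_report(self._att(rng.random((2, 6)), received),
                                         B=200, seed=0)
        mean = received.mean(axis=0)
        assert (np.array(rep["per_time_ci_low"]) <= mean + 1e-9).all()
        assert (np.array(rep["per_time_ci_high"]) >= mean - 1e-9).all()
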