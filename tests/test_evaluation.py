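"""Metrics, the iteration protocol, and model-comparison statistics."""

import numpy as np
import pytest
from scipy import stats

from pedmet.cohorts import WindowSpec
from pedmet.evaluation import (
    ProtocolResult,
    friedman_compare,
    longitudinal_vs_recent,
    nemenyi_critical_distance,
    optimize_threshold,
    roc_auc,
    run_protocol,
    sensitivity_specificity,
)
from pedmet.models import ModelConfig
from test_models import make_dataset


def brute_force_auc(scores, labels):
    """Pair counting: P(case > control) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_friedman(ranks):
    """Chi-square statistic from the rank-sum formula (no ties)."""
    k, n = ranks.shape
    r_sum = ranks.sum(axis=1)
    return 12.0 / (n * k * (k + 1)) * np.sum(r_sum**2) - 3.0 * n * (k + 1)


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_hand_counted_pairs(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(np.exp(3 * scores), labels), abs=1e-12
        )


class TestThreshold:
    def test_separable_scores_midpoint(self):
        t = optimize_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0.2 < t <= 0.8
        assert t == pytest.approx(0.5)

    def test_random_scores_give_near_zero_j(self):
        rng = np.random.default_rng(2)
        scores = rng.random(500)
        labels = rng.integers(0, 2, size=500)
        t = optimize_threshold(scores, labels)
        sens, spec = sensitivity_specificity(scores, labels, t)
        assert sens + spec - 1.0 < 0.15  # J at optimum stays small under the null

    def test_j_reproduced_from_confusion_matrix(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0.6, 0.2, 40), rng.normal(0.4, 0.2, 60)])
        labels = np.array([1] * 40 + [0] * 60)
        t = optimize_threshold(scores, labels)
        sens, spec = sensitivity_specificity(scores, labels, t)
        best_j = max(
            sensitivity_specificity(scores, labels, c)[0]
            + sensitivity_specificity(scores, labels, c)[1]
            - 1.0
            for c in np.unique(scores)
        )
        assert sens + spec - 1.0 == pytest.approx(best_j, abs=1e-9)

    def test_ties_resolve_toward_higher_specificity(self):
        # J = 0.5 both below 0.2 and above 0.8; the larger cutoff wins
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 1, 0, 1]
        assert optimize_threshold(scores, labels) == pytest.approx(0.85)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold([0.1, 0.9], [1, 1])


class TestRunProtocol:
    def test_deterministic_under_base_seed(self):
        ds = make_dataset(n=80, signal=1.0)
        cfg = ModelConfig(kind="random_forest", n_estimators=30, seed=0)
        a = run_protocol(ds, cfg, iterations=2, base_seed=5)
        b = run_protocol(ds, cfg, iterations=2, base_seed=5)
        assert a.iterations == b.iterations

    def test_single_iteration_medians_equal_values(self):
        ds = make_dataset(n=80, signal=1.0)
        cfg = ModelConfig(kind="random_forest", n_estimators=30, seed=0)
        r = run_protocol(ds, cfg, iterations=1, base_seed=1)
        assert r.median_test_auc == r.iterations[0]["test_auc"]
        assert r.median_sensitivity == r.iterations[0]["sensitivity"]

    def test_records_all_metrics(self):
        ds = make_dataset(n=80, signal=1.0)
        cfg = ModelConfig(kind="random_forest", n_estimators=30, seed=0)
        r = run_protocol(ds, cfg, iterations=2, base_seed=0)
        for it in r.iterations:
            assert {"cv_auc", "test_auc", "sensitivity", "specificity", "threshold"} <= set(it)
        assert len(r.to_frame()) == 2
        assert set(r.summary()["metric"]) == {"test_auc", "sensitivity", "specificity", "cv_auc"}


class TestFriedman:
    def test_identical_aucs_zero_statistic(self):
        table = np.full((3, 5), 0.7)
        stat, p, ranks = friedman_compare(table)
        assert stat == 0.0
        assert np.allclose(ranks, 2.0)

    def test_dominant_model_rank_one(self):
        table = np.array(
            [[0.9, 0.91, 0.92, 0.9], [0.8, 0.7, 0.75, 0.72], [0.6, 0.65, 0.6, 0.62]]
        )
        _, _, ranks = friedman_compare(table, ["A", "B", "C"])
        assert ranks["A"] == 1.0

    def test_hand_computed_statistic(self):
        # per-window ranks [[1,2,3],[1,2,3],[1,3,2],[1,2,3]] -> 6.5
        table = np.array(
            [[0.9, 0.9, 0.9, 0.9], [0.8, 0.8, 0.7, 0.8], [0.7, 0.7, 0.8, 0.7]]
        )
        stat, _, _ = friedman_compare(table)
        assert stat == pytest.approx(6.5)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            table = rng.random((5, 8))
            stat, _, _ = friedman_compare(table)
            ranks = np.array([stats.rankdata(-table[:, j]) for j in range(8)]).T
            assert stat == pytest.approx(brute_force_friedman(ranks), abs=1e-9)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        table = rng.random((4, 10))
        stat, p, _ = friedman_compare(table)
        ref = stats.friedmanchisquare(*[table[i] for i in range(4)])
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_missing_cells_rejected(self):
        table = np.full((3, 4), 0.7)
        table[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman_compare(table)

    def test_nemenyi_distance_formula(self):
        assert nemenyi_critical_distance(4, 8) == pytest.approx(
            2.569 * np.sqrt(4 * 5 / (6 * 8.0))
        )


def _protocol_stub(window, aucs):
    return ProtocolResult(window, "stub", [{"test_auc": a} for a in aucs])


class TestLongitudinalVsRecent:
    def _windows(self, k):
        return [WindowSpec("t2d", 2, 2 + i + 1, (13.4, 18.0)) for i in range(k)]

    def test_identical_aucs_no_improvement(self):
        ws = self._windows(4)
        traj = [_protocol_stub(w, [0.7, 0.72]) for w in ws]
        rec = [_protocol_stub(w, [0.7, 0.72]) for w in ws]
        med, imps, p = longitudinal_vs_recent(traj, rec)
        assert med == 0.0 and p == 1.0

    def test_uniform_gain_positive_and_significant(self):
        ws = self._windows(8)
        rng = np.random.default_rng(6)
        base = [0.6 + 0.02 * rng.random(2) for _ in ws]
        traj = [_protocol_stub(w, list(b + 0.05)) for w, b in zip(ws, base)]
        rec = [_protocol_stub(w, list(b)) for w, b in zip(ws, base)]
        med, imps, p = longitudinal_vs_recent(traj, rec)
        assert med > 0
        assert np.all(imps > 0)
        assert p < 0.01

    def test_single_pair_degenerate_p(self):
        ws = self._windows(1)
        traj = [_protocol_stub(ws[0], [0.75])]
        rec = [_protocol_stub(ws[0], [0.70])]
        _, _, p = longitudinal_vs_recent(traj, rec)
        assert p == pytest.approx(0.5)

    def test_window_mismatch_rejected(self):
        traj = [_protocol_stub(WindowSpec("t2d", 2, 5, (13.4, 18.0)), [0.7])]
        rec = [_protocol_stub(WindowSpec("t2d", 2, 6, (13.4, 18.0)), [0.7])]
        with pytest.raises(ValueError):
            longitudinal_vs_recent(traj, rec)


def test_critical_difference_plot_writes_file(tmp_path):
    from pedmet.evaluation import critical_difference_plot, nemenyi_critical_distance

    cd = nemenyi_critical_distance(3, 10)
    path = tmp_path / "cd.png"
    critical_difference_plot({"A": 1.2, "B": 2.1, "C": 2.7}, cd, str(path))
    assert path.exists() and path.stat().st_size > 0
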