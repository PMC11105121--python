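"""Window enumeration, cohort assembly, feature screening and splits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from pedmet.cohorts import (
    StratificationError,
    WindowSpec,
    assemble_cohort,
    association_screen,
    build_wide_candidates,
    enumerate_windows,
    lasso_select,
    stratified_kfold,
    stratified_split,
)
from pedmet.phenotype import label_outcome
from pedmet.simulate import SimulationConfig, generate_cohort


def brute_force_bh(pvals):
    """Textbook Benjamini-Hochberg: q_i = min_{j>=rank(i)} (m * p_(j) / j)."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, m * pvals[idx] / rank_from_top)
        q[idx] = running_min
    return np.minimum(q, 1.0)


class TestEnumerateWindows:
    @pytest.mark.parametrize(
        "onset_mean, expected", [(13.4, 66), (12.5, 55), (12.3, 55), (3.4, 1)]
    )
    def test_printed_window_counts(self, onset_mean, expected):
        assert len(enumerate_windows(onset_mean)) == expected

    def test_smallest_case_is_two_to_three(self):
        (w,) = enumerate_windows(3.4)
        assert (w.start_age, w.end_age) == (2, 3)

    def test_no_valid_window_raises(self):
        with pytest.raises(ValueError):
            enumerate_windows(3.0)

    def test_ordering_and_bounds(self):
        ws = enumerate_windows(12.5)
        pairs = [(w.start_age, w.end_age) for w in ws]
        assert pairs == sorted(pairs)
        assert all(2 <= s < e <= 12 for s, e in pairs)

    @settings(max_examples=30, deadline=None)
    @given(onset=st.floats(3.1, 18.0))
    def test_count_is_binomial_coefficient(self, onset):
        assert len(enumerate_windows(onset)) == math.comb(math.floor(onset) - 1, 2)


@pytest.fixture(scope="module")
def assembled(ref, definitions):
    ps = generate_cohort(SimulationConfig(n_patients=500, seed=21))
    defn = definitions["prediabetes"]
    labels = {p.patient_id: label_outcome(p, defn, ref) for p in ps}
    window = WindowSpec("prediabetes", 4, 10, (12.3, 18.0))
    return ps, labels, assemble_cohort(ps, labels, window, ref, 12.3)


class TestAssembleCohort:

    def test_rows_aligned(self, assembled):
        _, _, ds = assembled
        assert ds.trajectory_tensor.shape[0] == len(ds.labels) == len(ds.patient_ids)
        assert ds.trajectory_tensor.shape[1:] == (6, 2)
        assert ds.wide_matrix.shape == (ds.n_patients, len(ds.feature_names))

    def test_only_covering_included_patients(self, assembled, ref):
        from pedmet.phenotype import passes_inclusion
        from pedmet.trajectories import harmonize_bmi

        ps, labels, ds = assembled
        by_id = ps.by_id()
        for pid in ds.patient_ids:
            assert passes_inclusion(by_id[pid], ref)

    def test_outcome_codes_never_leak_into_wide_features(self, assembled):
        _, _, ds = assembled
        assert not any(name.startswith("dx_R73") for name in ds.feature_names)

    def test_small_cohort_dropped(self, ref, definitions):
        ps = generate_cohort(SimulationConfig(n_patients=25, seed=22))
        defn = definitions["prediabetes"]
        labels = {p.patient_id: label_outcome(p, defn, ref) for p in ps}
        window = WindowSpec("prediabetes", 2, 12, (12.3, 18.0))
        assert assemble_cohort(ps, labels, window, ref, 12.3) is None


class TestAssociationScreen:
    def test_bh_adjustment_matches_brute_force(self):
        # classic worked case
        pvals = np.array([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(brute_force_bh(pvals), [0.04, 0.04, 0.04, 0.5])
        # and on random p-values against statsmodels' implementation
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(2, 30))
            assert np.allclose(multipletests(p, method="fdr_bh")[1], brute_force_bh(p))

    def test_feature_identical_to_label_tiny_q(self):
        rng = np.random.default_rng(1)
        y = (rng.random(200) < 0.5).astype(int)
        X = np.column_stack([y.astype(float), rng.normal(size=200)])
        q = association_screen(X, y, ["dup", "noise"])
        assert q["dup"] < 1e-5
        assert q["noise"] > 0.05

    def test_constant_feature_q_one(self):
        rng = np.random.default_rng(2)
        y = (rng.random(100) < 0.4).astype(int)
        X = np.column_stack([np.ones(100), y + rng.normal(0, 2, 100)])
        q = association_screen(X, y, ["const", "weak"])
        assert q["const"] == 1.0

    def test_type_one_error_controlled(self):
        # label-independent feature passes in roughly alpha of replicates
        rng = np.random.default_rng(3)
        hits = 0
        reps = 300
        for _ in range(reps):
            y = (rng.random(300) < 0.3).astype(int)
            x = rng.normal(size=(300, 1))
            q = association_screen(x, y, ["f"])
            hits += q["f"] < 0.05
        rate = hits / reps
        assert rate < 0.10  # ~5% nominal; generous Monte-Carlo margin

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            association_screen(np.ones((10, 1)), np.zeros(10), ["f"])


class TestLassoSelect:
    def _data(self, seed=7, n=2000, beta=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 10))
        eta = beta * X[:, 0] - 1.5
        y = (rng.random(n) < expit(eta)).astype(int)
        return X, y, [f"f{i}" for i in range(10)]

    def test_recovers_true_feature(self):
        X, y, names = self._data()
        kept = lasso_select(X, y, names, seed=7)
        assert "f0" in kept
        assert len(kept) <= 4  # 1-SE rule keeps the model sparse

    def test_deterministic_under_seed(self):
        X, y, names = self._data()
        assert lasso_select(X, y, names, seed=3) == lasso_select(X, y, names, seed=3)

    def test_pure_noise_gives_empty_or_tiny_subset(self):
        X, y, names = self._data(beta=0.0, n=500)
        kept = lasso_select(X, y, names, seed=0)
        assert len(kept) <= 2  # typically empty under the 1-SE rule

    def test_selection_subset_of_candidates(self):
        X, y, names = self._data(n=800)
        assert set(lasso_select(X, y, names, seed=1)) <= set(names)


class TestSplits:
    def test_split_proportions_exact(self):
        y = np.array([1] * 10 + [0] * 90)
        tr, te = stratified_split(y, 0.8, seed=0)
        assert y[tr].sum() == 8 and y[te].sum() == 2
        assert len(tr) == 80 and len(te) == 20

    def test_split_is_partition(self):
        y = (np.random.default_rng(0).random(57) < 0.3).astype(int)
        tr, te = stratified_split(y, 0.8, seed=4)
        assert len(np.intersect1d(tr, te)) == 0
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(57))

    def test_split_deterministic(self):
        y = (np.random.default_rng(1).random(100) < 0.2).astype(int)
        a = stratified_split(y, 0.8, seed=9)
        b = stratified_split(y, 0.8, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_kfold_exact_class_counts(self):
        y = np.array([1] * 9 + [0] * 90)
        folds = stratified_kfold(y, k=3, seed=0)
        for f in range(3):
            assert y[folds == f].sum() == 3
            assert (y[folds == f] == 0).sum() == 30

    def test_kfold_is_partition(self):
        y = (np.random.default_rng(2).random(80) < 0.3).astype(int)
        folds = stratified_kfold(y, k=3, seed=1)
        assert set(folds) == {0, 1, 2}
        assert len(folds) == 80

    def test_too_few_cases_raises(self):
        y = np.array([1] * 2 + [0] * 50)
        with pytest.raises(StratificationError):
            stratified_kfold(y, k=3, seed=0)


class TestWideCandidates:
    def test_one_hot_drops_reference_level(self, small_cohort):
        records = list(small_cohort.patients)
        _, names = build_wide_candidates(records, (3, 10))
        sexes = sorted({p.sex for p in records})
        assert f"sex_{sexes[0]}" not in names
        assert f"sex_{sexes[1]}" in names

    def test_code_indicators_respect_window(self, small_cohort):
        records = list(small_cohort.patients)
        X, names = build_wide_candidates(records, (3, 10))
        if "dx_Z23" in names:
            j = names.index("dx_Z23")
            for i, p in enumerate(records):
                expected = float(any(3 <= d.age < 10 and d.code == "Z23" for d in p.diagnoses))
                assert X[i, j] == expected
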