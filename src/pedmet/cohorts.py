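"""Observation-window enumeration, cohort assembly and wide-feature selection.

An observation window [s, e) is an integer age range supplying predictor
data; the prediction window runs from the outcome's mean onset age to 18.
All integer windows with 2 <= s < e <= floor(mean onset age) are candidates,
and any assembled cohort with fewer than 20 surviving patients is dropped.

Wide (scalar) features are one-hot demographics plus ever/never ICD-code
indicators within the window.  Selection is two-stage: univariable logistic
association screening with Benjamini-Hochberg control (q < 0.05), then an
L1-penalized logistic path with the one-standard-error rule on 3-fold
cross-validated deviance.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .growth import GrowthReference
from .phenotype import Label, passes_inclusion
from .records import PatientRecord, PatientSet
from .trajectories import harmonize_bmi, truncate_for_outcome, visit_trajectory

__all__ = [
    "WindowSpec",
    "CohortDataset",
    "StratificationError",
    "enumerate_windows",
    "build_wide_candidates",
    "assemble_cohort",
    "association_screen",
    "lasso_select",
    "stratified_split",
    "stratified_kfold",
]

MIN_COHORT_SIZE = 20
FDR_THRESHOLD = 0.05


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    outcome: str
    start_age: int
    end_age: int
    prediction_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.start_age < self.end_age:
            raise ValueError("start_age must be < end_age")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start_age, self.end_age)

    @property
    def length(self) -> int:
        return self.end_age - self.start_age


@dataclasses.dataclass
class CohortDataset:
    """Model-ready data for one (outcome, window) pair.

    ``trajectory_tensor`` has shape (patients, years, 2) with channel 0 the
    harmonized BMI and channel 1 the per-year distinct-day visit count.
    """

    trajectory_tensor: np.ndarray
    wide_matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    window: WindowSpec
    patient_ids: list[str]
    channels: tuple[str, str] = ("bmi", "visits")

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        if not (
            self.trajectory_tensor.shape[0] == self.wide_matrix.shape[0] == len(self.labels) == n
        ):
            raise ValueError("rows of tensor, wide matrix, labels and ids must align")
        if self.trajectory_tensor.shape[1] != self.window.length:
            raise ValueError("tensor year dimension must equal window length")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def subset_features(self, names: list[str]) -> "CohortDataset":
        idx = [self.feature_names.index(n) for n in names]
        return dataclasses.replace(
            self, wide_matrix=self.wide_matrix[:, idx], feature_names=list(names)
        )


class StratificationError(ValueError):
    """A stratum is too small to split as requested."""


def enumerate_windows(onset_mean: float, outcome: str = "outcome") -> list[WindowSpec]:
    """All integer observation windows [s, e) with 2 <= s < e <= floor(onset_mean),
    ordered by (s, e).  The count is C(floor(onset_mean) - 1, 2)."""
    if onset_mean <= 3:
        raise ValueError(
            f"no valid observation window: mean onset age {onset_mean} leaves no room above age 2"
        )
    emax = math.floor(onset_mean)
    pred = (float(onset_mean), 18.0)
    return [
        WindowSpec(outcome, s, e, pred) for s in range(2, emax) for e in range(s + 1, emax + 1)
    ]


def build_wide_candidates(
    records: list[PatientRecord], window: tuple[int, int], min_code_count: int = 5
) -> tuple[np.ndarray, list[str]]:
    """Candidate scalar features: one-hot demographics (first level is the
    reference) and ever/never ICD indicators within the window."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for attr in ("sex", "race", "insurance"):
        levels = sorted({getattr(p, attr) for p in records})
        for level in levels[1:]:  # first level = reference
            cols.append(np.array([float(getattr(p, attr) == level) for p in records]))
            names.append(f"{attr}_{level}")
    s, e = window
    code_sets = [
        {d.code for d in p.diagnoses if s <= d.age < e} for p in records
    ]
    counts: dict[str, int] = {}
    for cs in code_sets:
        for c in cs:
            counts[c] = counts.get(c, 0) + 1
    for code in sorted(c for c, k in counts.items() if k >= min_code_count):
        cols.append(np.array([float(code in cs) for cs in code_sets]))
        names.append(f"dx_{code}")
    matrix = np.column_stack(cols) if cols else np.zeros((len(records), 0))
    return matrix, names


def assemble_cohort(
    pset: PatientSet,
    labels: dict[str, Label],
    window: WindowSpec,
    ref: GrowthReference,
    onset_mean: float,
    selected_features: list[str] | None = None,
    min_size: int = MIN_COHORT_SIZE,
) -> CohortDataset | None:
    """Assemble the model-ready dataset for one window, or None when dropped.

    A patient survives when they pass the inclusion and activity filters,
    their record truncated at the outcome cutoff still yields a BMI
    trajectory covering the window, and they have a label.
    """
    kept: list[tuple] = []  # (truncated record, (bmi traj, visit traj), label)
    for p in pset:
        lab = labels.get(p.patient_id)
        if lab is None or not passes_inclusion(p, ref):
            continue
        truncated = truncate_for_outcome(p, lab, onset_mean)
        bmi_traj = harmonize_bmi(truncated, window.window)
        if bmi_traj is None:
            continue
        visits = visit_trajectory(truncated, window.window)
        kept.append((truncated, (bmi_traj, visits), lab.is_case))
    if len(kept) < min_size:
        return None
    records = [k[0] for k in kept]
    tensor = np.stack(
        [np.column_stack([bmi.values, vis.values]) for _, (bmi, vis), _ in kept]
    )
    wide, names = build_wide_candidates(records, window.window)
    y = np.array([k[2] for k in kept], dtype=int)
    ds = CohortDataset(
        trajectory_tensor=tensor,
        wide_matrix=wide,
        labels=y,
        feature_names=names,
        window=window,
        patient_ids=[r.patient_id for r in records],
    )
    if selected_features is not None:
        ds = ds.subset_features(selected_features)
    return ds


def _univariable_logit_p(x: np.ndarray, y: np.ndarray) -> float:
    """Wald p-value for one feature in a univariable logistic model, with a
    likelihood-ratio fallback when the fit separates or fails to converge."""
    if np.ptp(x) == 0:
        return 1.0  # constant feature carries no association by convention
    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if fit.mle_retvals.get("converged", False) and np.all(np.isfinite(fit.bse)) and fit.bse[1] < 1e3:
            return float(fit.pvalues[1])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        pass
    # fallback: likelihood-ratio test, robust under (quasi-)separation
    p0 = max(min(y.mean(), 1 - 1e-12), 1e-12)
    ll0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0)))
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000)
    clf.fit(x[:, None], y)
    prob = np.clip(clf.predict_proba(x[:, None])[:, 1], 1e-12, 1 - 1e-12)
    ll1 = float(np.sum(y * np.log(prob) + (1 - y) * np.log1p(-prob)))
    lr = max(0.0, 2.0 * (ll1 - ll0))
    return float(stats.chi2.sf(lr, df=1))


def association_screen(
    wide_matrix: np.ndarray, labels: np.ndarray, feature_names: list[str]
) -> dict[str, float]:
    """Per-feature BH-adjusted p-values (q-values) from univariable logistic
    association tests.  Features with q < 0.05 pass the screen."""
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("association screening requires both classes present")
    pvals = np.array(
        [_univariable_logit_p(wide_matrix[:, j], y) for j in range(wide_matrix.shape[1])]
    )
    if len(pvals) == 0:
        return {}
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return dict(zip(feature_names, (float(q) for q in qvals)))


def _binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log1p(-prob)))


def lasso_select(
    wide_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    folds: int = 3,
    seed: int = 0,
    n_lambdas: int = 30,
) -> list[str]:
    """L1-penalized logistic selection with the one-standard-error rule.

    Fits the regularization path, picks the largest penalty whose
    cross-validated deviance is within one standard error of the minimum, and
    returns the features with nonzero coefficients there.  An empty subset is
    a valid result.
    """
    X = np.asarray(wide_matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[1] == 0:
        return []
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd_safe
    n = len(y)
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n_lambdas)

    fold_assign = stratified_kfold(y, k=folds, seed=seed)
    dev = np.zeros((folds, n_lambdas))
    for f in range(folds):
        tr, va = fold_assign != f, fold_assign == f
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise StratificationError("a cross-validation fold contains a single class")
        for j, lam in enumerate(lambdas):
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (lam * tr.sum()), solver="liblinear", max_iter=500
            )
            clf.fit(Xs[tr], y[tr])
            dev[f, j] = _binomial_deviance(y[va], clf.predict_proba(Xs[va])[:, 1])
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(mean_dev))
    threshold = mean_dev[j_min] + se_dev[j_min]
    j_1se = int(np.argmax(mean_dev <= threshold))  # largest lambda within 1 SE
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lambdas[j_1se] * n), solver="liblinear", max_iter=500
    )
    clf.fit(Xs, y)
    coef = clf.coef_.ravel()
    return [name for name, c in zip(feature_names, coef) if abs(c) > 1e-8]


def select_wide_features(
    wide_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    fdr: float = FDR_THRESHOLD,
) -> tuple[list[str], dict[str, float]]:
    """Screen (BH q < fdr) then select (LASSO, 1-SE rule).  Returns the kept
    feature names and the full q-value map for the selection report."""
    qvals = association_screen(wide_matrix, labels, feature_names)
    passing = [n for n in feature_names if qvals.get(n, 1.0) < fdr]
    if not passing:
        return [], qvals
    idx = [feature_names.index(n) for n in passing]
    kept = lasso_select(wide_matrix[:, idx], labels, passing, seed=seed)
    return kept, qvals


def stratified_split(
    labels: np.ndarray, train_frac: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified index split; per-stratum allocation is exact
    to the nearest patient."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) >= 2 else n_train
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def stratified_kfold(labels: np.ndarray, k: int = 3, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) preserving class proportions; every stratum
    must have at least k members."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise StratificationError(
                f"stratum {cls!r} has {len(idx)} members, fewer than k={k} folds"
            )
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % k
    return assign
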