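"""Evaluation protocol and model comparison statistics.

Each (outcome, window, model) combination is evaluated by repeating, with a
fresh stratified 80/20 split per iteration: hyperparameter tuning on 20% of
the training set, stratified 3-fold cross-validation on the training set
(mean CV AUC recorded, out-of-fold scores pooled to optimize the decision
threshold by Youden's J), a final fit, and test-set AUC / sensitivity /
specificity at the frozen threshold.  Ten iterations by default, medians
reported.

Model comparison across windows uses the tie-corrected Friedman rank test
with the Nemenyi critical distance; longitudinal-versus-recent-BMI
comparisons use paired percent improvements and the Wilcoxon signed-rank
test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohorts import CohortDataset, stratified_kfold, stratified_split
from .models import (
    ModelConfig,
    TrainedModel,
    _rows,
    build_model,
    hyperparameter_search,
    predict_proba,
    train,
)

__all__ = [
    "ProtocolResult",
    "roc_auc",
    "optimize_threshold",
    "sensitivity_specificity",
    "run_protocol",
    "friedman_compare",
    "nemenyi_critical_distance",
    "longitudinal_vs_recent",
]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random case outscores a random control, ties counted 1/2."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def optimize_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J (sensitivity + specificity - 1).

    Candidates are midpoints between consecutive distinct scores (a score at
    or above the threshold is called positive); among ties the larger
    threshold — higher specificity — wins.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold optimization requires both classes")
    uniq = np.unique(s)
    if len(uniq) == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_j = candidates[0], -np.inf
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    for t in candidates:
        call = s >= t
        j = (call & (y == 1)).sum() / n_pos + (~call & (y == 0)).sum() / n_neg - 1.0
        if j > best_j - 1e-12 and (j > best_j + 1e-12 or t > best_t):
            best_j, best_t = max(best_j, j), t
    return float(best_t)


def sensitivity_specificity(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    s, y = np.asarray(scores, dtype=float), np.asarray(labels)
    call = s >= threshold
    sens = float((call & (y == 1)).sum() / max((y == 1).sum(), 1))
    spec = float((~call & (y == 0)).sum() / max((y == 0).sum(), 1))
    return sens, spec


@dataclasses.dataclass
class ProtocolResult:
    """Per-iteration metrics and their medians for one window and model."""

    window: object
    kind: str
    iterations: list[dict]

    @property
    def median_test_auc(self) -> float:
        return float(np.median([it["test_auc"] for it in self.iterations]))

    @property
    def median_sensitivity(self) -> float:
        return float(np.median([it["sensitivity"] for it in self.iterations]))

    @property
    def median_specificity(self) -> float:
        return float(np.median([it["specificity"] for it in self.iterations]))

    @property
    def mean_cv_auc(self) -> float:
        return float(np.mean([it["cv_auc"] for it in self.iterations]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.iterations)
        df.insert(0, "model", self.kind)
        df.insert(0, "window", f"[{self.window.start_age},{self.window.end_age})"
                  if hasattr(self.window, "start_age") else str(self.window))
        return df

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["test_auc", "sensitivity", "specificity", "cv_auc"],
                "median": [
                    self.median_test_auc,
                    self.median_sensitivity,
                    self.median_specificity,
                    float(np.median([it["cv_auc"] for it in self.iterations])),
                ],
                "mean": [
                    float(np.mean([it["test_auc"] for it in self.iterations])),
                    float(np.mean([it["sensitivity"] for it in self.iterations])),
                    float(np.mean([it["specificity"] for it in self.iterations])),
                    self.mean_cv_auc,
                ],
            }
        )


def run_protocol(
    dataset: CohortDataset,
    config: ModelConfig,
    iterations: int = 10,
    base_seed: int = 0,
    tune_budget: int = 1,
    cv_folds: int = 3,
) -> ProtocolResult:
    """Run the full train/validate/test protocol on one cohort dataset.

    ``tune_budget`` > 1 enables random hyperparameter search on a tuning
    split carved from the training ids; with budget 1 the given config is
    used as-is (the search would return its single sample anyway).
    """
    results = []
    n_ch = dataset.trajectory_tensor.shape[2]
    n_wide = dataset.wide_matrix.shape[1]
    for it in range(iterations):
        seed = base_seed + it
        train_idx, test_idx = stratified_split(dataset.labels, 0.8, seed=seed)
        cfg = dataclasses.replace(config, seed=seed)
        if tune_budget > 1:
            cfg = hyperparameter_search(dataset, train_idx, cfg, budget=tune_budget, seed=seed)

        y_train = dataset.labels[train_idx]
        folds = stratified_kfold(y_train, k=cv_folds, seed=seed)
        cv_aucs, oof_scores, oof_labels = [], [], []
        for f in range(cv_folds):
            tr = train_idx[folds != f]
            va = train_idx[folds == f]
            fitted = train(
                build_model(cfg, dataset.window.length, n_ch, n_wide), _rows(dataset, tr), cfg
            )
            s = predict_proba(fitted, dataset.trajectory_tensor[va], dataset.wide_matrix[va])
            cv_aucs.append(roc_auc(s, dataset.labels[va]))
            oof_scores.append(s)
            oof_labels.append(dataset.labels[va])
        threshold = optimize_threshold(np.concatenate(oof_scores), np.concatenate(oof_labels))

        final = train(
            build_model(cfg, dataset.window.length, n_ch, n_wide), _rows(dataset, train_idx), cfg
        )
        test_scores = predict_proba(
            final, dataset.trajectory_tensor[test_idx], dataset.wide_matrix[test_idx]
        )
        auc = roc_auc(test_scores, dataset.labels[test_idx])
        sens, spec = sensitivity_specificity(test_scores, dataset.labels[test_idx], threshold)
        results.append(
            {
                "iteration": it,
                "cv_auc": float(np.mean(cv_aucs)),
                "test_auc": auc,
                "sensitivity": sens,
                "specificity": spec,
                "threshold": threshold,
            }
        )
    return ProtocolResult(dataset.window, config.kind, results)


def friedman_compare(auc_table: np.ndarray, model_names: list[str] | None = None):
    """Tie-corrected Friedman test on a (models x windows) AUC table.

    Windows are blocks; within each block models are ranked 1 = best (highest
    AUC), with average ranks on ties.  Returns (statistic, p-value, mean rank
    per model); lower mean rank is better.
    """
    table = np.asarray(auc_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 models and >= 2 windows")
    if np.isnan(table).any():
        raise ValueError("incomplete block design: missing cells")
    k, n = table.shape
    ranks = np.empty_like(table)
    tie_sum = 0.0
    for j in range(n):
        ranks[:, j] = stats.rankdata(-table[:, j])  # 1 = best AUC
        _, counts = np.unique(table[:, j], return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    r_sum = ranks.sum(axis=1)
    statistic = 12.0 / (n * k * (k + 1)) * np.sum(r_sum**2) - 3.0 * n * (k + 1)
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = statistic / correction
        p = float(stats.chi2.sf(statistic, df=k - 1))
    mean_ranks = ranks.mean(axis=1)
    if model_names is not None:
        mean_ranks = dict(zip(model_names, (float(r) for r in mean_ranks)))
    return float(statistic), float(p), mean_ranks


# two-tailed Studentized-range q(alpha=0.05) / sqrt(2) for the Nemenyi test
_NEMENYI_Q05 = {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850, 7: 2.949,
                8: 3.031, 9: 3.102, 10: 3.164}


def nemenyi_critical_distance(k: int, n: int, alpha: float = 0.05) -> float:
    """Critical mean-rank distance at alpha=0.05 for k models over n windows."""
    if alpha != 0.05:
        raise ValueError("only alpha=0.05 is tabulated")
    if k not in _NEMENYI_Q05:
        raise ValueError(f"k={k} outside tabulated range 2..10")
    return float(_NEMENYI_Q05[k] * np.sqrt(k * (k + 1) / (6.0 * n)))


def critical_difference_plot(mean_ranks: dict[str, float], cd: float, path: str) -> None:
    """Minimal critical-difference display: mean ranks on a number line with
    the CD bar; lower rank is better."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 2 + 0.3 * len(mean_ranks)))
    items = sorted(mean_ranks.items(), key=lambda kv: kv[1])
    for i, (name, rank) in enumerate(items):
        ax.plot(rank, i, "o", color="k")
        ax.annotate(f" {name} ({rank:.2f})", (rank, i), va="center")
    lo = min(r for _, r in items)
    ax.plot([lo, lo + cd], [-0.7, -0.7], lw=3, color="tab:red")
    ax.annotate(f"CD = {cd:.2f}", (lo, -1.0), color="tab:red")
    ax.set_yticks([])
    ax.set_xlabel("mean rank (lower is better)")
    ax.set_ylim(-1.5, len(items))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def longitudinal_vs_recent(
    protocols_traj: list[ProtocolResult], protocols_recent: list[ProtocolResult]
) -> tuple[float, np.ndarray, float]:
    """Paired comparison of trajectory-based vs most-recent-BMI models.

    Pairs per-iteration test AUCs across identical windows; returns the
    median percent improvement 100*(AUC_traj - AUC_recent)/AUC_recent, the
    array of paired improvements, and the one-sided Wilcoxon signed-rank
    p-value (alternative: trajectory better).
    """
    by_window = {str(p.window): p for p in protocols_recent}
    imps = []
    for pt in protocols_traj:
        pr = by_window.get(str(pt.window))
        if pr is None:
            raise ValueError(f"window {pt.window} missing from recent-BMI protocols")
        for a, b in zip(pt.iterations, pr.iterations):
            imps.append(100.0 * (a["test_auc"] - b["test_auc"]) / b["test_auc"])
    if len(imps) != sum(len(p.iterations) for p in protocols_recent):
        raise ValueError("window sets do not pair one-to-one")
    imps = np.asarray(imps)
    if np.allclose(imps, 0.0):
        return 0.0, imps, 1.0
    res = stats.wilcoxon(imps, alternative="greater")
    return float(np.median(imps)), imps, float(res.pvalue)
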