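"""Shapley-value explanations for trajectory + scalar classifiers.

Attributions are estimated by permutation sampling on the probability scale:
for each sampled feature ordering and background row, features are switched
one at a time from the background value to the instance value, and each
feature's marginal change in predicted probability is averaged over
orderings.  Because every ordering telescopes from the background prediction
to the instance prediction, the attributions plus the base value (the mean
background prediction) sum to the prediction exactly, up to float error.

Trajectory positions are features too: position ``t`` of channel ``bmi``
appears as ``bmi_t{t}``, and a channel's per-patient importance is the
largest absolute attribution over its positions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .models import TrainedModel, predict_proba

__all__ = [
    "Explanation",
    "shapley_attributions",
    "shap_explain",
    "trajectory_importance",
    "global_importance",
    "patient_report",
]

ADDITIVITY_TOL = 1e-3


def shapley_attributions(
    predict,
    instance: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley values for one flat instance.

    ``predict`` maps an (n, d) array to n scalars.  For each sampled ordering
    a background row is morphed into the instance one feature at a time; the
    marginal prediction changes, averaged over orderings, estimate each
    feature's Shapley value.  Returns (attributions, base value); the
    attributions sum to ``predict(instance) - base`` exactly (telescoping),
    so additivity holds up to float error.
    """
    rng = rng or np.random.default_rng(0)
    x = np.asarray(instance, dtype=float)
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.shape[0]
    n_bg = len(bg)
    phi = np.zeros(d)
    base = None
    for _ in range(n_permutations):
        order = rng.permutation(d)
        # mask[s, j]: after s steps of this ordering, feature j is the instance's
        mask = np.zeros((d + 1, d), dtype=bool)
        for step, j in enumerate(order):
            mask[step + 1] = mask[step]
            mask[step + 1, j] = True
        # every path point evaluated against the full background (Rao-Blackwell
        # over the background instead of pairing one row per permutation)
        paths = np.where(mask[None, :, :], x[None, None, :], bg[:, None, :])
        preds = predict(paths.reshape(-1, d)).reshape(n_bg, d + 1).mean(axis=0)
        phi[order] += preds[1:] - preds[:-1]
        if base is None:
            base = preds[0]
    return phi / n_permutations, float(base)


@dataclasses.dataclass
class Explanation:
    patient_id: str
    base_value: float
    contributions: dict[str, float]
    prediction: float
    threshold: float

    @property
    def call(self) -> str:
        return "positive" if self.prediction >= self.threshold else "negative"

    def additivity_gap(self) -> float:
        return abs(self.base_value + sum(self.contributions.values()) - self.prediction)


def _feature_names(model: TrainedModel, channels: tuple[str, ...]) -> list[str]:
    names = [
        f"{ch}_t{t}" for ch in channels[: model.n_channels] for t in range(model.window_length)
    ]
    return names + list(model.feature_names)


def _flatten(traj: np.ndarray, wide: np.ndarray) -> np.ndarray:
    # channel-major to match _feature_names: all bmi positions, then visits, then wide
    n, T, C = traj.shape
    return np.hstack([traj.transpose(0, 2, 1).reshape(n, C * T), wide])


def _unflatten(flat: np.ndarray, T: int, C: int) -> tuple[np.ndarray, np.ndarray]:
    n = flat.shape[0]
    traj = flat[:, : C * T].reshape(n, C, T).transpose(0, 2, 1)
    return traj, flat[:, C * T :]


def shap_explain(
    model: TrainedModel,
    trajectory_tensor: np.ndarray,
    wide_matrix: np.ndarray,
    background: tuple[np.ndarray, np.ndarray],
    threshold: float = 0.5,
    patient_ids: list[str] | None = None,
    n_permutations: int = 20,
    max_background: int = 100,
    seed: int = 0,
    channels: tuple[str, ...] = ("bmi", "visits"),
) -> list[Explanation]:
    """Per-instance Shapley attributions over trajectory positions and wide
    features, on the probability scale.

    ``background`` is (trajectory_tensor, wide_matrix) drawn from training
    data; at most ``max_background`` rows are used (subsampled with the seed).
    """
    bg_traj, bg_wide = background
    if len(bg_traj) == 0:
        raise ValueError("background set must be nonempty")
    rng = np.random.default_rng(seed)
    if len(bg_traj) > max_background:
        keep = rng.choice(len(bg_traj), size=max_background, replace=False)
        bg_traj, bg_wide = bg_traj[keep], bg_wide[keep]

    names = _feature_names(model, channels)
    d = len(names)
    T, C = model.window_length, model.n_channels
    bg_flat = _flatten(np.asarray(bg_traj, dtype=float), np.asarray(bg_wide, dtype=float))
    inst_flat = _flatten(
        np.asarray(trajectory_tensor, dtype=float), np.asarray(wide_matrix, dtype=float)
    )

    def f(flat_rows: np.ndarray) -> np.ndarray:
        traj, wide = _unflatten(flat_rows, T, C)
        return predict_proba(model, traj, wide)

    explanations = []
    for i, x in enumerate(inst_flat):
        phi, base = shapley_attributions(f, x, bg_flat, n_permutations, rng)
        pid = patient_ids[i] if patient_ids is not None else f"instance_{i}"
        explanations.append(
            Explanation(
                patient_id=pid,
                base_value=base,
                contributions=dict(zip(names, (float(v) for v in phi))),
                prediction=float(f(x[None, :])[0]),
                threshold=threshold,
            )
        )
    return explanations


def trajectory_importance(explanation: Explanation, channel: str) -> tuple[float, int]:
    """Max absolute attribution over the channel's positions, with its
    position (earliest on ties)."""
    prefix = f"{channel}_t"
    vals = {
        int(k[len(prefix):]): v
        for k, v in explanation.contributions.items()
        if k.startswith(prefix) and k[len(prefix):].isdigit()
    }
    if not vals:
        raise KeyError(f"channel {channel!r} not present in explanation")
    best_pos = min(vals, key=lambda p: (-abs(vals[p]), p))
    return abs(vals[best_pos]), best_pos


def global_importance(
    explanations: list[Explanation], channels: tuple[str, ...] = ("bmi", "visits")
) -> pd.DataFrame:
    """Mean absolute attribution per feature pooled over samples (and
    windows), trajectory channels first reduced per patient to their max
    absolute position.  Descending order."""
    if not explanations:
        raise ValueError("need at least one explanation")
    rows: dict[str, list[float]] = {}
    for ex in explanations:
        present = set()
        for ch in channels:
            try:
                imp, _ = trajectory_importance(ex, ch)
            except KeyError:
                continue
            rows.setdefault(f"{ch}_trajectory", []).append(imp)
            present.add(ch)
        for name, v in ex.contributions.items():
            if any(name.startswith(f"{ch}_t") and name[len(ch) + 2:].isdigit() for ch in present):
                continue
            rows.setdefault(name, []).append(abs(v))
    table = pd.DataFrame(
        {"feature": list(rows), "mean_abs_shap": [float(np.mean(v)) for v in rows.values()]}
    )
    return table.sort_values("mean_abs_shap", ascending=False, ignore_index=True)


def patient_report(explanation: Explanation) -> dict:
    """Structured per-patient decision report: contributions sorted by
    magnitude with direction, the prediction, threshold and call."""
    contribs = sorted(explanation.contributions.items(), key=lambda kv: -abs(kv[1]))
    table = pd.DataFrame(
        {
            "feature": [k for k, _ in contribs],
            "shap_value": [v for _, v in contribs],
            "direction": [
                "risk-increasing" if v > 0 else ("risk-decreasing" if v < 0 else "neutral")
                for _, v in contribs
            ],
        }
    )
    return {
        "patient_id": explanation.patient_id,
        "prediction": explanation.prediction,
        "threshold": explanation.threshold,
        "call": explanation.call,
        "base_value": explanation.base_value,
        "contributions": table,
    }


def beeswarm_plot(explanations: list[Explanation], path: str, top: int = 15) -> None:
    """Summary plot: per-feature attribution spread across patients."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = global_importance(explanations)["feature"].tolist()[:top]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(order) + 1.5))
    rng = np.random.default_rng(0)
    for i, feat in enumerate(reversed(order)):
        if feat.endswith("_trajectory"):
            ch = feat[: -len("_trajectory")]
            vals = []
            for ex in explanations:
                imp, pos = trajectory_importance(ex, ch)
                vals.append(ex.contributions[f"{ch}_t{pos}"])
        else:
            vals = [ex.contributions.get(feat, 0.0) for ex in explanations]
        ax.scatter(vals, i + rng.uniform(-0.15, 0.15, len(vals)), s=8, alpha=0.6)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(list(reversed(order)))
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("attribution (probability scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
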