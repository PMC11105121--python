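"""Harmonize irregular longitudinal records into uniform per-year trajectories.

Visit ages are irregular, so trajectories are partitioned into disjoint
half-open one-year age segments [y, y+1).  Each segment's BMI is the mean of
all BMIs recorded within it; interior empty segments are filled by linear
interpolation between the nearest observed segment means.  No extrapolation:
a patient whose records do not bracket the observation window is excluded
(``harmonize_bmi`` returns None).  The visit channel counts distinct
encounter days per year, with genuine zeros for contact-free years.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .growth import compute_bmi
from .phenotype import Label
from .records import PatientRecord

__all__ = [
    "HarmonizedTrajectory",
    "harmonize_bmi",
    "visit_trajectory",
    "truncate_for_outcome",
    "NormParams",
    "zscore_fit",
    "zscore_apply",
]

OBSERVED, INTERPOLATED = "observed", "interpolated"


@dataclasses.dataclass
class HarmonizedTrajectory:
    patient_id: str
    window: tuple[int, int]  # [start_age, end_age)
    values: np.ndarray  # one value per year
    observed_mask: np.ndarray  # bool, True where a record was observed
    channel: str  # "bmi" or "visits"

    def __post_init__(self) -> None:
        s, e = self.window
        if len(self.values) != e - s or len(self.observed_mask) != e - s:
            raise ValueError("trajectory length must equal window length")


def _segment_means(patient: PatientRecord) -> dict[int, float]:
    seg: dict[int, list[float]] = {}
    for m in patient.measurements:
        seg.setdefault(math.floor(m.age), []).append(compute_bmi(m.weight_kg, m.height_cm))
    return {y: float(np.mean(v)) for y, v in seg.items()}


def harmonize_bmi(patient: PatientRecord, window: tuple[int, int]) -> HarmonizedTrajectory | None:
    """Per-year BMI over ``window`` = [s, e), or None when not covering.

    A record at an integer age belongs to the segment it starts (half-open
    convention).  Coverage requires an observed segment at or before the
    window's first year and at or after its last year; interior gaps are
    linearly interpolated in segment index.
    """
    s, e = window
    if not (isinstance(s, (int, np.integer)) and isinstance(e, (int, np.integer))):
        raise TypeError("window bounds must be integers")
    if not (2 <= s < e):
        raise ValueError(f"window must satisfy 2 <= s < e, got [{s}, {e})")
    seg = _segment_means(patient)
    if not seg:
        return None
    observed_years = sorted(seg)
    if observed_years[0] > s or observed_years[-1] < e - 1:
        return None  # not covering: would require extrapolation
    xs = np.array(observed_years, dtype=float)
    ys = np.array([seg[y] for y in observed_years], dtype=float)
    years = np.arange(s, e)
    values = np.interp(years.astype(float), xs, ys)
    mask = np.array([y in seg for y in years], dtype=bool)
    # exact segment means where observed (interp already returns them at nodes)
    return HarmonizedTrajectory(patient.patient_id, (int(s), int(e)), values, mask, "bmi")


def visit_trajectory(patient: PatientRecord, window: tuple[int, int]) -> HarmonizedTrajectory:
    """Per-year count of distinct encounter days in ``window``; empty years are 0."""
    s, e = window
    if not (2 <= s < e):
        raise ValueError(f"window must satisfy 2 <= s < e, got [{s}, {e})")
    days: dict[int, set[int]] = {}
    for age in patient.encounters:
        y = math.floor(age)
        if s <= y < e:
            days.setdefault(y, set()).add(int(round(age * 365.25)))
    years = np.arange(s, e)
    counts = np.array([len(days.get(int(y), ())) for y in years], dtype=float)
    mask = counts > 0
    return HarmonizedTrajectory(patient.patient_id, (int(s), int(e)), counts, mask, "visits")


def truncate_for_outcome(
    patient: PatientRecord, label: Label, onset_mean: float
) -> PatientRecord:
    """Drop all events at or after the truncation age.

    Controls are truncated at the cohort's mean onset age; cases additionally
    at their own diagnosis age, whichever comes first.
    """
    cutoff = onset_mean
    if label.is_case and label.onset_age is not None:
        cutoff = min(cutoff, label.onset_age)
    return dataclasses.replace(
        patient,
        measurements=[m for m in patient.measurements if m.age < cutoff],
        encounters=[a for a in patient.encounters if a < cutoff],
        diagnoses=[d for d in patient.diagnoses if d.age < cutoff],
        labs=[lab for lab in patient.labs if lab.age < cutoff],
        medications=[m for m in patient.medications if m.age < cutoff],
    )


@dataclasses.dataclass
class NormParams:
    """Per-column mean and population SD learned from training rows only."""

    mean: np.ndarray
    sd: np.ndarray


def zscore_fit(train_matrix: np.ndarray) -> NormParams:
    x = np.asarray(train_matrix, dtype=float)
    return NormParams(mean=x.mean(axis=0), sd=x.std(axis=0))  # population SD (ddof=0)


def zscore_apply(matrix: np.ndarray, params: NormParams) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if x.shape[-1] != params.mean.shape[0]:
        raise ValueError(
            f"column count mismatch: matrix has {x.shape[-1]}, params expect {params.mean.shape[0]}"
        )
    safe_sd = np.where(params.sd == 0, 1.0, params.sd)
    z = (x - params.mean) / safe_sd
    z[..., params.sd == 0] = 0.0  # constant columns carry no information
    return z
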