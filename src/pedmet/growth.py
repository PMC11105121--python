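"""Pediatric anthropometry: BMI, LMS growth references, weight classes.

The LMS method summarises a growth reference by three age- and sex-specific
parameters: the Box-Cox power ``L``, the median ``M`` and the coefficient of
variation ``S``.  A measurement ``X`` converts to a standard-normal deviate

    z = ((X / M)**L - 1) / (L * S)    (L != 0)
    z = ln(X / M) / S                 (L == 0)

and the percentile is ``100 * Phi(z)``.  Weight classes follow the CDC
cut-points on the BMI-for-age percentile (underweight < 5th, normal 5th-85th,
overweight 85th-95th, obesity >= 95th) with severe obesity defined as
BMI >= 120% of the 95th-percentile BMI.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GrowthReference",
    "compute_bmi",
    "bmi_percentile",
    "weight_class",
    "load_reference",
]

WEIGHT_CLASSES = ("underweight", "normal", "overweight", "obesity", "severe_obesity")

#: fraction of the 95th-percentile BMI defining severe obesity
SEVERE_OBESITY_FACTOR = 1.2


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m^2 from weight in kg and height in cm."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError(
            f"weight and height must be positive, got weight={weight_kg}, height={height_cm}"
        )
    return weight_kg / (height_cm / 100.0) ** 2


@dataclasses.dataclass(frozen=True)
class GrowthReference:
    """A BMI-for-age LMS table indexed by sex and age in months.

    ``entries`` holds columns ``sex`` (male/female), ``agemos``, ``L``, ``M``,
    ``S``.  Lookups linearly interpolate L, M and S at the requested age.
    Any table in the CDC file layout can be loaded with :func:`load_reference`;
    the bundled default is a synthetic table with the same shape and realistic
    magnitudes, not the measured CDC reference.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "agemos", "L", "M", "S"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"growth reference missing columns: {sorted(missing)}")
        if (self.entries["M"] <= 0).any() or (self.entries["S"] <= 0).any():
            raise ValueError("growth reference requires M > 0 and S > 0")
        for sex, grp in self.entries.groupby("sex"):
            if not grp["agemos"].is_monotonic_increasing or grp["agemos"].duplicated().any():
                raise ValueError(f"ages must be strictly increasing within sex {sex!r}")

    def _arrays(self, sex: str) -> dict[str, np.ndarray]:
        cache = self.__dict__.setdefault("_sex_arrays", {})
        if sex not in cache:
            grp = self.entries[self.entries["sex"] == sex]
            if grp.empty:
                raise KeyError(f"sex {sex!r} not in growth reference")
            cache[sex] = {c: grp[c].to_numpy(dtype=float) for c in ("agemos", "L", "M", "S")}
        return cache[sex]

    def age_range_months(self, sex: str) -> tuple[float, float]:
        a = self._arrays(sex)["agemos"]
        return float(a[0]), float(a[-1])

    def lms(self, age_years: float, sex: str) -> tuple[float, float, float]:
        """Interpolated (L, M, S) at ``age_years`` for ``sex``."""
        arr = self._arrays(sex)
        agemos = age_years * 12.0
        lo, hi = arr["agemos"][0], arr["agemos"][-1]
        if not (lo <= agemos <= hi):
            raise ValueError(
                f"age {age_years:.2f} y outside reference coverage "
                f"[{lo / 12:.2f}, {hi / 12:.2f}] y for sex {sex!r}"
            )
        x = arr["agemos"]
        return tuple(float(np.interp(agemos, x, arr[c])) for c in ("L", "M", "S"))

    def bmi_at_z(self, z: float, age_years: float, sex: str) -> float:
        """Invert the LMS transform: the BMI whose z-score is ``z``."""
        L, M, S = self.lms(age_years, sex)
        if abs(L) < 1e-12:
            return M * float(np.exp(S * z))
        # for L < 0 the transform has a finite asymptote at z = -1/(L*S);
        # clamp just inside it so extreme z maps to an extreme, finite BMI
        base = max(1.0 + L * S * z, 0.05)
        return M * base ** (1.0 / L)

    def p95_bmi(self, age_years: float, sex: str) -> float:
        """The 95th-percentile BMI at this age/sex (severe-obesity anchor)."""
        return self.bmi_at_z(float(norm.ppf(0.95)), age_years, sex)


def bmi_percentile(
    bmi: float, age_years: float, sex: str, ref: GrowthReference
) -> tuple[float, float]:
    """LMS z-score and percentile of a BMI at a given age and sex.

    Returns ``(z, percentile)`` with percentile on the 0-100 scale.
    """
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    L, M, S = ref.lms(age_years, sex)
    if abs(L) < 1e-12:
        z = np.log(bmi / M) / S
    else:
        z = ((bmi / M) ** L - 1.0) / (L * S)
    return float(z), float(norm.cdf(z) * 100.0)


def weight_class(percentile: float, bmi: float | None = None, p95_bmi: float | None = None) -> str:
    """CDC weight class from a BMI percentile (0-100 scale).

    Severe obesity requires ``bmi`` and ``p95_bmi`` and takes precedence over
    plain obesity when ``bmi >= 1.2 * p95_bmi``.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must lie in [0, 100], got {percentile}")
    if bmi is not None and p95_bmi is not None and bmi >= SEVERE_OBESITY_FACTOR * p95_bmi:
        return "severe_obesity"
    if percentile < 5.0:
        return "underweight"
    if percentile < 85.0:
        return "normal"
    if percentile < 95.0:
        return "overweight"
    return "obesity"


def load_reference(path: str | Path | None = None) -> GrowthReference:
    """Load an LMS table (columns sex, agemos, L, M, S) from CSV.

    With no ``path`` the bundled synthetic table is used.  A real CDC
    BMI-for-age file in the same layout drops in unchanged.
    """
    if path is None:
        with resources.files("pedmet").joinpath("data/cdc_lms_synthetic.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return GrowthReference(entries=table)
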