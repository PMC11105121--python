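"""Synthetic pediatric EHR cohorts with known ground truth.

The generator emulates the statistical structure the prediction pipeline
assumes, not any real patient population: irregular visit timing (a renewal
process with optional patient-level rate heterogeneity), age- and
sex-dependent growth (a latent BMI z-score following a random-intercept /
random-slope linear process, mapped to BMI through the LMS growth reference),
sparse diagnosis codes and labs, and an outcome signal carried jointly by
trajectory shape (cases' z-scores drift upward) and by scalar ("wide")
features through a logistic link whose intercept is solved numerically so the
realized prevalence matches the target.

Cases reveal themselves to the pipeline only through emitted diagnoses, labs
and medications after a simulated onset age; the latent indicator is kept on
the PatientSet for tests (:func:`truth_labels`) and never enters the flat
files.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .growth import GrowthReference, load_reference
from .records import Diagnosis, Lab, Measurement, MedicationOrder, PatientRecord, PatientSet

__all__ = ["SimulationConfig", "generate_cohort", "truth_labels", "DEFAULT_WIDE_EFFECTS"]

AGE_START, AGE_END = 2.0, 18.0

#: default log-odds contributions of the scalar risk features
DEFAULT_WIDE_EFFECTS = {
    "dx_obesity": 0.8,
    "dx_weight_gain": 0.6,
    "sex_female": 0.3,
    "insurance_medicaid": 0.5,
    "dx_vaccination": -0.4,
}

# diagnosis codes the wide features are emitted as
_FEATURE_CODES = {
    "dx_obesity": "E66.9",
    "dx_weight_gain": "R63.5",
    "dx_vaccination": "Z23",
}
_FEATURE_BASE_RATES = {
    "dx_obesity": 0.25,
    "dx_weight_gain": 0.10,
    "dx_vaccination": 0.40,
}

# outcome evidence emitted after onset (code / lab / medication per outcome)
_ONSET_EVENTS = {
    "prediabetes": {"code": "R73.03", "lab": ("hba1c", 6.0)},
    "metabolic_syndrome": {"code": "E88.81", "lab": ("tg", 180.0)},
    "t2d": {"code": "E11.9", "lab": ("hba1c", 7.1), "med": "metformin"},
}

# median height (cm) by age in years, used to split BMI into height and weight
_H_AGES = np.array([2, 4, 6, 8, 10, 12, 14, 16, 18], dtype=float)
_H_MALE = np.array([86.5, 102.5, 115.5, 127.5, 138.5, 149.0, 163.0, 173.0, 176.5])
_H_FEMALE = np.array([85.5, 101.5, 115.0, 127.5, 138.5, 151.5, 160.0, 162.5, 163.5])


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 2000
    seed: int = 0
    mean_visits_per_year: float = 2.0
    visit_overdispersion: float = 0.5
    growth_ref: str | None = None  # path to an LMS table; bundled table if None
    outcome: str = "prediabetes"
    target_prevalence: float = 0.10
    traj_signal_effect: float = 0.12  # BMI z-score drift per year for cases
    wide_signal_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_WIDE_EFFECTS)
    )
    missing_year_rate: float = 0.15
    measurement_noise_sd: float = 0.15  # z-score units per measurement
    emission_rate: float = 0.97  # P(case emits outcome evidence)
    false_emission_rate: float = 0.005  # P(control emits outcome evidence)
    dropout_rate: float = 0.05  # P(patient stops visiting early)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError(f"target_prevalence must lie in (0, 1), got {self.target_prevalence}")
        if self.mean_visits_per_year <= 0:
            raise ValueError("mean_visits_per_year must be positive")
        if not 0.0 <= self.missing_year_rate < 1.0:
            raise ValueError("missing_year_rate must lie in [0, 1)")
        if self.visit_overdispersion < 0:
            raise ValueError("visit_overdispersion must be nonnegative")
        if self.outcome not in _ONSET_EVENTS:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def _wide_value(name: str, sex: str, insurance: str, race: str, flags: dict[str, bool]) -> float:
    if name.startswith("dx_"):
        return float(flags.get(name, False))
    if name.startswith("sex_"):
        return float(sex == name.split("_", 1)[1])
    if name.startswith("insurance_"):
        return float(insurance == name.split("_", 1)[1])
    if name.startswith("race_"):
        return float(race == name.split("_", 1)[1])
    raise ValueError(f"unknown wide feature {name!r}")


def generate_cohort(config: SimulationConfig) -> PatientSet:
    """Simulate one cohort; identical config and seed give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref = load_reference(config.growth_ref)

    n = config.n_patients
    sexes = np.where(rng.random(n) < 0.549, "male", "female")
    races = rng.choice(
        ["caucasian", "black", "hispanic", "other"], size=n, p=[0.73, 0.17, 0.06, 0.04]
    )
    insurances = rng.choice(["private", "medicaid", "other"], size=n, p=[0.55, 0.35, 0.10])
    flags = {
        name: rng.random(n) < rate for name, rate in _FEATURE_BASE_RATES.items()
    }

    # linear predictor from the wide features; intercept solved for prevalence
    eta = np.zeros(n)
    for name, effect in config.wide_signal_effects.items():
        vals = np.array(
            [
                _wide_value(name, sexes[i], insurances[i], races[i], {k: v[i] for k, v in flags.items()})
                for i in range(n)
            ]
        )
        eta += effect * vals
    p = config.target_prevalence
    alpha = brentq(lambda a: expit(a + eta).mean() - p, -30.0, 30.0)
    is_case = rng.random(n) < expit(alpha + eta)

    # latent growth process
    z0 = rng.normal(0.85, 0.65, size=n)
    slope = rng.normal(0.015, 0.05, size=n)
    slope = slope + np.where(is_case, config.traj_signal_effect, 0.0)
    height_dev = rng.normal(0.0, 0.03, size=n)
    onset_ages = rng.uniform(9.0, 16.0, size=n)
    dropout = rng.random(n) < config.dropout_rate
    dropout_age = rng.uniform(10.0, 16.0, size=n)

    # per-patient visit rates (gamma-mixed renewal process)
    if config.visit_overdispersion > 0:
        shape = 1.0 / config.visit_overdispersion
        rate_mult = rng.gamma(shape, config.visit_overdispersion, size=n)
    else:
        rate_mult = np.ones(n)
    rates = np.maximum(config.mean_visits_per_year * rate_mult, 0.2)

    width = len(str(n - 1))
    patients: list[PatientRecord] = []
    truth: dict[str, int] = {}
    for i in range(n):
        pid = f"P{i:0{width}d}"
        sex = str(sexes[i])
        rec = PatientRecord(
            patient_id=pid, sex=sex, race=str(races[i]), insurance=str(insurances[i])
        )

        last_age = dropout_age[i] if dropout[i] else AGE_END
        visits = []
        t = AGE_START + rng.exponential(1.0 / rates[i])
        while t < last_age:
            visits.append(t)
            t += rng.exponential(1.0 / rates[i])
        rec.encounters.extend(visits)

        blank_years = {
            y for y in range(int(AGE_START), int(AGE_END)) if rng.random() < config.missing_year_rate
        }
        h_med = _H_MALE if sex == "male" else _H_FEMALE
        for age in visits:
            if rng.random() > 0.9 or math.floor(age) in blank_years:
                continue
            z = z0[i] + slope[i] * (age - AGE_START) + rng.normal(0.0, config.measurement_noise_sd)
            z = float(np.clip(z, -3.0, 3.5))  # keep inside the LMS support
            bmi = ref.bmi_at_z(z, age, sex)
            height = float(np.interp(age, _H_AGES, h_med)) * (1.0 + height_dev[i])
            weight = bmi * (height / 100.0) ** 2
            rec.measurements.append(Measurement(age, height, weight))

        for name, code in _FEATURE_CODES.items():
            if flags[name][i]:
                age = float(rng.uniform(AGE_START, last_age)) if last_age > AGE_START else AGE_START
                rec.diagnoses.append(Diagnosis(age, code))
                rec.encounters.append(age)

        emit = rng.random() < (config.emission_rate if is_case[i] else config.false_emission_rate)
        if emit:
            onset = float(onset_ages[i]) if is_case[i] else float(rng.uniform(9.0, 16.0))
            onset = min(onset, 17.9)
            events = _ONSET_EVENTS[config.outcome]
            rec.diagnoses.append(Diagnosis(onset, events["code"]))
            rec.encounters.append(onset)
            if "lab" in events:
                analyte, value = events["lab"]
                rec.labs.append(Lab(onset, analyte, value * float(rng.uniform(0.98, 1.1))))
            if "med" in events:
                rec.medications.append(MedicationOrder(min(onset + 0.05, 17.95), events["med"]))

        truth[pid] = int(is_case[i])
        patients.append(rec.sorted())

    provenance = {
        "generator": "pedmet.simulate.generate_cohort",
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    return PatientSet(patients=patients, provenance=provenance, truth=truth)


def truth_labels(pset: PatientSet) -> dict[str, int]:
    """The simulator's latent case indicator; for tests and validation only."""
    if pset.truth is None:
        raise ValueError("patient set was not produced by generate_cohort (no latent labels)")
    return dict(pset.truth)
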