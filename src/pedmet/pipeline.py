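"""End-to-end conveniences tying the pipeline stages together."""

from __future__ import annotations

import dataclasses

from .cohorts import CohortDataset, WindowSpec, assemble_cohort
from .growth import load_reference
from .phenotype import label_outcome, load_outcome_definitions
from .records import PatientSet
from .simulate import SimulationConfig, generate_cohort

__all__ = ["label_patient_set", "simulated_window_dataset"]


def label_patient_set(pset: PatientSet, outcome: str, ref=None, definitions=None):
    """Phenotype every patient for one outcome; returns {patient_id: Label}."""
    ref = ref if ref is not None else load_reference()
    defn = (definitions or load_outcome_definitions())[outcome]
    return {p.patient_id: label_outcome(p, defn, ref) for p in pset}, defn


def simulated_window_dataset(
    window: tuple[int, int],
    outcome: str = "prediabetes",
    seed: int = 0,
    n_patients: int = 2000,
    **config_overrides,
) -> CohortDataset | None:
    """Simulate a cohort, phenotype it, and assemble one window dataset.

    Extra keyword arguments override :class:`SimulationConfig` fields.  The
    labels the models see come from the phenotyping rules applied to the
    emitted events, never from the simulator's latent truth.
    """
    cfg = SimulationConfig(n_patients=n_patients, seed=seed, outcome=outcome, **config_overrides)
    pset = generate_cohort(cfg)
    ref = load_reference(cfg.growth_ref)
    labels, defn = label_patient_set(pset, outcome, ref=ref)
    spec = WindowSpec(outcome, window[0], window[1], (defn.onset_mean, 18.0))
    return assemble_cohort(pset, labels, spec, ref, defn.onset_mean)
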