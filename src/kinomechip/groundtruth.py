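"""Mechanistic ground truth for the simulator.

The generative model treats each kinase as a first-order catalyst: a substrate
accumulates phosphosignal with velocity equal to the weight-summed activity of
its upstream kinases, and a drug scales a kinase's activity by single-site
occupancy ``1 / (1 + [D]/IC50)``. Sex, tissue and per-patient biology enter as
multiplicative factors on kinase activity, which is what lets group-level
dichotomies (e.g. AKT up in male tumors, down in female tumors) be scripted as
fixtures with exactly known recovery targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np

from .annotation import KinaseSubstrateMap
from .design import CohortDesign, DrugPanel
from .errors import InvalidParameterError


@dataclass(frozen=True)
class NoiseModel:
    """Heteroscedastic noise: multiplicative lognormal spot and replicate
    effects (given as coefficients of variation) plus additive Gaussian
    background noise in AU."""

    spot_cv: float = 0.10
    replicate_cv: float = 0.05
    background_sd: float = 2.0

    def __post_init__(self):
        for name in ("spot_cv", "replicate_cv"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise InvalidParameterError(f"{name} must lie in [0, 1)")
        if self.background_sd < 0:
            raise InvalidParameterError("background_sd must be >= 0")

    @property
    def silent(self) -> bool:
        return self.spot_cv == 0 and self.replicate_cv == 0 and self.background_sd == 0


NOISELESS = NoiseModel(0.0, 0.0, 0.0)


@dataclass
class GroundTruth:
    """Known kinase biology driving a simulation.

    Attributes
    ----------
    baseline_activity : kinase_id -> activity (AU/ms per unit kinetic factor).
    kinetic_rate : substrate_id -> first-order rate constant per cycle.
    condition_multipliers : (kinase_id, tissue, sex) -> fold multiplier on
        activity; absent keys mean 1.0.
    drug_ic50 : (kinase_id, drug_id) -> IC50 in nM; absent = no interaction.
    patient_effects : (patient_id, kinase_id) -> fold multiplier capturing
        inter-patient biology; absent keys mean 1.0.
    response_overrides : (patient_id, drug_id, kinase_id) -> fold factor that
        replaces the occupancy factor for that patient (e.g. > 1 emulates a
        non-responder whose target activity rises under an inhibitor).
    noise : NoiseModel.
    """

    baseline_activity: Dict[str, float]
    kinetic_rate: Dict[str, float]
    condition_multipliers: Dict[Tuple[str, str, str], float] = field(default_factory=dict)
    drug_ic50: Dict[Tuple[str, str], float] = field(default_factory=dict)
    patient_effects: Dict[Tuple[str, str], float] = field(default_factory=dict)
    response_overrides: Dict[Tuple[str, str, str], float] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        if any(v <= 0 for v in self.baseline_activity.values()):
            raise InvalidParameterError("baseline activities must be strictly positive")
        if any(v <= 0 for v in self.kinetic_rate.values()):
            raise InvalidParameterError("kinetic rates must be strictly positive")
        if any(v <= 0 for v in self.drug_ic50.values()):
            raise InvalidParameterError("IC50 values must be strictly positive")
        for d in (self.condition_multipliers, self.patient_effects, self.response_overrides):
            if any(v <= 0 for v in d.values()):
                raise InvalidParameterError("multipliers must be strictly positive")

    def multiplier(self, kinase: str, tissue: str, sex: str) -> float:
        return self.condition_multipliers.get((kinase, tissue, sex), 1.0)

    def patient_effect(self, patient: str, kinase: str) -> float:
        return self.patient_effects.get((patient, kinase), 1.0)

    def noiseless(self) -> "GroundTruth":
        """Copy with all noise switched off (shares the dict fields)."""
        return replace(self, noise=NOISELESS)


#: tumor fold-changes for the named kinases, (male, female); the ABL axis is
#: up in both sexes, the AKT axis shows the male-up / female-down dichotomy.
_TUMOR_EFFECTS = {
    "ABL1": (2.5, 2.5),
    "ABL2": (2.0, 2.0),
    "INSR": (1.8, 1.8),
    "SYK": (1.6, 1.6),
    "DDR1": (1.5, 1.5),
    "SRC": (1.4, 1.4),
    "FRK": (1.3, 1.3),
    "AKT1": (1.8, 0.60),
    "AKT2": (1.7, 0.65),
    "ERK1": (1.5, 1.5),
    "GSK3": (1.3, 1.3),
    "AMPKA1": (1.2, 1.2),
    "AURA": (1.3, 1.3),
}

#: synthetic but pharmacologically plausible IC50s (nM). Imatinib is the
#: weakest ABL inhibitor of the three; rebastinib and olverembatinib carry
#: off-target entries that produce reportable off-target calls.
_DEFAULT_IC50 = {
    ("ABL1", "imatinib"): 600.0,
    ("ABL2", "imatinib"): 700.0,
    ("ABL1", "rebastinib"): 10.0,
    ("ABL2", "rebastinib"): 15.0,
    ("DDR1", "rebastinib"): 40.0,
    ("ABL1", "olverembatinib"): 4.0,
    ("ABL2", "olverembatinib"): 6.0,
    ("SRC", "olverembatinib"): 80.0,
    ("FRK", "olverembatinib"): 120.0,
}


def default_ground_truth(
    amap: KinaseSubstrateMap,
    cohort: CohortDesign,
    panel: DrugPanel,
    seed: int = 0,
    *,
    noise: NoiseModel | None = None,
    patient_sd: float = 0.2,
    non_responders: Mapping[Tuple[str, str], str] = (),
) -> GroundTruth:
    """Build a realistic GroundTruth for an annotation/cohort/panel triple.

    Baselines are lognormal (median 1.2 AU/ms, log-sd 0.35); kinetic rates are
    Uniform(0.02, 0.08) per cycle so curves approach saturation over a run of
    ~100 cycles; unnamed kinases get mild lognormal tumor effects (log-sd
    0.15, shared across sexes). ``non_responders`` maps (patient_id, drug_id)
    to a kinase whose occupancy factor is replaced by 1.4 (activity rises
    under the inhibitor) for that patient.
    """
    rng = np.random.default_rng(seed)
    kin_ids = list(amap.kinases["kinase_id"])
    sub_ids = list(amap.substrates["substrate_id"])

    baseline = {k: float(v) for k, v in zip(kin_ids, np.exp(rng.normal(np.log(1.2), 0.35, len(kin_ids))))}
    rates = {s: float(v) for s, v in zip(sub_ids, rng.uniform(0.02, 0.08, len(sub_ids)))}

    cond: Dict[Tuple[str, str, str], float] = {}
    for k in kin_ids:
        if k in _TUMOR_EFFECTS:
            m, f = _TUMOR_EFFECTS[k]
        else:
            m = f = float(np.exp(rng.normal(0.0, 0.15)))
        cond[(k, "tumor", "M")] = m
        cond[(k, "tumor", "F")] = f

    pat_eff: Dict[Tuple[str, str], float] = {}
    if patient_sd > 0:
        draws = np.exp(rng.normal(0.0, patient_sd, (len(cohort.patients), len(kin_ids))))
        for i, (pid, _) in enumerate(cohort.patients):
            for j, k in enumerate(kin_ids):
                pat_eff[(pid, k)] = float(draws[i, j])

    panel_drugs = {d.drug_id for d in panel.drugs}
    ic50 = {
        (kin, drug): v
        for (kin, drug), v in _DEFAULT_IC50.items()
        if kin in set(kin_ids) and drug in panel_drugs
    }

    overrides = {
        (pid, drug, kin): 1.4 for (pid, drug), kin in dict(non_responders).items()
    }

    return GroundTruth(
        baseline_activity=baseline,
        kinetic_rate=rates,
        condition_multipliers=cond,
        drug_ic50=ic50,
        patient_effects=pat_eff,
        response_overrides=overrides,
        noise=noise if noise is not None else NoiseModel(),
    )
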