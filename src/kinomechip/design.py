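"""Assay, cohort and drug-panel descriptions.

These frozen dataclasses pin down the geometry of a PamChip-style kinome run:
which peptide chips are used (PTK and STK), how many immobilized substrates and
kinetic read cycles each carries, the camera exposure ladder, detector
saturation, and the study design around it (paired tumor/adjacent tissue from a
sexed patient cohort, technical replicates, and an inhibitor panel spiked into
the reaction mix against a vehicle control).

Defaults reproduce the reference assay: 196 PTK + 144 STK substrates (340
total), 94 PTK / 124 STK reaction cycles, a 9-patient cohort (5 male, 4
female) run in technical triplicate, and three ABL inhibitors — imatinib
1000 nM, rebastinib 100 nM, olverembatinib 100 nM — against a DMSO vehicle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence, Tuple

from .errors import InvalidParameterError

CHIP_TYPES = ("PTK", "STK")

#: kinase family/group labels used on kinome trees; TK kinases act on the PTK
#: chip, all other groups on the STK chip.
FAMILY_GROUPS = ("TK", "TKL", "STE", "CK1", "AGC", "CAMK", "CMGC", "Other")


def _freeze(d: Mapping) -> Mapping:
    return MappingProxyType(dict(d))


@dataclass(frozen=True)
class AssayDesign:
    """Chip geometry and detector characteristics.

    Parameters
    ----------
    substrates_per_chip : mapping chip type -> number of peptide substrates.
    cycles_per_chip : mapping chip type -> number of kinetic read cycles.
    exposure_times : strictly increasing camera exposures in milliseconds.
    saturation_level : maximum detector intensity (AU); reads clip here.
    background_level : mean background intensity (AU) added to every read.
    """

    substrates_per_chip: Mapping[str, int] = field(
        default_factory=lambda: _freeze({"PTK": 196, "STK": 144})
    )
    cycles_per_chip: Mapping[str, int] = field(
        default_factory=lambda: _freeze({"PTK": 94, "STK": 124})
    )
    exposure_times: Tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0)
    saturation_level: float = 65535.0
    background_level: float = 100.0

    def __post_init__(self):
        object.__setattr__(self, "substrates_per_chip", _freeze(self.substrates_per_chip))
        object.__setattr__(self, "cycles_per_chip", _freeze(self.cycles_per_chip))
        object.__setattr__(self, "exposure_times", tuple(float(e) for e in self.exposure_times))
        for chip in self.chip_types:
            if chip not in CHIP_TYPES:
                raise InvalidParameterError(f"unknown chip type {chip!r}")
            if self.substrates_per_chip[chip] < 1:
                raise InvalidParameterError(f"{chip}: substrate count must be >= 1")
            if self.cycles_per_chip.get(chip, 0) < 2:
                raise InvalidParameterError(f"{chip}: cycle count must be >= 2")
        if set(self.cycles_per_chip) != set(self.substrates_per_chip):
            raise InvalidParameterError("substrates_per_chip and cycles_per_chip must cover the same chips")
        exp = self.exposure_times
        if len(exp) < 2 or any(b <= a for a, b in zip(exp, exp[1:])):
            raise InvalidParameterError("exposure_times must be strictly increasing with length >= 2")
        if not self.saturation_level > self.background_level >= 0:
            raise InvalidParameterError("need saturation_level > background_level >= 0")

    @property
    def chip_types(self) -> Tuple[str, ...]:
        return tuple(sorted(self.substrates_per_chip))

    @property
    def n_substrates(self) -> int:
        return sum(self.substrates_per_chip.values())


@dataclass(frozen=True)
class CohortDesign:
    """Patients, tissues and replication of a study.

    ``patients`` is a sequence of ``(patient_id, sex)`` with sex in {"M", "F"}.
    ``pooled`` switches between per-patient lysates and per-sex pooled lysates
    (equal allocation across patients of a sex).
    """

    patients: Tuple[Tuple[str, str], ...] = (
        ("HCC-M-1", "M"),
        ("HCC-M-2", "M"),
        ("HCC-M-3", "M"),
        ("HCC-M-4", "M"),
        ("HCC-M-5", "M"),
        ("HCC-F-6", "F"),
        ("HCC-F-7", "F"),
        ("HCC-F-8", "F"),
        ("HCC-F-9", "F"),
    )
    tissues: Tuple[str, ...] = ("tumor", "adjacent")
    technical_replicates: int = 3
    pooled: bool = False

    def __post_init__(self):
        object.__setattr__(self, "patients", tuple((str(p), str(s)) for p, s in self.patients))
        object.__setattr__(self, "tissues", tuple(self.tissues))
        if len(self.patients) < 1:
            raise InvalidParameterError("cohort needs at least one patient")
        if len({p for p, _ in self.patients}) != len(self.patients):
            raise InvalidParameterError("duplicate patient ids")
        for _, sex in self.patients:
            if sex not in ("M", "F"):
                raise InvalidParameterError(f"sex must be 'M' or 'F', got {sex!r}")
        if self.technical_replicates < 1:
            raise InvalidParameterError("technical_replicates must be >= 1")
        if len(self.tissues) < 1:
            raise InvalidParameterError("at least one tissue required")

    @property
    def sexes(self) -> Tuple[str, ...]:
        return tuple(sorted({s for _, s in self.patients}))

    def patients_of_sex(self, sex: str) -> Tuple[str, ...]:
        return tuple(p for p, s in self.patients if s == sex)


@dataclass(frozen=True)
class Drug:
    """One inhibitor in the panel: id, nominal target kinase, assay dose (nM)."""

    drug_id: str
    nominal_target: str
    concentration_nm: float

    def __post_init__(self):
        if self.concentration_nm < 0:
            raise InvalidParameterError(f"{self.drug_id}: concentration must be >= 0")


@dataclass(frozen=True)
class DrugPanel:
    """Inhibitor panel plus the single vehicle control.

    The vehicle is the implicit zero-concentration treatment; treatment labels
    are ``(vehicle_label, drug_id, ...)`` in panel order.
    """

    drugs: Tuple[Drug, ...] = (
        Drug("imatinib", "ABL1", 1000.0),
        Drug("rebastinib", "ABL1", 100.0),
        Drug("olverembatinib", "ABL1", 100.0),
    )
    vehicle_label: str = "vehicle"

    def __post_init__(self):
        object.__setattr__(self, "drugs", tuple(self.drugs))
        ids = [d.drug_id for d in self.drugs]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("duplicate drug ids in panel")
        if self.vehicle_label in ids:
            raise InvalidParameterError("vehicle_label collides with a drug id")

    @property
    def treatments(self) -> Tuple[str, ...]:
        return (self.vehicle_label,) + tuple(d.drug_id for d in self.drugs)

    def drug(self, drug_id: str) -> Drug:
        for d in self.drugs:
            if d.drug_id == drug_id:
                return d
        raise KeyError(drug_id)

    def concentration(self, treatment: str) -> float:
        if treatment == self.vehicle_label:
            return 0.0
        return self.drug(treatment).concentration_nm
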