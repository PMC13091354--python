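"""PerMed scores and the clinical-trial-on-a-chip comparison.

The PerMed score of a kinase under a contrast is the mean, over its mapped
substrates, of the percent change of quantified signal in the treated
condition relative to control: ``mean_s 100·(treat_s − ctrl_s)/ctrl_s``. It
is computed on the *linear, background-subtracted* scale; because treated
signals can dip below the subtracted background, scores below −100% are
legal and meaningful (strong inhibition).

The trial stage applies the score per patient (or pooled group) and drug:
the drug's nominal target yields the on-target score, every other kinase
with |score| above a threshold is an off-target call (sign retained, so
compensatory *increases* are reported as positive), a strictly positive
on-target score under an inhibitor marks a non-responder, and drugs are
ranked by on-target inhibition with off-target burden as tie-breaker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import KinaseSubstrateMap
from .design import DrugPanel
from .errors import ContrastError, InvalidParameterError, UnscorableError
from .quantify import QuantifiedSignalMatrix

DEFAULT_OFF_TARGET_THRESHOLD = 20.0  # percent


@dataclass
class PerMedReport:
    """PerMed score of one kinase for one contrast."""

    kinase_id: str
    treat_label: str
    ctrl_label: str
    per_substrate_pct: Dict[str, float]
    excluded: Dict[str, str]
    scale_tag: str = "linear_background_subtracted"

    @property
    def score(self) -> float:
        return float(np.mean(list(self.per_substrate_pct.values())))

    @property
    def n_substrates(self) -> int:
        return len(self.per_substrate_pct)


def permed_score(
    matrix: QuantifiedSignalMatrix,
    amap: KinaseSubstrateMap,
    kinase: str,
    treat_label: str,
    ctrl_label: str,
    *,
    epsilon: float = 1e-3,
    units: Optional[Sequence[Tuple[str, str]]] = None,
) -> PerMedReport:
    """PerMed score of ``kinase`` for treat vs. control treatment labels.

    ``units`` restricts to specific (patient, tissue) sample units; by
    default every unit carrying both labels contributes, and substrate
    signals are averaged across units before the percent change. Substrates
    whose control signal is within ``epsilon`` AU/ms of zero are excluded and
    reported (transparent denominator guard, no clipping).
    """
    if matrix.transform != "linear":
        raise InvalidParameterError("permed_score requires the linear-scale matrix")
    cols = matrix.values.columns
    for label in (treat_label, ctrl_label):
        if not any(t == label for _, _, t in cols):
            raise ContrastError(f"treatment label {label!r} absent from matrix")
    if units is None:
        units = sorted(
            {(p, ti) for p, ti, t in cols if t == treat_label and (p, ti, ctrl_label) in cols}
        )
        if not units:
            raise ContrastError(f"no sample unit carries both {treat_label!r} and {ctrl_label!r}")
    mapped = amap.substrates_of(kinase)["substrate_id"]
    mapped = [s for s in mapped if s in matrix.values.index]
    if not mapped:
        raise UnscorableError(f"kinase {kinase!r} has no measured substrates")
    treat_cols = [(p, ti, treat_label) for p, ti in units]
    ctrl_cols = [(p, ti, ctrl_label) for p, ti in units]
    treat = matrix.values.loc[mapped, treat_cols].mean(axis=1)
    ctrl = matrix.values.loc[mapped, ctrl_cols].mean(axis=1)

    pcts: Dict[str, float] = {}
    excluded: Dict[str, str] = {}
    for s in mapped:
        c, t = float(ctrl.loc[s]), float(treat.loc[s])
        if np.isnan(c) or np.isnan(t):
            excluded[s] = "masked"
        elif abs(c) < epsilon:
            excluded[s] = f"control_below_epsilon({epsilon:g})"
        else:
            pcts[s] = 100.0 * (t - c) / c
    if not pcts:
        raise UnscorableError(f"kinase {kinase!r}: all substrates excluded ({excluded})")
    return PerMedReport(kinase, treat_label, ctrl_label, pcts, excluded)


def detect_off_target(
    scores: Dict[str, float],
    nominal_target: str,
    threshold: float = DEFAULT_OFF_TARGET_THRESHOLD,
) -> List[Tuple[str, float]]:
    """Kinases (excluding the nominal target) with |PerMed| ≥ threshold,
    sorted by |score| descending; the sign (direction) is retained."""
    hits = [(k, v) for k, v in scores.items() if k != nominal_target and abs(v) >= threshold]
    hits.sort(key=lambda kv: (-abs(kv[1]), kv[0]))
    return hits


@dataclass
class DrugResult:
    """Per-drug outcome within one sample unit."""

    drug_id: str
    nominal_target: str
    target_permed: Optional[float]
    off_targets: List[Tuple[str, float]]
    non_responder: Optional[bool]
    scores: Dict[str, float]
    assayed: bool = True


@dataclass
class TrialReport:
    """Clinical-trial-on-a-chip report for one sample unit."""

    unit: Tuple[str, str]  # (patient_id or pool id, tissue)
    vehicle_label: str
    off_target_threshold: float
    drugs: Dict[str, DrugResult]
    drug_ranking: List[str]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.unit[0],
            "tissue": self.unit[1],
            "vehicle_label": self.vehicle_label,
            "off_target_threshold_pct": self.off_target_threshold,
            "drug_ranking": self.drug_ranking,
            "drugs": {
                d.drug_id: {
                    "nominal_target": d.nominal_target,
                    "assayed": d.assayed,
                    "target_permed_pct": d.target_permed,
                    "non_responder": d.non_responder,
                    "off_targets": [{"kinase_id": k, "permed_pct": v} for k, v in d.off_targets],
                    "kinase_permed_pct": d.scores,
                }
                for d in self.drugs.values()
            },
        }

    def to_long_table(self) -> pd.DataFrame:
        rows = []
        for d in self.drugs.values():
            for k, v in d.scores.items():
                rows.append((self.unit[0], self.unit[1], d.drug_id, k, v, k == d.nominal_target))
        return pd.DataFrame(
            rows, columns=["patient_id", "tissue", "drug_id", "kinase_id", "permed_pct", "is_target"]
        )


def rank_drugs(results: Sequence[DrugResult]) -> List[str]:
    """Order drugs for a unit: most negative on-target PerMed first, then
    fewer off-target calls, then smaller off-target burden; non-responder
    drugs last regardless; unscored/not-assayed drugs after those."""

    def key(d: DrugResult):
        if not d.assayed or d.target_permed is None:
            tier = 2
            target = 0.0
        elif d.non_responder:
            tier = 1
            target = d.target_permed
        else:
            tier = 0
            target = d.target_permed
        burden = sum(abs(v) for _, v in d.off_targets)
        return (tier, target, len(d.off_targets), burden, d.drug_id)

    return [d.drug_id for d in sorted(results, key=key)]


@dataclass(frozen=True)
class TrialParams:
    off_target_threshold: float = DEFAULT_OFF_TARGET_THRESHOLD
    epsilon: float = 1e-3
    min_substrates: int = 1
    tissue: str = "tumor"


def run_trial(
    matrix: QuantifiedSignalMatrix,
    amap: KinaseSubstrateMap,
    panel: DrugPanel,
    params: TrialParams = TrialParams(),
) -> List[TrialReport]:
    """Score every (sample unit, drug, kinase) and call on/off-target effects.

    One report per sample unit of ``params.tissue`` that carries a vehicle
    column. Drugs absent from the matrix are listed as not assayed rather
    than failing the whole trial.
    """
    cols = matrix.values.columns
    vehicle = panel.vehicle_label
    units = sorted({(p, ti) for p, ti, t in cols if ti == params.tissue})
    if not units:
        raise ContrastError(f"no sample units for tissue {params.tissue!r}")
    # precompute each kinase's measured substrate rows once; the per-cell
    # arithmetic below is exactly permed_score's, just batched
    index = matrix.values.index
    kinase_rows = {}
    for kinase, subs in amap.edges.groupby("kinase_id")["substrate_id"]:
        pos = index.get_indexer(subs)
        pos = pos[pos >= 0]
        if pos.size:
            kinase_rows[kinase] = pos
    reports = []
    for unit in units:
        if (unit[0], unit[1], vehicle) not in cols:
            raise ContrastError(f"unit {unit} lacks the vehicle treatment {vehicle!r}")
        ctrl = matrix.values[(unit[0], unit[1], vehicle)].to_numpy(float)
        drug_results: Dict[str, DrugResult] = {}
        for drug in panel.drugs:
            if (unit[0], unit[1], drug.drug_id) not in cols:
                drug_results[drug.drug_id] = DrugResult(
                    drug.drug_id, drug.nominal_target, None, [], None, {}, assayed=False
                )
                continue
            treat = matrix.values[(unit[0], unit[1], drug.drug_id)].to_numpy(float)
            valid = np.isfinite(ctrl) & np.isfinite(treat) & (np.abs(ctrl) >= params.epsilon)
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(valid, 100.0 * (treat - ctrl) / ctrl, np.nan)
            scores: Dict[str, float] = {}
            for kinase, pos in kinase_rows.items():
                vals = pct[pos]
                vals = vals[np.isfinite(vals)]
                if vals.size >= params.min_substrates:
                    scores[kinase] = float(vals.mean())
            target = scores.get(drug.nominal_target)
            off = detect_off_target(scores, drug.nominal_target, params.off_target_threshold)
            non_resp = None if target is None else bool(target > 0)
            drug_results[drug.drug_id] = DrugResult(
                drug.drug_id, drug.nominal_target, target, off, non_resp, scores
            )
        ranking = rank_drugs(list(drug_results.values()))
        reports.append(
            TrialReport(unit, vehicle, params.off_target_threshold, drug_results, ranking)
        )
    return reports


def write_trial_json(reports: Sequence[TrialReport], path) -> None:
    payload = [r.to_dict() for r in reports]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_trial_tsv(reports: Sequence[TrialReport], path) -> None:
    tables = [r.to_long_table() for r in reports]
    pd.concat(tables, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.9g")
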