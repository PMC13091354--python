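"""Forward simulator for multi-cycle, multi-exposure kinome-array runs.

Model
-----
For substrate *s* in sample unit *u* under treatment *t*, the phosphorylation
velocity is the weight-summed activity of its upstream kinases,

    V(s,u,t) = Σ_K  w(K,s) · baseline(K) · mult(K, tissue_u, sex_u)
                     · mean_{p ∈ u} [ pat(p,K) · f_drug(p,t,K) ],

where ``f_drug`` is single-site occupancy ``1/(1 + [D]/IC50)`` (or a
per-patient override emulating e.g. a non-responder). The real-time kinetic
read follows a saturating exponential, ``A(s,u,t,c) = V · (1 − exp(−r_s c))``
over cycles ``c = 1..C``, and the camera sees

    I = clip(background + e · A · spot · rep + ε,  0,  saturation)

at each exposure ``e`` (ms), with lognormal spot/replicate effects of unit
mean and additive Gaussian read noise ε. Pooled lysates average the noiseless
per-patient velocities (equal allocation) before noise is applied.

The emitted table is long-format with one row per
(substrate, sample, treatment, replicate, cycle, exposure) measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import KinaseSubstrateMap
from .design import AssayDesign, CohortDesign, DrugPanel
from .errors import ConsistencyError, InvalidParameterError, UnscorableError
from .groundtruth import GroundTruth

RAW_COLUMNS = (
    "substrate_id",
    "chip_type",
    "patient_id",
    "sex",
    "tissue",
    "treatment",
    "replicate",
    "cycle",
    "exposure_ms",
    "intensity",
)


def drug_scaling(activity: float, concentration: float, ic50: float) -> float:
    """Scale a kinase activity by single-site inhibitor occupancy.

    Returns ``activity / (1 + concentration/ic50)``; monotone non-increasing
    in concentration, identity at zero dose, halved at ``concentration ==
    ic50``.
    """
    if ic50 <= 0:
        raise InvalidParameterError("ic50 must be strictly positive")
    if activity <= 0:
        raise InvalidParameterError("activity must be strictly positive")
    if concentration < 0:
        raise InvalidParameterError("concentration must be >= 0")
    return activity / (1.0 + concentration / ic50)


@dataclass(frozen=True)
class SampleUnit:
    """One assayed lysate: an individual patient or a per-sex pool."""

    sample_id: str
    sex: str
    tissue: str
    members: Tuple[str, ...]  # contributing patient ids


def cohort_units(cohort: CohortDesign) -> List[SampleUnit]:
    """Sample units implied by a cohort design (pooled or per-patient)."""
    units: List[SampleUnit] = []
    if cohort.pooled:
        for sex in cohort.sexes:
            members = cohort.patients_of_sex(sex)
            for tissue in cohort.tissues:
                units.append(SampleUnit(f"POOL-{sex}", sex, tissue, members))
    else:
        for pid, sex in cohort.patients:
            for tissue in cohort.tissues:
                units.append(SampleUnit(pid, sex, tissue, (pid,)))
    return units


def _occupancy(conc: float, ic50: float) -> float:
    return 1.0 / (1.0 + conc / ic50)


def _kinase_activity(
    truth: GroundTruth, panel: DrugPanel, kinase: str, unit: SampleUnit, treatment: str
) -> float:
    """Effective activity of one kinase in one unit under one treatment."""
    base = truth.baseline_activity[kinase] * truth.multiplier(kinase, unit.tissue, unit.sex)
    conc = panel.concentration(treatment)
    ic50 = truth.drug_ic50.get((kinase, treatment))
    acc = 0.0
    for pid in unit.members:
        if treatment != panel.vehicle_label and (pid, treatment, kinase) in truth.response_overrides:
            f = truth.response_overrides[(pid, treatment, kinase)]
        elif ic50 is not None and conc > 0:
            f = _occupancy(conc, ic50)
        else:
            f = 1.0
        acc += truth.patient_effect(pid, kinase) * f
    return base * acc / len(unit.members)


def compute_velocities(
    amap: KinaseSubstrateMap,
    truth: GroundTruth,
    units: Sequence[SampleUnit],
    panel: DrugPanel,
) -> Tuple[np.ndarray, pd.Index]:
    """Noiseless velocities V[s, u, t] for every substrate/unit/treatment.

    Returns the array (substrates × units × treatments, ordered as in the
    annotation / ``units`` / ``panel.treatments``) and the substrate index.
    """
    W, sub_index, kin_index = amap.weight_matrix()
    treatments = panel.treatments
    act = np.empty((len(kin_index), len(units), len(treatments)))
    for ki, kinase in enumerate(kin_index):
        for ui, unit in enumerate(units):
            for ti, treatment in enumerate(treatments):
                act[ki, ui, ti] = _kinase_activity(truth, panel, kinase, unit, treatment)
    V = W @ act.reshape(len(kin_index), -1)
    return V.reshape(len(sub_index), len(units), len(treatments)), sub_index


def _check_consistency(
    design: AssayDesign,
    amap: KinaseSubstrateMap,
    truth: GroundTruth,
    panel: DrugPanel,
) -> None:
    counts = amap.substrates_per_chip()
    for chip in design.chip_types:
        if counts.get(chip, 0) != design.substrates_per_chip[chip]:
            raise ConsistencyError(
                f"{chip}: design expects {design.substrates_per_chip[chip]} substrates, "
                f"annotation has {counts.get(chip, 0)}"
            )
    kin_ids = set(amap.kinases["kinase_id"])
    for sub in amap.substrates["substrate_id"]:
        if sub not in truth.kinetic_rate:
            raise ConsistencyError(f"ground truth lacks kinetic_rate for substrate {sub!r}")
    for kin in kin_ids:
        if kin not in truth.baseline_activity:
            raise ConsistencyError(f"ground truth lacks baseline_activity for kinase {kin!r}")
    for d in panel.drugs:
        if d.nominal_target not in kin_ids:
            raise ConsistencyError(f"panel target {d.nominal_target!r} absent from annotation")
    for (kin, drug_id) in truth.drug_ic50:
        if kin not in kin_ids:
            raise ConsistencyError(f"IC50 entry references unknown kinase {kin!r}")
        if drug_id not in {d.drug_id for d in panel.drugs}:
            raise ConsistencyError(f"IC50 entry references unknown drug {drug_id!r}")


def simulate_signals(
    design: AssayDesign,
    amap: KinaseSubstrateMap,
    truth: GroundTruth,
    cohort: CohortDesign,
    panel: DrugPanel,
    seed: int,
) -> pd.DataFrame:
    """Simulate a full raw intensity table, deterministic in ``seed``.

    Output columns follow :data:`RAW_COLUMNS`; the table is grid-complete —
    every (substrate, sample, treatment, replicate) carries its full
    cycle × exposure grid.
    """
    _check_consistency(design, amap, truth, panel)
    rng = np.random.default_rng(seed)
    units = cohort_units(cohort)
    treatments = panel.treatments
    R = cohort.technical_replicates
    exposures = np.asarray(design.exposure_times)
    E = len(exposures)
    bg = design.background_level
    sat = design.saturation_level
    noise = truth.noise
    sig_spot = float(np.sqrt(np.log1p(noise.spot_cv**2)))
    sig_rep = float(np.sqrt(np.log1p(noise.replicate_cv**2)))

    V, sub_index = compute_velocities(amap, truth, units, panel)
    chip_of = amap.chip_of().loc[sub_index].to_numpy()
    rates_all = np.array([truth.kinetic_rate[s] for s in sub_index])

    unit_pat = np.array([u.sample_id for u in units])
    unit_sex = np.array([u.sex for u in units])
    unit_tis = np.array([u.tissue for u in units])
    U, T = len(units), len(treatments)

    frames: List[pd.DataFrame] = []
    for chip in design.chip_types:  # sorted, so the RNG stream is well-defined
        sel = chip_of == chip
        subs = np.asarray(sub_index)[sel]
        S = len(subs)
        C = design.cycles_per_chip[chip]
        cycles = np.arange(1, C + 1)
        kin = 1.0 - np.exp(-np.outer(rates_all[sel], cycles))  # (S, C)
        A = V[sel][:, :, :, None] * kin[:, None, None, :]  # (S, U, T, C)

        if noise.spot_cv > 0:
            spot = rng.lognormal(-0.5 * sig_spot**2, sig_spot, (S, U, T, R))
        else:
            spot = np.ones((S, U, T, R))
        if noise.replicate_cv > 0:
            repf = rng.lognormal(-0.5 * sig_rep**2, sig_rep, (U, T, R))
        else:
            repf = np.ones((U, T, R))
        signal = (
            A[:, :, :, None, :, None]
            * spot[:, :, :, :, None, None]
            * repf[None, :, :, :, None, None]
            * exposures[None, None, None, None, None, :]
        )
        if noise.background_sd > 0:
            signal += rng.normal(0.0, noise.background_sd, signal.shape)
        intensity = np.clip(bg + signal, 0.0, sat).reshape(-1)

        n = intensity.size
        block_u = T * R * C * E
        block_t = R * C * E
        block_r = C * E
        sub_codes = np.repeat(np.arange(S, dtype=np.int32), block_u * U)
        u_codes = np.tile(np.repeat(np.arange(U, dtype=np.int32), block_u), S)
        t_codes = np.tile(np.repeat(np.arange(T, dtype=np.int32), block_t), S * U)
        r_codes = np.tile(np.repeat(np.arange(R, dtype=np.int32), block_r), S * U * T)
        c_codes = np.tile(np.repeat(np.arange(C, dtype=np.int32), E), S * U * T * R)
        e_codes = np.tile(np.arange(E, dtype=np.int32), n // E)

        frames.append(
            pd.DataFrame(
                {
                    "substrate_id": pd.Categorical.from_codes(sub_codes, categories=list(subs)),
                    "chip_type": pd.Categorical([chip]).repeat(n),
                    "patient_id": pd.Categorical(unit_pat[u_codes]),
                    "sex": pd.Categorical(unit_sex[u_codes]),
                    "tissue": pd.Categorical(unit_tis[u_codes]),
                    "treatment": pd.Categorical.from_codes(t_codes, categories=list(treatments)),
                    "replicate": (r_codes + 1).astype(np.int32),
                    "cycle": cycles.astype(np.int32)[c_codes],
                    "exposure_ms": exposures[e_codes],
                    "intensity": intensity,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def write_raw(df: pd.DataFrame, path) -> None:
    """Write a raw signal table as TSV (gzip-transparent by extension)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_raw(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ConsistencyError(f"raw table missing columns: {sorted(missing)}")
    return df


def truth_permed(
    amap: KinaseSubstrateMap,
    truth: GroundTruth,
    panel: DrugPanel,
    kinase: str,
    drug: str,
    *,
    sex: str = "M",
    tissue: str = "tumor",
    members: Sequence[str] = (),
) -> float:
    """Analytic PerMed score (percent) from noiseless velocities.

    For each substrate mapped to ``kinase``, the percent change of its
    noiseless drug velocity relative to vehicle; the score is the mean over
    mapped substrates. The kinetic and exposure factors cancel in the ratio,
    so this is the exact recovery target for the full pipeline on noiseless
    data. ``members`` lists the pooled patients (empty = a unit without
    patient effects).
    """
    if drug not in {d.drug_id for d in panel.drugs}:
        raise ConsistencyError(f"unknown drug {drug!r}")
    mapped = amap.substrates_of(kinase)
    if len(mapped) == 0:
        raise UnscorableError(f"kinase {kinase!r} has no mapped substrates")
    unit = SampleUnit("truth", sex, tissue, tuple(members) or ("__virtual__",))
    pcts = []
    for sub in mapped["substrate_id"]:
        v_veh = 0.0
        v_drug = 0.0
        for _, row in amap.kinases_of(sub).iterrows():
            k, w = row["kinase_id"], row["weight"]
            v_veh += w * _kinase_activity(truth, panel, k, unit, panel.vehicle_label)
            v_drug += w * _kinase_activity(truth, panel, k, unit, drug)
        pcts.append(100.0 * (v_drug - v_veh) / v_veh)
    return float(np.mean(pcts))
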