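"""Self-contained evaluation experiments for the statistical machinery.

Each function builds its own inputs (random panels, spiked LFC tables, or
small simulated runs with known ground truth), runs the package end to end,
and returns the measured quantity. They exist so that calibration and
recovery claims about the method are recomputable from a single seed, both
in the test suite and from ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .annotation import KinaseSubstrateMap, build_default_annotation
from .design import AssayDesign, CohortDesign, Drug, DrugPanel
from .groundtruth import NOISELESS, GroundTruth, NoiseModel, default_ground_truth
from .permed import permed_score
from .quantify import quantify
from .simulate import cohort_units, simulate_signals, truth_permed
from .stats import SubstrateStats
from .upstream import exhaustive_z, sampling_z, score_kinases_z, uka_rank


def _random_annotation(
    rng: np.random.Generator,
    n_substrates: int,
    n_kinases: int,
    m_range: Tuple[int, int] = (3, 12),
    chip: str = "PTK",
) -> KinaseSubstrateMap:
    """Random bipartite map over one chip; every substrate gets ≥ 1 edge."""
    subs = [f"{chip}_{i + 1:03d}" for i in range(n_substrates)]
    fam = "TK" if chip == "PTK" else "AGC"
    kin_rows, edge_rows = [], []
    for j in range(n_kinases):
        kid = f"K{j + 1:04d}"
        kin_rows.append((kid, fam))
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        for s in rng.choice(subs, size=m, replace=False):
            edge_rows.append((kid, s, 1.0))
    covered = {s for _, s, _ in edge_rows}
    edge_rows += [(kin_rows[0][0], s, 1.0) for s in subs if s not in covered]
    edges = pd.DataFrame(edge_rows, columns=["kinase_id", "substrate_id", "weight"])
    edges = edges.drop_duplicates(subset=["kinase_id", "substrate_id"])
    return KinaseSubstrateMap(
        pd.DataFrame(kin_rows, columns=["kinase_id", "family_group"]),
        pd.DataFrame({"substrate_id": subs, "chip_type": chip}),
        edges,
    )


def _stats_from_lfcs(lfc: np.ndarray, chip: str = "PTK") -> SubstrateStats:
    lfc = np.atleast_2d(lfc.T).T  # (substrates, pairs)
    subs = [f"{chip}_{i + 1:03d}" for i in range(lfc.shape[0])]
    frame = pd.DataFrame(lfc, index=subs, columns=[f"pair{j}" for j in range(lfc.shape[1])])
    return SubstrateStats(frame, pd.Series(chip, index=frame.index), ("case", "control"))


def sampling_vs_exhaustive_gap(
    n_instances: int = 20, n_iter: int = 50_000, seed: int = 0
) -> float:
    """Largest |sampled z − exact z| over random small instances.

    Instances keep C(panel, m) within the exhaustive oracle's enumeration
    bound (panel 8–18 substrates, m 2–4).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 19))
        m = int(rng.integers(2, 5))
        lfcs = rng.normal(0, 0.5, n)
        subs = rng.choice(n, size=m, replace=False)
        all_subs = [f"PTK_{i + 1:03d}" for i in range(n)]
        picked = [f"PTK_{i + 1:03d}" for i in subs]
        edges = pd.DataFrame({"kinase_id": "K0001", "substrate_id": picked, "weight": 1.0})
        missing = [s for s in all_subs if s not in set(picked)]
        filler = pd.DataFrame({"kinase_id": "FILLER", "substrate_id": missing, "weight": 1.0})
        kin = pd.DataFrame({"kinase_id": ["K0001", "FILLER"], "family_group": ["TK", "TK"]})
        amap = KinaseSubstrateMap(
            kin,
            pd.DataFrame({"substrate_id": all_subs, "chip_type": "PTK"}),
            pd.concat([edges, filler], ignore_index=True),
        )
        stats = _stats_from_lfcs(lfcs)
        exact = exhaustive_z(stats, amap, "K0001")
        approx = sampling_z(stats, amap, "K0001", n_iter=n_iter, seed=int(rng.integers(2**31)), min_substrates=2)
        worst = max(worst, abs(approx.z - exact.z))
    return worst


def null_calibration_rate(
    n_kinases: int = 2000,
    panel_size: int = 196,
    sigma: float = 0.25,
    n_iter: int = 2000,
    seed: int = 0,
) -> float:
    """Fraction of kinases with |z| > 1.96 when LFCs are i.i.d. N(0, σ²) and
    maps are random — the nominal false-positive rate of the sampling null."""
    rng = np.random.default_rng(seed)
    kinases_per_batch = 200
    n_batches = int(np.ceil(n_kinases / kinases_per_batch))
    hits = total = 0
    for b in range(n_batches):
        amap = _random_annotation(rng, panel_size, kinases_per_batch, m_range=(3, 12))
        lfcs = rng.normal(0, sigma, panel_size)
        stats = _stats_from_lfcs(lfcs)
        table = score_kinases_z(stats, amap, n_iter=n_iter, seed=int(rng.integers(2**31)))
        z = table["z"].dropna()
        hits += int((z.abs() > 1.96).sum())
        total += len(z)
    return hits / total


def spiked_recovery_rate(
    n_runs: int = 50,
    panel_size: int = 196,
    m_spiked: int = 10,
    shift: float = 1.0,
    noise_sd: float = 0.1,
    n_pairs: int = 9,
    n_background: int = 80,
    seed: int = 0,
) -> float:
    """Fraction of runs where a kinase whose substrates are shifted by
    ``shift`` ranks first by |final_score| among random background kinases."""
    rng = np.random.default_rng(seed)
    top1 = 0
    for _ in range(n_runs):
        amap = _random_annotation(rng, panel_size, n_background, m_range=(3, 12))
        spiked_idx = rng.choice(panel_size, size=m_spiked, replace=False)
        spiked_edges = pd.DataFrame(
            {
                "kinase_id": "SPIKED",
                "substrate_id": [f"PTK_{i + 1:03d}" for i in spiked_idx],
                "weight": 1.0,
            }
        )
        kin = pd.concat(
            [amap.kinases, pd.DataFrame({"kinase_id": ["SPIKED"], "family_group": ["TK"]})],
            ignore_index=True,
        )
        amap = KinaseSubstrateMap(
            kin, amap.substrates, pd.concat([amap.edges, spiked_edges], ignore_index=True)
        )
        lfc = rng.normal(0, noise_sd, (panel_size, n_pairs))
        lfc[spiked_idx, :] += shift
        stats = _stats_from_lfcs(lfc)
        table = uka_rank(stats, amap, n_perm=500, n_iter=2000, seed=int(rng.integers(2**31)))
        if table.iloc[0]["kinase_id"] == "SPIKED":
            top1 += 1
    return top1 / n_runs


def _noiseless_pooled_run(seed: int):
    """Noiseless pooled-by-sex tumor run on the default assay."""
    amap = build_default_annotation(seed)
    cohort = CohortDesign(tissues=("tumor",), technical_replicates=1, pooled=True)
    panel = DrugPanel()
    truth = default_ground_truth(amap, cohort, panel, seed=seed, noise=NOISELESS)
    design = AssayDesign()
    raw = simulate_signals(design, amap, truth, cohort, panel, seed=seed)
    matrix = quantify(raw, design)
    return amap, cohort, panel, truth, matrix


def permed_oracle_error(seed: int = 0) -> Tuple[float, int]:
    """Max |pipeline PerMed − analytic PerMed| (percentage points) over every
    (kinase, drug, sex-pool) triple of a noiseless default run."""
    amap, cohort, panel, truth, matrix = _noiseless_pooled_run(seed)
    worst = 0.0
    n_pairs = 0
    for sex in cohort.sexes:
        members = cohort.patients_of_sex(sex)
        unit = (f"POOL-{sex}", "tumor")
        for drug in panel.drugs:
            for kinase in amap.kinases["kinase_id"]:
                measured = permed_score(
                    matrix, amap, kinase, drug.drug_id, panel.vehicle_label, units=[unit]
                )
                expected = truth_permed(
                    amap, truth, panel, kinase, drug.drug_id, sex=sex, tissue="tumor", members=members
                )
                worst = max(worst, abs(measured.score - expected))
                n_pairs += 1
    return worst, n_pairs


def _single_target_setup(conc: float, ic50: float, noise: NoiseModel, m: int = 10):
    """One kinase exclusively driving ``m`` substrates, one drug at ``conc``."""
    subs = [f"PTK_{i + 1:03d}" for i in range(m)]
    amap = KinaseSubstrateMap(
        pd.DataFrame({"kinase_id": ["TARGET"], "family_group": ["TK"]}),
        pd.DataFrame({"substrate_id": subs, "chip_type": "PTK"}),
        pd.DataFrame({"kinase_id": "TARGET", "substrate_id": subs, "weight": np.linspace(0.4, 1.0, m)}),
    )
    design = AssayDesign(substrates_per_chip={"PTK": m}, cycles_per_chip={"PTK": 94})
    cohort = CohortDesign(patients=(("P1", "M"),), tissues=("tumor",), technical_replicates=3)
    panel = DrugPanel(drugs=(Drug("inhibitor", "TARGET", conc),))
    return amap, design, cohort, panel


def exclusive_target_permed_at_ic50(seed: int = 0) -> float:
    """Pipeline PerMed of an exclusively-mapped target dosed at its IC50 on
    noiseless data (occupancy model ⇒ −50%)."""
    amap, design, cohort, panel = _single_target_setup(50.0, 50.0, NOISELESS)
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        baseline_activity={"TARGET": 10.0},
        kinetic_rate={s: float(r) for s, r in zip(amap.substrates["substrate_id"], rng.uniform(0.02, 0.08, 10))},
        drug_ic50={("TARGET", "inhibitor"): 50.0},
        noise=NOISELESS,
    )
    raw = simulate_signals(design, amap, truth, cohort, panel, seed=seed)
    matrix = quantify(raw, design)
    return permed_score(matrix, amap, "TARGET", "inhibitor", "vehicle").score


def noisy_permed_recovery_rate(
    n_runs: int = 50, tolerance_pts: float = 10.0, seed: int = 0
) -> Tuple[float, float]:
    """(fraction of runs with target PerMed within ±tolerance of truth,
    mean absolute error) under the default noise model, m = 10 substrates."""
    rng = np.random.default_rng(seed)
    amap, design, cohort, panel = _single_target_setup(50.0, 50.0, NoiseModel())
    within = 0
    abs_errs = []
    for _ in range(n_runs):
        run_seed = int(rng.integers(2**31))
        truth = GroundTruth(
            baseline_activity={"TARGET": 10.0},
            kinetic_rate={
                s: float(r)
                for s, r in zip(amap.substrates["substrate_id"], rng.uniform(0.02, 0.08, 10))
            },
            drug_ic50={("TARGET", "inhibitor"): 50.0},
            noise=NoiseModel(),
        )
        expected = truth_permed(amap, truth, panel, "TARGET", "inhibitor", sex="M", members=["P1"])
        raw = simulate_signals(design, amap, truth, cohort, panel, seed=run_seed)
        matrix = quantify(raw, design)
        got = permed_score(matrix, amap, "TARGET", "inhibitor", "vehicle").score
        err = abs(got - expected)
        abs_errs.append(err)
        if err <= tolerance_pts:
            within += 1
    return within / n_runs, float(np.mean(abs_errs))
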