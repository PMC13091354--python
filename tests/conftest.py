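"""Shared fixtures: toy annotations, small simulated runs, matrix builders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import kinomechip as kc

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_map():
    return kc.build_default_annotation(0)


@pytest.fixture
def toy_map():
    """One kinase (ABL1) driving two PTK substrates with distinct weights."""
    kin = pd.DataFrame({"kinase_id": ["ABL1"], "family_group": ["TK"]})
    sub = pd.DataFrame({"substrate_id": ["PTK_001", "PTK_002"], "chip_type": ["PTK", "PTK"]})
    edges = pd.DataFrame(
        {
            "kinase_id": ["ABL1", "ABL1"],
            "substrate_id": ["PTK_001", "PTK_002"],
            "weight": [0.5, 1.0],
        }
    )
    return kc.KinaseSubstrateMap(kin, sub, edges)


@pytest.fixture
def toy_truth():
    return kc.GroundTruth(
        baseline_activity={"ABL1": 10.0},
        kinetic_rate={"PTK_001": 0.05, "PTK_002": 0.1},
        drug_ic50={("ABL1", "imatinib"): 50.0},
        noise=kc.NOISELESS,
    )


@pytest.fixture
def toy_design():
    return kc.AssayDesign(substrates_per_chip={"PTK": 2}, cycles_per_chip={"PTK": 20})


@pytest.fixture
def toy_cohort():
    return kc.CohortDesign(patients=(("P1", "M"),), tissues=("tumor",), technical_replicates=2)


@pytest.fixture
def toy_panel():
    return kc.DrugPanel(drugs=(kc.Drug("imatinib", "ABL1", 50.0),))


@pytest.fixture
def toy_raw(toy_design, toy_map, toy_truth, toy_cohort, toy_panel):
    return kc.simulate_signals(toy_design, toy_map, toy_truth, toy_cohort, toy_panel, seed=1)


def make_matrix(values, chip=None, samples=None, transform="linear", n_replicates=1):
    """Build a QuantifiedSignalMatrix from a values DataFrame whose columns
    are (patient, tissue, treatment) tuples."""
    if not isinstance(values.columns, pd.MultiIndex):
        values = values.copy()
        values.columns = pd.MultiIndex.from_tuples(
            values.columns, names=["patient_id", "tissue", "treatment"]
        )
    values.index.name = "substrate_id"
    if chip is None:
        chip = pd.Series("PTK", index=values.index, name="chip_type")
    if samples is None:
        pats = sorted({p for p, _, _ in values.columns})
        samples = pd.DataFrame(
            {"patient_id": pats, "sex": ["M" if i % 2 == 0 else "F" for i in range(len(pats))]}
        )
    qc = pd.DataFrame("ok", index=values.index, columns=values.columns)
    return kc.QuantifiedSignalMatrix(values, qc, chip, samples, transform, n_replicates, {})


@pytest.fixture
def matrix_builder():
    return make_matrix


def random_map(rng, n_substrates=30, n_kinases=8, chip="PTK", m_range=(3, 8), prefix="K"):
    """A random bipartite map for statistical tests."""
    subs = [f"{chip}_{i + 1:03d}" for i in range(n_substrates)]
    kin_rows, edge_rows = [], []
    fam = "TK" if chip == "PTK" else "AGC"
    for j in range(n_kinases):
        kid = f"{prefix}{j + 1:03d}"
        kin_rows.append((kid, fam))
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        for s in rng.choice(subs, size=m, replace=False):
            edge_rows.append((kid, s, float(rng.uniform(0.2, 1.0))))
    # ensure every substrate has an edge
    covered = {s for _, s, _ in edge_rows}
    for s in subs:
        if s not in covered:
            edge_rows.append((kin_rows[0][0], s, 0.5))
    kin = pd.DataFrame(kin_rows, columns=["kinase_id", "family_group"])
    sub = pd.DataFrame({"substrate_id": subs, "chip_type": chip})
    edges = pd.DataFrame(edge_rows, columns=["kinase_id", "substrate_id", "weight"])
    edges = edges.drop_duplicates(subset=["kinase_id", "substrate_id"])
    return kc.KinaseSubstrateMap(kin, sub, edges)


def stats_from_lfcs(lfc_matrix: pd.DataFrame, chip="PTK", threshold=0.2):
    """SubstrateStats directly from a substrates × pairs LFC table."""
    chip_series = pd.Series(chip, index=lfc_matrix.index)
    return kc.SubstrateStats(lfc_matrix, chip_series, ("case", "control"), threshold)


@pytest.fixture
def stats_builder():
    return stats_from_lfcs


@pytest.fixture
def map_builder():
    return random_map
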