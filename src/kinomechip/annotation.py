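"""Substrate→kinase annotation: the weighted bipartite map behind upstream
kinase inference.

Each immobilized peptide substrate reports on the set of kinases that can
phosphorylate its motif; the map stores one weighted edge per
(kinase, substrate) pair, with a kinase family/group label per kinase and a
chip type per substrate. The default fixture is structurally realistic — 340
substrates (196 PTK, 144 STK), 520 kinases across the standard family groups,
substrate in-degrees on 1..15 — but is generated, not copied from any vendor
database (the commercial mappings are proprietary).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import CHIP_TYPES, FAMILY_GROUPS
from .errors import AnnotationError

ANNOTATION_COLUMNS = ("kinase_id", "family_group", "substrate_id", "chip_type", "weight")

#: kinases that must exist in the default fixture, with family group and the
#: minimum number of mapped substrates each receives.
NAMED_KINASES = {
    "ABL1": ("TK", 12),
    "ABL2": ("TK", 8),
    "INSR": ("TK", 8),
    "SYK": ("TK", 6),
    "DDR1": ("TK", 6),
    "FRK": ("TK", 6),
    "SRC": ("TK", 8),
    "AKT1": ("AGC", 6),
    "AKT2": ("AGC", 6),
    "ERK1": ("CMGC", 6),
    "GSK3": ("CMGC", 6),
    "AMPKA1": ("CAMK", 6),
    "AURA": ("Other", 6),
}

#: filler kinase counts per family group for the default fixture (the named
#: kinases above come on top; totals give 520 kinases, 190 on the TK side).
_FILLER_COUNTS = {
    "TK": 183,
    "TKL": 55,
    "STE": 50,
    "CK1": 30,
    "AGC": 55,
    "CAMK": 50,
    "CMGC": 54,
    "Other": 30,
}

#: substrate in-degree distribution: truncated geometric on 1..15,
#: P(d) ∝ 0.78**d (mean ≈ 3.9 kinases per peptide motif).
_DEGREE_SUPPORT = np.arange(1, 16)
_DEGREE_P = 0.78 ** _DEGREE_SUPPORT
_DEGREE_P = _DEGREE_P / _DEGREE_P.sum()


def _chip_of_family(family: str) -> str:
    return "PTK" if family == "TK" else "STK"


@dataclass
class KinaseSubstrateMap:
    """Weighted bipartite substrate→kinase annotation.

    Attributes
    ----------
    kinases : DataFrame with columns ``kinase_id``, ``family_group``.
    substrates : DataFrame with columns ``substrate_id``, ``chip_type``.
    edges : DataFrame with columns ``kinase_id``, ``substrate_id``, ``weight``
        (catalytic weight in (0, 1]).
    """

    kinases: pd.DataFrame
    substrates: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self):
        self.kinases = self.kinases.reset_index(drop=True)
        self.substrates = self.substrates.reset_index(drop=True)
        self.edges = self.edges.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        kin_ids = set(self.kinases["kinase_id"])
        sub_ids = set(self.substrates["substrate_id"])
        if len(kin_ids) != len(self.kinases):
            raise AnnotationError("duplicate kinase ids")
        if len(sub_ids) != len(self.substrates):
            raise AnnotationError("duplicate substrate ids")
        bad_fam = set(self.kinases["family_group"]) - set(FAMILY_GROUPS)
        if bad_fam:
            raise AnnotationError(f"unknown family groups: {sorted(bad_fam)}")
        bad_chip = set(self.substrates["chip_type"]) - set(CHIP_TYPES)
        if bad_chip:
            raise AnnotationError(f"unknown chip types: {sorted(bad_chip)}")
        dangling_k = set(self.edges["kinase_id"]) - kin_ids
        if dangling_k:
            raise AnnotationError(f"edges reference unknown kinases: {sorted(dangling_k)[:5]}")
        dangling_s = set(self.edges["substrate_id"]) - sub_ids
        if dangling_s:
            raise AnnotationError(f"edges reference unknown substrates: {sorted(dangling_s)[:5]}")
        dup = self.edges.duplicated(subset=["kinase_id", "substrate_id"])
        if dup.any():
            pair = self.edges.loc[dup.idxmax(), ["kinase_id", "substrate_id"]]
            raise AnnotationError(f"duplicate edge ({pair['kinase_id']}, {pair['substrate_id']})")
        w = self.edges["weight"].to_numpy(float)
        if not ((w > 0) & (w <= 1)).all():
            raise AnnotationError("edge weights must lie in (0, 1]")
        orphan = sub_ids - set(self.edges["substrate_id"])
        if orphan:
            raise AnnotationError(f"substrates without any kinase edge: {sorted(orphan)[:5]}")

    # -------------------------------------------------------------- accessors
    @property
    def n_substrates(self) -> int:
        return len(self.substrates)

    @property
    def n_kinases(self) -> int:
        return len(self.kinases)

    def substrates_per_chip(self) -> Dict[str, int]:
        return self.substrates["chip_type"].value_counts().to_dict()

    def chip_of(self) -> pd.Series:
        """substrate_id -> chip_type."""
        return self.substrates.set_index("substrate_id")["chip_type"]

    def family_of(self) -> pd.Series:
        """kinase_id -> family_group."""
        return self.kinases.set_index("kinase_id")["family_group"]

    def substrates_of(self, kinase_id: str) -> pd.DataFrame:
        """Edges of one kinase: columns substrate_id, weight."""
        return self.edges.loc[self.edges["kinase_id"] == kinase_id, ["substrate_id", "weight"]]

    def kinases_of(self, substrate_id: str) -> pd.DataFrame:
        return self.edges.loc[self.edges["substrate_id"] == substrate_id, ["kinase_id", "weight"]]

    def weight_matrix(self) -> Tuple[np.ndarray, pd.Index, pd.Index]:
        """Dense substrate × kinase weight matrix with its row/column indexes."""
        sub_index = pd.Index(self.substrates["substrate_id"], name="substrate_id")
        kin_index = pd.Index(self.kinases["kinase_id"], name="kinase_id")
        W = np.zeros((len(sub_index), len(kin_index)))
        si = sub_index.get_indexer(self.edges["substrate_id"])
        ki = kin_index.get_indexer(self.edges["kinase_id"])
        W[si, ki] = self.edges["weight"].to_numpy(float)
        return W, sub_index, kin_index

    # --------------------------------------------------------------------- IO
    def to_frame(self) -> pd.DataFrame:
        """Flat 5-column table (one row per edge)."""
        fam = self.family_of()
        chip = self.chip_of()
        out = self.edges.copy()
        out.insert(1, "family_group", fam.loc[out["kinase_id"]].to_numpy())
        out.insert(3, "chip_type", chip.loc[out["substrate_id"]].to_numpy())
        return out[list(ANNOTATION_COLUMNS)]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "KinaseSubstrateMap":
        missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
        if missing:
            raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")
        kinases = frame[["kinase_id", "family_group"]].drop_duplicates("kinase_id")
        conflict = frame[["kinase_id", "family_group"]].drop_duplicates()
        if len(conflict) != len(kinases):
            raise AnnotationError("a kinase appears with two family groups")
        substrates = frame[["substrate_id", "chip_type"]].drop_duplicates("substrate_id")
        s_conflict = frame[["substrate_id", "chip_type"]].drop_duplicates()
        if len(s_conflict) != len(substrates):
            raise AnnotationError("a substrate appears with two chip types")
        edges = frame[["kinase_id", "substrate_id", "weight"]].copy()
        return cls(kinases.reset_index(drop=True), substrates.reset_index(drop=True), edges)


def read_annotation(path) -> KinaseSubstrateMap:
    """Read a 5-column annotation TSV; errors name offending line numbers.

    Line numbers count the header as line 1.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")
    dup = frame.duplicated(subset=["kinase_id", "substrate_id"], keep="first")
    if dup.any():
        lines = [int(i) + 2 for i in frame.index[dup][:5]]
        raise AnnotationError(f"duplicate (kinase, substrate) edges at lines {lines}")
    bad_w = ~((frame["weight"] > 0) & (frame["weight"] <= 1))
    if bad_w.any():
        lines = [int(i) + 2 for i in frame.index[bad_w][:5]]
        raise AnnotationError(f"weights outside (0, 1] at lines {lines}")
    return KinaseSubstrateMap.from_frame(frame)


def write_annotation(amap: KinaseSubstrateMap, path) -> None:
    amap.to_tsv(path)


# --------------------------------------------------------------------------- #
# default fixture generator
# --------------------------------------------------------------------------- #


def build_default_annotation(seed: int = 0) -> KinaseSubstrateMap:
    """Generate the default annotation fixture, deterministic in ``seed``.

    Produces 196 PTK + 144 STK substrates and 520 kinases (190 tyrosine
    kinases, 330 serine/threonine-side kinases across TKL/STE/CK1/AGC/CAMK/
    CMGC/Other). Substrate in-degree is drawn from a truncated geometric
    distribution on 1..15; edge weights are Uniform(0.2, 1]. The named kinases
    used in downstream reports (ABL1, ABL2, INSR, SYK, DDR1, FRK, SRC, AKT1,
    AKT2, ERK1, GSK3, AMPKA1, AURA) are guaranteed realistic substrate sets
    (ABL1 ≥ 12 PTK substrates). Every kinase gets at least one substrate so
    the flat edge-table serialization round-trips losslessly.
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)

    kin_rows: List[Tuple[str, str]] = [(k, fam) for k, (fam, _) in NAMED_KINASES.items()]
    for fam in FAMILY_GROUPS:
        for i in range(_FILLER_COUNTS[fam]):
            kin_rows.append((f"{fam}{i + 1:03d}", fam))
    kinases = pd.DataFrame(kin_rows, columns=["kinase_id", "family_group"])

    sub_rows = [(f"PTK_{i + 1:03d}", "PTK") for i in range(196)]
    sub_rows += [(f"STK_{i + 1:03d}", "STK") for i in range(144)]
    substrates = pd.DataFrame(sub_rows, columns=["substrate_id", "chip_type"])

    pools = {
        chip: kinases.loc[kinases["family_group"].map(_chip_of_family) == chip, "kinase_id"].to_numpy()
        for chip in CHIP_TYPES
    }

    edge_set = set()
    edges: List[Tuple[str, str]] = []

    def add_edge(kin: str, sub: str) -> None:
        if (kin, sub) not in edge_set:
            edge_set.add((kin, sub))
            edges.append((kin, sub))

    for sub, chip in sub_rows:
        degree = int(rng.choice(_DEGREE_SUPPORT, p=_DEGREE_P))
        for kin in rng.choice(pools[chip], size=degree, replace=False):
            add_edge(str(kin), sub)

    # guarantee realistic substrate sets for the named report kinases
    chip_subs = {
        chip: substrates.loc[substrates["chip_type"] == chip, "substrate_id"].to_numpy()
        for chip in CHIP_TYPES
    }
    for kin, (fam, n_min) in NAMED_KINASES.items():
        chip = _chip_of_family(fam)
        have = {s for k, s in edges if k == kin}
        deficit = n_min - len(have)
        if deficit > 0:
            candidates = np.array([s for s in chip_subs[chip] if s not in have])
            for sub in rng.choice(candidates, size=deficit, replace=False):
                add_edge(kin, str(sub))

    # every kinase participates in at least one edge
    covered = {k for k, _ in edges}
    for kin, fam in kin_rows:
        if kin not in covered:
            chip = _chip_of_family(fam)
            sub = str(rng.choice(chip_subs[chip]))
            add_edge(kin, sub)

    edge_df = pd.DataFrame(edges, columns=["kinase_id", "substrate_id"])
    edge_df["weight"] = np.round(rng.uniform(0.2, 1.0, size=len(edge_df)), 6)
    edge_df = edge_df.sort_values(["substrate_id", "kinase_id"], kind="mergesort").reset_index(drop=True)
    return KinaseSubstrateMap(kinases, substrates, edge_df)
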