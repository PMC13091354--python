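"""Per-substrate differential statistics between conditions.

Contrasts are paired on the log2 scale: tumor vs. adjacent tissue within each
patient, or drug vs. vehicle within each sample. The per-substrate statistic
is the mean log2 fold change (LFC) across pairs, with a waterfall flag at
|mean LFC| ≥ 0.2 (inclusive) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .errors import ContrastError, InvalidParameterError, PairingError
from .quantify import QuantifiedSignalMatrix

DEFAULT_LFC_THRESHOLD = 0.2


@dataclass
class SubstrateStats:
    """Per-substrate paired LFCs.

    ``per_pair`` has substrates in rows and one column per pair (patient, or
    sample unit for treatment contrasts); ``mean_lfc`` is its row mean and the
    flag marks |mean LFC| ≥ threshold (inclusive).
    """

    per_pair: pd.DataFrame
    chip: pd.Series
    contrast: Tuple[str, str]
    threshold: float = DEFAULT_LFC_THRESHOLD

    @property
    def mean_lfc(self) -> pd.Series:
        return self.per_pair.mean(axis=1)

    @property
    def n_pairs(self) -> int:
        return self.per_pair.shape[1]

    def table(self) -> pd.DataFrame:
        mean = self.mean_lfc
        return pd.DataFrame(
            {
                "substrate_id": self.per_pair.index,
                "chip_type": self.chip.loc[self.per_pair.index].to_numpy(),
                "mean_lfc": mean.to_numpy(),
                "n_pairs": self.n_pairs,
                "flag": (mean.abs() >= self.threshold).to_numpy(),
            }
        ).reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False, float_format="%.9g")


def paired_lfc(
    matrix: QuantifiedSignalMatrix,
    treatment: str = "vehicle",
    sex: Optional[str] = None,
    tissues: Tuple[str, str] = ("tumor", "adjacent"),
    threshold: float = DEFAULT_LFC_THRESHOLD,
) -> SubstrateStats:
    """Tumor-vs-adjacent LFC per substrate, paired within patients.

    The matrix must be on the log2 scale. With ``sex`` given, only patients of
    that sex contribute pairs.
    """
    if matrix.transform != "log2":
        raise InvalidParameterError("paired_lfc requires a log2-scale matrix")
    case, control = tissues
    cols = matrix.values.columns
    patients = sorted({p for p, _, t in cols if t == treatment})
    if sex is not None:
        sex_of = matrix.samples.set_index("patient_id")["sex"]
        patients = [p for p in patients if sex_of.get(p) == sex]
    lfcs = {}
    for p in patients:
        have = {ti for pp, ti, t in cols if pp == p and t == treatment}
        if case not in have or control not in have:
            raise PairingError(f"patient {p!r} lacks a {case}/{control} pair")
        lfcs[p] = matrix.values[(p, case, treatment)] - matrix.values[(p, control, treatment)]
    per_pair = pd.DataFrame(lfcs, index=matrix.values.index)
    return SubstrateStats(per_pair, matrix.chip, (case, control), threshold)


def treatment_lfc(
    matrix: QuantifiedSignalMatrix,
    vehicle_label: str,
    drug_label: str,
    tissue: Optional[str] = "tumor",
    threshold: float = DEFAULT_LFC_THRESHOLD,
) -> SubstrateStats:
    """Drug-vs-vehicle LFC per substrate, paired within sample units."""
    if matrix.transform != "log2":
        raise InvalidParameterError("treatment_lfc requires a log2-scale matrix")
    cols = matrix.values.columns
    for label in (vehicle_label, drug_label):
        if not any(t == label for _, _, t in cols):
            raise ContrastError(f"treatment label {label!r} absent from matrix")
    units = sorted(
        {
            (p, ti)
            for p, ti, t in cols
            if t == drug_label and (tissue is None or ti == tissue) and (p, ti, vehicle_label) in cols
        }
    )
    if not units:
        raise ContrastError(f"no sample unit carries both {drug_label!r} and {vehicle_label!r}")
    lfcs = {}
    for p, ti in units:
        lfcs[f"{p}|{ti}"] = matrix.values[(p, ti, drug_label)] - matrix.values[(p, ti, vehicle_label)]
    per_pair = pd.DataFrame(lfcs, index=matrix.values.index)
    return SubstrateStats(per_pair, matrix.chip, (drug_label, vehicle_label), threshold)


def flag_substrates(stats: SubstrateStats, threshold: Optional[float] = None) -> pd.DataFrame:
    """Substrates with |mean LFC| ≥ threshold, in waterfall (signed descending)
    order."""
    thr = stats.threshold if threshold is None else threshold
    if thr <= 0:
        raise InvalidParameterError("threshold must be > 0")
    tbl = stats.table()
    tbl["flag"] = tbl["mean_lfc"].abs() >= thr
    out = tbl[tbl["flag"]].sort_values("mean_lfc", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


def heatmap_matrix(
    values: pd.DataFrame,
    row_scaling: str = "none",
    cluster: bool = True,
) -> Tuple[pd.DataFrame, List[str]]:
    """Plot-ready heat-map table: optional row z-scoring and hierarchical row
    ordering (correlation distance, average linkage).

    Returns the reordered table and the list of substrates whose rows were
    constant (emitted as zeros under z-scoring, with a warning flag).
    """
    if row_scaling not in ("none", "zscore"):
        raise InvalidParameterError(f"unknown row_scaling {row_scaling!r}")
    X = values.to_numpy(float)
    sd = X.std(axis=1, ddof=0)
    constant = sd == 0
    warned = list(values.index[constant])
    if row_scaling == "zscore":
        mu = X.mean(axis=1, keepdims=True)
        denom = np.where(constant, 1.0, sd)[:, None]
        X = np.where(constant[:, None], 0.0, (X - mu) / denom)
    out = pd.DataFrame(X, index=values.index, columns=values.columns)
    if cluster and len(out) > 2:
        D = ssd.pdist(out.to_numpy(float), metric="correlation")
        D = np.nan_to_num(D, nan=1.0)  # constant rows correlate with nothing
        order = sch.leaves_list(sch.linkage(D, method="average"))
        out = out.iloc[order]
    return out, warned
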