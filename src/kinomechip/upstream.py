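"""Upstream kinase inference from substrate statistics.

Given per-substrate log2 fold changes and a substrate→kinase annotation, each
kinase is scored by the mean LFC of its mapped substrates and standardized
against nulls:

* **sampling Z** — the null draws random substrate sets of the same size
  (without replacement, uniform over the measured panel of the same chip
  type) and recomputes the statistic; ``z = (observed − null mean)/null sd``.
  An exhaustive enumeration over all size-m subsets is provided as the exact
  oracle for small panels.
* **two-component ranking** — a documented approximation of hierarchical
  upstream-kinase ratings: a *specificity* Z against the substrate-sampling
  null plus a *significance* Z against a sign-flip null over the paired LFCs
  (appropriate because contrasts are paired). The final score is
  ``sign(stat) × mean(|specificity Z|, |significance Z|)`` and kinases are
  ranked by its magnitude. The construction is fully reproducible but is not
  a numeric clone of any proprietary tool.

Sampling is always within chip type: PTK and STK runs are separate chips, so
a tyrosine kinase is only ever compared against the PTK substrate panel.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import KinaseSubstrateMap
from .errors import DegenerateNullError, SizeError, UnscorableError
from .stats import SubstrateStats

TREE_COLUMNS = ("kinase_id", "family_group", "activity", "significance")


class ConfigWarning(UserWarning):
    """Non-fatal configuration problem (e.g. too few permutations)."""


@dataclass(frozen=True)
class ZScore:
    """A kinase statistic standardized against a substrate-sampling null."""

    kinase_id: str
    m: int
    stat: float
    z: float
    null_mean: float
    null_sd: float


def _measured_panel(stats: SubstrateStats, chip: str) -> pd.Series:
    """Measured substrates (finite mean LFC) of one chip, sorted by id so all
    scores are invariant to input row order."""
    mean = stats.mean_lfc
    chips = stats.chip.loc[mean.index]
    panel = mean[(chips == chip) & mean.notna()]
    return panel.sort_index()


def _mapped_measured(
    stats: SubstrateStats, amap: KinaseSubstrateMap, kinase: str
) -> Tuple[str, pd.Series]:
    """(chip, panel-restricted mean LFCs of the kinase's substrates)."""
    mapped = amap.substrates_of(kinase)["substrate_id"]
    if len(mapped) == 0:
        raise UnscorableError(f"kinase {kinase!r} has no mapped substrates")
    chip_of = amap.chip_of()
    chips = sorted(set(chip_of.loc[mapped]))
    # pick the chip where the kinase has the most measured substrates
    best: Tuple[int, str, pd.Series] = (-1, "", pd.Series(dtype=float))
    for chip in chips:
        panel = _measured_panel(stats, chip)
        sel = panel.loc[panel.index.intersection(mapped)]
        if len(sel) > best[0]:
            best = (len(sel), chip, sel)
    if best[0] <= 0:
        raise UnscorableError(f"kinase {kinase!r} has no measured substrates")
    return best[1], best[2].sort_index()


def kinase_statistic(stats: SubstrateStats, amap: KinaseSubstrateMap, kinase: str) -> float:
    """Mean LFC over a kinase's mapped, measured substrates."""
    _, sel = _mapped_measured(stats, amap, kinase)
    return float(sel.mean())


def _subset_mean_null(values: np.ndarray, m: int, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Means of ``n_iter`` random size-m subsets drawn without replacement."""
    idx = np.argsort(rng.random((n_iter, values.size)), axis=1)[:, :m]
    return values[idx].mean(axis=1)


def sampling_z(
    stats: SubstrateStats,
    amap: KinaseSubstrateMap,
    kinase: str,
    n_iter: int = 2000,
    seed: int = 0,
    min_substrates: int = 3,
) -> ZScore:
    """Sampling-null Z-score of one kinase's mean-LFC statistic."""
    chip, sel = _mapped_measured(stats, amap, kinase)
    m = len(sel)
    if m < min_substrates:
        raise UnscorableError(f"kinase {kinase!r}: m={m} < min_substrates={min_substrates}")
    panel = _measured_panel(stats, chip)
    if len(panel) <= m:
        raise SizeError(f"panel of {len(panel)} does not exceed m={m}")
    rng = np.random.default_rng(seed)
    null = _subset_mean_null(panel.to_numpy(), m, n_iter, rng)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise DegenerateNullError(
            f"kinase {kinase!r}: sampling null has zero variance "
            f"(panel LFCs are degenerate; panel sd={panel.std(ddof=0):.3g})"
        )
    stat = float(sel.mean())
    return ZScore(kinase, m, stat, (stat - mu) / sd, mu, sd)


def exhaustive_z(
    stats: SubstrateStats,
    amap: KinaseSubstrateMap,
    kinase: str,
    max_combinations: int = 200_000,
) -> ZScore:
    """Exact Z against the enumerated null over every size-m subset."""
    chip, sel = _mapped_measured(stats, amap, kinase)
    m = len(sel)
    panel = _measured_panel(stats, chip).to_numpy()
    n = panel.size
    if m >= n:
        raise SizeError(f"m={m} must be smaller than the panel ({n})")
    n_comb = math.comb(n, m)
    if n_comb > max_combinations:
        raise SizeError(f"C({n},{m})={n_comb} exceeds the bound {max_combinations}")
    idx = np.fromiter(itertools.chain.from_iterable(itertools.combinations(range(n), m)), dtype=np.intp)
    means = panel[idx.reshape(n_comb, m)].mean(axis=1)
    mu, sd = float(means.mean()), float(means.std(ddof=0))
    if sd == 0:
        raise DegenerateNullError(f"kinase {kinase!r}: exhaustive null has zero variance")
    stat = float(sel.mean())
    return ZScore(kinase, m, stat, (stat - mu) / sd, mu, sd)


def _scorable_kinases(
    stats: SubstrateStats, amap: KinaseSubstrateMap, min_substrates: int
) -> List[Tuple[str, str, pd.Series]]:
    """(kinase, chip, mapped measured LFCs) for every scorable kinase."""
    out = []
    for kinase in amap.kinases["kinase_id"]:
        try:
            chip, sel = _mapped_measured(stats, amap, kinase)
        except UnscorableError:
            continue
        if len(sel) >= min_substrates:
            out.append((kinase, chip, sel))
    return out


def score_kinases_z(
    stats: SubstrateStats,
    amap: KinaseSubstrateMap,
    n_iter: int = 2000,
    seed: int = 0,
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Sampling-null Z-scores for every scorable kinase (waterfall-ready).

    Null draws are shared between kinases with the same chip and substrate
    count, which makes panel-wide scoring fast without changing the null.
    Kinases whose null is degenerate get ``z = NaN``.
    """
    rng = np.random.default_rng(seed)
    fam = amap.family_of()
    entries = _scorable_kinases(stats, amap, min_substrates)
    panels = {chip: _measured_panel(stats, chip) for chip in sorted({c for _, c, _ in entries})}
    null_moments: Dict[Tuple[str, int], Tuple[float, float]] = {}
    for chip in sorted(panels):
        values = panels[chip].to_numpy()
        for m in sorted({len(sel) for _, c, sel in entries if c == chip}):
            if len(values) <= m:
                continue
            null = _subset_mean_null(values, m, n_iter, rng)
            null_moments[(chip, m)] = (float(null.mean()), float(null.std(ddof=1)))
    rows = []
    for kinase, chip, sel in entries:
        m = len(sel)
        stat = float(sel.mean())
        mu_sd = null_moments.get((chip, m))
        if mu_sd is None or mu_sd[1] == 0:
            z = np.nan
        else:
            z = (stat - mu_sd[0]) / mu_sd[1]
        rows.append((kinase, fam.loc[kinase], chip, m, stat, z))
    out = pd.DataFrame(rows, columns=["kinase_id", "family_group", "chip_type", "m", "stat", "z"])
    out = out.sort_values("z", ascending=False, kind="mergesort").reset_index(drop=True)
    return out


def uka_rank(
    stats: SubstrateStats,
    amap: KinaseSubstrateMap,
    n_perm: int = 500,
    n_iter: int = 2000,
    seed: int = 0,
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Two-component upstream-kinase ranking.

    Columns: kinase_id, family_group, chip_type, m, stat, specificity_z,
    significance_z, final_score, rank. Ranked by |final_score| descending;
    ties break toward larger m, then lexicographic kinase id. Degenerate
    nulls with a statistic equal to the null mean score zero for that
    component.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100 gives a coarse significance null", ConfigWarning, stacklevel=2
        )
    rng = np.random.default_rng(seed)
    fam = amap.family_of()
    entries = _scorable_kinases(stats, amap, min_substrates)
    chips = sorted({c for _, c, _ in entries})
    panels = {chip: _measured_panel(stats, chip) for chip in chips}

    null_moments: Dict[Tuple[str, int], Tuple[float, float]] = {}
    for chip in chips:
        values = panels[chip].to_numpy()
        for m in sorted({len(sel) for _, c, sel in entries if c == chip}):
            if len(values) <= m:
                continue
            null = _subset_mean_null(values, m, n_iter, rng)
            null_moments[(chip, m)] = (float(null.mean()), float(null.std(ddof=1)))

    # one sign-flip matrix per chip, shared across kinases
    n_pairs = stats.per_pair.shape[1]
    signs = {chip: rng.choice([-1.0, 1.0], size=(n_perm, n_pairs)) for chip in chips}

    def _component_z(obs: float, mu: float, sd: float, label: str, kinase: str) -> float:
        if sd == 0:
            if obs == mu:
                return 0.0
            raise DegenerateNullError(f"kinase {kinase!r}: degenerate {label} null")
        return (obs - mu) / sd

    rows = []
    for kinase, chip, sel in entries:
        m = len(sel)
        stat = float(sel.mean())
        mu_sd = null_moments.get((chip, m))
        if mu_sd is None:
            continue
        spec_z = _component_z(stat, mu_sd[0], mu_sd[1], "specificity", kinase)

        pairmeans = stats.per_pair.loc[sel.index].mean(axis=0).to_numpy(float)
        obs = float(pairmeans.mean())
        null = signs[chip] @ pairmeans / n_pairs
        sig_z = _component_z(obs, float(null.mean()), float(null.std(ddof=1)), "significance", kinase)

        final = float(np.sign(stat)) * 0.5 * (abs(spec_z) + abs(sig_z))
        rows.append((kinase, fam.loc[kinase], chip, m, stat, spec_z, sig_z, final))

    out = pd.DataFrame(
        rows,
        columns=[
            "kinase_id",
            "family_group",
            "chip_type",
            "m",
            "stat",
            "specificity_z",
            "significance_z",
            "final_score",
        ],
    )
    out["abs_final"] = out["final_score"].abs()
    out = out.sort_values(
        ["abs_final", "m", "kinase_id"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="abs_final")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def kinome_tree_export(scores: pd.DataFrame, amap: Optional[KinaseSubstrateMap] = None) -> pd.DataFrame:
    """Annotation table for kinome-tree renderers.

    One row per scored kinase: id, family group (branch color), activity
    (node color = the kinase statistic) and significance (node size =
    |final_score|, or |z| for Z-mode tables). Kinases without a family label
    are assigned "Other" with a warning.
    """
    fam = scores.get("family_group")
    if fam is None and amap is not None:
        fam = amap.family_of().reindex(scores["kinase_id"]).to_numpy()
    if fam is None:
        warnings.warn("no family labels available; assigning 'Other'", ConfigWarning, stacklevel=2)
        fam = pd.Series(["Other"] * len(scores))
    fam = pd.Series(np.asarray(fam), index=scores.index)
    if fam.isna().any():
        warnings.warn("kinases without family labels assigned 'Other'", ConfigWarning, stacklevel=2)
        fam = fam.fillna("Other")
    size_col = "final_score" if "final_score" in scores.columns else "z"
    return pd.DataFrame(
        {
            "kinase_id": scores["kinase_id"].to_numpy(),
            "family_group": fam.to_numpy(),
            "activity": scores["stat"].to_numpy(),
            "significance": scores[size_col].abs().to_numpy(),
        }
    )


def write_tree_tsv(tree: pd.DataFrame, path) -> None:
    tree.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_tree_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
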