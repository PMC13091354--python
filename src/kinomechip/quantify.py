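"""Quantification: raw cycle × exposure intensities → one activity value per
substrate per sample-treatment, with QC flags.

The per-spot statistic is the *exposure slope*: the background-corrected
least-squares slope through the origin of intensity vs. camera exposure,
refit after discarding saturated reads. Slopes are computed per cycle; the
reported value is the *end-level* (mean slope over the final cycles, default
window 10), matching final-cycle imaging of the real-time curve. Replicates
are collapsed by arithmetic mean after quantification; an initial-rate mode
(mean over the first cycles) is available behind a switch.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import AssayDesign
from .errors import (
    AllSaturatedError,
    ConfigError,
    InvalidParameterError,
    StructuralError,
)

QC_FLAGS = ("ok", "saturated", "low_signal", "high_cv")

_KEY_COLS = ["substrate_id", "patient_id", "tissue", "treatment", "replicate"]


def fit_exposure_slope(
    intensities: Sequence[float],
    exposures: Sequence[float],
    saturation: float,
    background: float = 0.0,
) -> float:
    """Background-corrected through-origin slope of intensity vs. exposure.

    Points at or above ``saturation`` are excluded before the fit; at least
    two unsaturated points must survive.
    """
    y = np.asarray(intensities, dtype=float)
    e = np.asarray(exposures, dtype=float)
    if y.shape != e.shape or y.size < 2:
        raise InvalidParameterError("need equal-length intensity/exposure lists of length >= 2")
    if np.any(np.diff(e) <= 0):
        raise InvalidParameterError("exposures must be strictly increasing")
    mask = y < saturation
    if mask.sum() < 2:
        raise AllSaturatedError("fewer than 2 unsaturated exposure points")
    ym = y[mask] - background
    em = e[mask]
    return float(np.dot(em, ym) / np.dot(em, em))


def kinetic_endlevel(series: Sequence[float], window: int = 10) -> float:
    """Mean of the last ``window`` per-cycle slopes of a kinetic series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise InvalidParameterError("empty series")
    if not (1 <= window <= x.size):
        raise InvalidParameterError(f"window must lie in [1, {x.size}]")
    return float(x[-window:].mean())


@dataclass(frozen=True)
class QuantifyParams:
    """Tunables of the quantification stage.

    ``statistic`` selects the summary over the kinetic curve: ``endlevel``
    (mean slope over the last ``window`` cycles) or ``initial_rate`` (mean
    over the first ``window``). ``low_signal_floor`` is in AU/ms;
    ``high_cv_threshold`` applies to the replicate coefficient of variation.
    """

    window: int = 10
    statistic: str = "endlevel"
    low_signal_floor: float = 0.01
    high_cv_threshold: float = 0.5
    log2_floor: float = 1e-3

    def __post_init__(self):
        if self.statistic not in ("endlevel", "initial_rate"):
            raise ConfigError(f"unknown statistic {self.statistic!r}")
        if self.window < 1:
            raise ConfigError("window must be >= 1")


@dataclass
class QuantifiedSignalMatrix:
    """Substrate × (patient, tissue, treatment) matrix of quantified signals.

    ``values`` rows are substrates, columns a (patient_id, tissue, treatment)
    MultiIndex; linear cells are exposure slopes in AU/ms with the design
    background already removed by the through-origin fit. ``qc`` holds one
    flag per cell from :data:`QC_FLAGS`. ``samples`` records patient sex.
    """

    values: pd.DataFrame
    qc: pd.DataFrame
    chip: pd.Series  # substrate_id -> chip_type
    samples: pd.DataFrame  # patient_id, sex
    transform: str = "linear"
    n_replicates: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.transform not in ("linear", "log2"):
            raise InvalidParameterError(f"unknown transform {self.transform!r}")
        if self.values.shape != self.qc.shape:
            raise InvalidParameterError("values and qc shapes differ")

    def to_log2(self, floor: Optional[float] = None) -> "QuantifiedSignalMatrix":
        """Return a log2 view; cells are floored at ``log2_floor`` AU/ms so
        every log cell is finite."""
        if self.transform == "log2":
            return self
        eps = floor if floor is not None else self.meta.get("log2_floor", 1e-3)
        vals = np.log2(np.maximum(self.values, eps))
        meta = dict(self.meta, log2_floor=eps)
        return QuantifiedSignalMatrix(
            vals, self.qc.copy(), self.chip, self.samples, "log2", self.n_replicates, meta
        )

    def flag_counts(self) -> Dict[str, int]:
        counts = pd.Series(self.qc.to_numpy().ravel()).value_counts().to_dict()
        return {f: int(counts.get(f, 0)) for f in QC_FLAGS}

    # --------------------------------------------------------------------- IO
    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flat = self.values.copy()
        flat.columns = ["|".join(c) for c in self.values.columns]
        flat.insert(0, "chip_type", self.chip.loc[self.values.index].to_numpy())
        flat.to_csv(out / "matrix.tsv", sep="\t", float_format="%.9g")
        qc = self.qc.copy()
        qc.columns = flat.columns[1:]
        qc.to_csv(out / "qc.tsv", sep="\t")
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        meta = dict(self.meta, transform=self.transform, n_replicates=self.n_replicates)
        (out / "matrix_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, in_dir) -> "QuantifiedSignalMatrix":
        src = Path(in_dir)
        flat = pd.read_csv(src / "matrix.tsv", sep="\t", index_col=0)
        chip = flat.pop("chip_type")
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split("|")) for c in flat.columns], names=["patient_id", "tissue", "treatment"]
        )
        flat.columns = cols
        qc = pd.read_csv(src / "qc.tsv", sep="\t", index_col=0)
        qc.columns = cols
        samples = pd.read_csv(src / "samples.tsv", sep="\t")
        meta = json.loads((src / "matrix_meta.json").read_text())
        transform = meta.pop("transform")
        n_rep = meta.pop("n_replicates")
        return cls(flat, qc, chip, samples, transform, n_rep, meta)


def _first_missing_key(chip_df: pd.DataFrame, dims: Dict[str, np.ndarray]) -> tuple:
    """Locate one missing grid cell for the structural error message."""
    full = pd.MultiIndex.from_product(list(dims.values()), names=list(dims))
    have = pd.MultiIndex.from_frame(chip_df[list(dims)])
    missing = full.difference(have)
    return tuple(missing[0]) if len(missing) else ()


def quantify(
    raw: pd.DataFrame,
    design: AssayDesign,
    params: QuantifyParams = QuantifyParams(),
) -> QuantifiedSignalMatrix:
    """Quantify a grid-complete raw table into one value per substrate/sample.

    Per (substrate, sample, treatment, replicate): exposure slope per cycle →
    end-level (or initial rate) → replicate mean. QC flags: ``saturated`` when
    a window cycle has < 2 unsaturated exposures in some replicate,
    ``low_signal`` below the floor, ``high_cv`` above the replicate-CV
    threshold; precedence saturated > low_signal > high_cv.
    """
    required = set(_KEY_COLS + ["chip_type", "cycle", "exposure_ms", "intensity", "sex"])
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise StructuralError(f"raw table missing columns: {sorted(missing_cols)}")

    exposures = np.asarray(sorted(raw["exposure_ms"].unique()), dtype=float)
    sat = design.saturation_level
    bg = design.background_level

    blocks = []
    qc_blocks = []
    chips = []
    n_rep = int(raw["replicate"].nunique())
    for chip in sorted(raw["chip_type"].unique()):
        cdf = raw[raw["chip_type"] == chip]
        dims = {
            "substrate_id": np.asarray(sorted(cdf["substrate_id"].unique())),
            "patient_id": np.asarray(sorted(cdf["patient_id"].unique())),
            "tissue": np.asarray(sorted(cdf["tissue"].unique())),
            "treatment": np.asarray(sorted(cdf["treatment"].unique())),
            "replicate": np.asarray(sorted(cdf["replicate"].unique())),
            "cycle": np.asarray(sorted(cdf["cycle"].unique())),
            "exposure_ms": np.asarray(sorted(cdf["exposure_ms"].unique())),
        }
        expected = int(np.prod([len(v) for v in dims.values()]))
        if len(cdf) != expected:
            key = _first_missing_key(cdf, dims)
            raise StructuralError(
                f"{chip}: raw table is not grid-complete "
                f"({len(cdf)} rows, expected {expected}); first missing key: {key}"
            )
        codes = np.zeros(len(cdf), dtype=np.int64)
        for name, values in dims.items():
            idx = pd.Index(values)
            codes = codes * len(values) + idx.get_indexer(cdf[name])
        if len(np.unique(codes)) != len(codes):
            raise StructuralError(f"{chip}: duplicate measurement rows present")
        order = np.argsort(codes, kind="stable")
        shape = tuple(len(v) for v in dims.values())
        I = cdf["intensity"].to_numpy(float)[order].reshape(shape)  # (S,U,Ti,T,R,C,E)

        e = dims["exposure_ms"]
        mask = I < sat
        num = np.einsum("...e,e->...", np.where(mask, I - bg, 0.0), e)
        den = np.einsum("...e,e->...", mask.astype(float), e**2)
        ok = mask.sum(axis=-1) >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            slopes = np.where(ok, num / np.where(den > 0, den, 1.0), np.nan)  # (S,U,Ti,T,R,C)

        w = min(params.window, slopes.shape[-1])
        sl = slopes[..., -w:] if params.statistic == "endlevel" else slopes[..., :w]
        per_rep = sl.mean(axis=-1)  # NaN if any window cycle saturated; (S,U,Ti,T,R)

        value = per_rep.mean(axis=-1)  # (S,U,Ti,T)
        if per_rep.shape[-1] > 1:
            sd = per_rep.std(axis=-1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cv = np.where(np.abs(value) > 0, sd / np.abs(value), 0.0)
        else:
            cv = np.zeros_like(value)

        flags = np.full(value.shape, "ok", dtype=object)
        flags[cv > params.high_cv_threshold] = "high_cv"
        flags[np.abs(value) < params.low_signal_floor] = "low_signal"
        flags[np.isnan(value)] = "saturated"

        n_s = len(dims["substrate_id"])
        col_index = pd.MultiIndex.from_product(
            [dims["patient_id"], dims["tissue"], dims["treatment"]],
            names=["patient_id", "tissue", "treatment"],
        )
        blocks.append(
            pd.DataFrame(value.reshape(n_s, -1), index=dims["substrate_id"], columns=col_index)
        )
        qc_blocks.append(
            pd.DataFrame(flags.reshape(n_s, -1), index=dims["substrate_id"], columns=col_index)
        )
        chips.append(pd.Series(chip, index=dims["substrate_id"]))

    values = pd.concat(blocks)
    qc = pd.concat(qc_blocks)
    chip_series = pd.concat(chips)
    chip_series.name = "chip_type"
    values.index.name = "substrate_id"
    qc.index.name = "substrate_id"
    samples = raw[["patient_id", "sex"]].drop_duplicates().sort_values("patient_id")
    samples = samples.astype(str).reset_index(drop=True)
    meta = dict(asdict(params), background_level=bg, saturation_level=sat)
    return QuantifiedSignalMatrix(values, qc, chip_series, samples, "linear", n_rep, meta)


def qc_filter(
    matrix: QuantifiedSignalMatrix, policy: str = "mask_cell"
) -> Tuple[QuantifiedSignalMatrix, Dict[str, int]]:
    """Apply a QC policy and return (filtered matrix, flag-count report).

    Policies: ``mask_cell`` (non-ok cells → NaN), ``drop_substrate`` (drop the
    whole row when any cell is non-ok), ``keep`` (no change).
    """
    if policy not in ("mask_cell", "drop_substrate", "keep"):
        raise ConfigError(f"unknown QC policy {policy!r}")
    report = matrix.flag_counts()
    report["policy"] = policy  # type: ignore[assignment]
    bad = matrix.qc != "ok"
    if policy == "keep" or not bad.to_numpy().any():
        return matrix, report
    if policy == "mask_cell":
        values = matrix.values.mask(bad)
        qc = matrix.qc
        chip = matrix.chip
    else:
        keep_rows = ~bad.any(axis=1)
        values = matrix.values.loc[keep_rows]
        qc = matrix.qc.loc[keep_rows]
        chip = matrix.chip.loc[values.index]
    out = QuantifiedSignalMatrix(
        values, qc.copy(), chip, matrix.samples, matrix.transform, matrix.n_replicates, dict(matrix.meta)
    )
    return out, report
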