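"""Configuration and the end-to-end pipeline.

One YAML config drives the whole workflow: simulate (optional) → quantify →
substrate stats → upstream kinase scores → drug trial. Every stage writes a
plain TSV/JSON artifact into the run directory, floats serialized with 9
significant digits, plus the resolved config, a ``run_meta.json`` carrying
the package version / seed / config hash, and a ``run.log`` with stage
timings. All data artifacts are byte-deterministic given config + seed; only
the log (wall times) varies between runs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from . import __version__
from .annotation import KinaseSubstrateMap, build_default_annotation, read_annotation
from .design import AssayDesign, CohortDesign, Drug, DrugPanel
from .errors import ConfigError, PipelineStageError
from .groundtruth import NoiseModel, default_ground_truth
from .permed import TrialParams, run_trial, write_trial_json, write_trial_tsv
from .quantify import QuantifiedSignalMatrix, QuantifyParams, quantify
from .simulate import simulate_signals, write_raw
from .stats import heatmap_matrix, paired_lfc
from .upstream import kinome_tree_export, score_kinases_z, uka_rank, write_tree_tsv

_TOP_KEYS = {
    "seed",
    "out_dir",
    "annotation",
    "design",
    "cohort",
    "truth",
    "panel",
    "simulate",
    "quantify",
    "stats",
    "uka",
    "trial",
}
_SECTION_KEYS = {
    "annotation": {"path", "seed"},
    "design": {
        "substrates_per_chip",
        "cycles_per_chip",
        "exposure_times",
        "saturation_level",
        "background_level",
    },
    "cohort": {"patients", "tissues", "technical_replicates", "pooled"},
    "truth": {"noise", "patient_sd", "non_responders", "seed"},
    "panel": {"drugs", "vehicle_label"},
    "simulate": {"enabled", "write_raw"},
    "quantify": {"window", "statistic", "low_signal_floor", "high_cv_threshold", "log2_floor"},
    "stats": {"lfc_threshold", "treatment", "row_scaling"},
    "uka": {"mode", "n_iter", "n_perm", "min_substrates"},
    "trial": {"off_target_threshold", "epsilon", "min_substrates", "tissue"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; ``raw`` keeps the resolved mapping."""

    seed: int
    raw: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: Dict[str, Any]) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SECTION_KEYS.items():
            sub = data.get(section)
            if sub is None:
                continue
            if not isinstance(sub, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(f"unknown keys in section {section!r}: {sorted(bad)}")
        if "seed" not in data:
            raise ConfigError("config must set a seed (stochastic stages require it)")
        seed = data["seed"]
        if not isinstance(seed, int) or seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        return cls(seed=seed, raw=dict(data))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def section(self, name: str) -> Dict[str, Any]:
        return dict(self.raw.get(name) or {})

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()[:16]


def _build_design(cfg: PipelineConfig) -> AssayDesign:
    return AssayDesign(**cfg.section("design"))


def _build_cohort(cfg: PipelineConfig) -> CohortDesign:
    sec = cfg.section("cohort")
    if "patients" in sec:
        sec["patients"] = [tuple(p) for p in sec["patients"]]
    return CohortDesign(**sec)


def _build_panel(cfg: PipelineConfig) -> DrugPanel:
    sec = cfg.section("panel")
    if "drugs" in sec:
        sec["drugs"] = [Drug(d["drug_id"], d["nominal_target"], float(d["concentration_nm"])) for d in sec["drugs"]]
    return DrugPanel(**sec)


def _build_annotation(cfg: PipelineConfig) -> KinaseSubstrateMap:
    sec = cfg.section("annotation")
    if "path" in sec:
        return read_annotation(sec["path"])
    return build_default_annotation(int(sec.get("seed", cfg.seed)))


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full workflow into ``out_dir`` and return its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t_start = time.perf_counter()

    def log(msg: str) -> None:
        line = f"[kinomechip] {msg}"
        print(line, file=sys.stderr)
        log_lines.append(line)

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(f"stage {name}: FAILED ({exc})")
                    raise PipelineStageError(name, exc) from exc
                log(f"stage {name}: done in {time.perf_counter() - self.t0:.2f}s")
                return False

        return _Stage()

    (out / "config.yaml").write_text(config.canonical_yaml())
    log(f"config hash {config.config_hash()}, seed {config.seed}")

    with stage("annotation"):
        amap = _build_annotation(config)
        amap.to_tsv(out / "annotation.tsv")
        design = _build_design(config)
        cohort = _build_cohort(config)
        panel = _build_panel(config)

    sim_sec = config.section("simulate")
    with stage("simulate"):
        truth_sec = config.section("truth")
        noise_sec = truth_sec.get("noise") or {}
        noise = NoiseModel(**noise_sec) if noise_sec else None
        non_resp = {
            (entry["patient_id"], entry["drug_id"]): entry["kinase_id"]
            for entry in truth_sec.get("non_responders") or []
        }
        truth = default_ground_truth(
            amap,
            cohort,
            panel,
            seed=int(truth_sec.get("seed", config.seed)),
            noise=noise,
            patient_sd=float(truth_sec.get("patient_sd", 0.2)),
            non_responders=non_resp,
        )
        raw = simulate_signals(design, amap, truth, cohort, panel, config.seed)
        if sim_sec.get("write_raw", False):
            write_raw(raw, out / "raw_signals.tsv.gz")

    with stage("quantify"):
        qsec = config.section("quantify")
        qparams = QuantifyParams(**qsec)
        matrix = quantify(raw, design, qparams)
        matrix.write(out)

    stats_sec = config.section("stats")
    with stage("stats"):
        log2 = matrix.to_log2()
        threshold = float(stats_sec.get("lfc_threshold", 0.2))
        stats = paired_lfc(
            log2,
            treatment=stats_sec.get("treatment", panel.vehicle_label),
            threshold=threshold,
        )
        stats.write_tsv(out / "substrate_stats.tsv")
        ordered, _ = heatmap_matrix(log2.values, row_scaling=stats_sec.get("row_scaling", "zscore"))
        flat = ordered.copy()
        flat.columns = ["|".join(c) for c in ordered.columns]
        flat.to_csv(out / "heatmap.tsv", sep="\t", float_format="%.9g")

    uka_sec = config.section("uka")
    with stage("uka"):
        mode = uka_sec.get("mode", "uka")
        if mode == "z":
            scores = score_kinases_z(
                stats,
                amap,
                n_iter=int(uka_sec.get("n_iter", 2000)),
                seed=config.seed,
                min_substrates=int(uka_sec.get("min_substrates", 3)),
            )
        elif mode == "uka":
            scores = uka_rank(
                stats,
                amap,
                n_perm=int(uka_sec.get("n_perm", 500)),
                n_iter=int(uka_sec.get("n_iter", 2000)),
                seed=config.seed,
                min_substrates=int(uka_sec.get("min_substrates", 3)),
            )
        else:
            raise ConfigError(f"unknown uka mode {mode!r}")
        scores.to_csv(out / "kinase_scores.tsv", sep="\t", index=False, float_format="%.9g")
        write_tree_tsv(kinome_tree_export(scores, amap), out / "kinome_tree.tsv")

    with stage("trial"):
        tsec = config.section("trial")
        tparams = TrialParams(
            off_target_threshold=float(tsec.get("off_target_threshold", 20.0)),
            epsilon=float(tsec.get("epsilon", 1e-3)),
            min_substrates=int(tsec.get("min_substrates", 1)),
            tissue=tsec.get("tissue", "tumor"),
        )
        reports = run_trial(matrix, amap, panel, tparams)
        write_trial_json(reports, out / "trial.json")
        write_trial_tsv(reports, out / "trial_scores.tsv")

    meta = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": ["annotation", "simulate", "quantify", "stats", "uka", "trial"],
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    log(f"pipeline finished in {time.perf_counter() - t_start:.2f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
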