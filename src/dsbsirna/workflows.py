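"""Reproducible end-to-end runs tying the stages together.

Each workflow takes a single integer seed plus a config-override mapping,
resolves defaults, derives a named random substream per stage from the
top-level seed, executes the module pipeline, writes its outputs and the
resolved configuration into a run directory, and returns the key results
as plain Python objects.  Unknown configuration keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import features as feat
from . import qpcr as qp
from . import screen as scr
from .locus import derive_features
from .reads import map_reads
from .simulate import (
    LocusSimConfig,
    PlateSimConfig,
    QpcrSimConfig,
    simulate_qpcr,
    simulate_screen,
    simulate_sirna_library,
)


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-stage child seed derived from the top-level seed."""
    return int(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def _build_config(cls, overrides: Mapping[str, Any] | None, seed: int, stage: str):
    overrides = dict(overrides or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown config keys for {stage}: {sorted(unknown)}")
    overrides.setdefault("seed", substream_seed(seed, stage))
    return cls(**overrides)


def _echo_config(cfg, out_dir: Path, name: str) -> None:
    data = dataclasses.asdict(cfg)
    # YAML-safe: tuples and tuple keys to lists/strings
    def _clean(x):
        if isinstance(x, dict):
            return {str(k): _clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [_clean(v) for v in x]
        return x

    with open(out_dir / f"{name}.config.yaml", "w") as fh:
        yaml.safe_dump(_clean(data), fh, sort_keys=True)


def run_sirna_workflow(
    out_dir: str | Path,
    seed: int = 0,
    sim_config: Mapping[str, Any] | None = None,
    exclusion_pad: int = cov.DEFAULT_EXCLUSION_PAD,
    min_overhang: int = 1,
    write_files: bool = True,
) -> dict[str, Any]:
    """simulate -> map -> coverage -> cut ratio -> feature coverage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _build_config(LocusSimConfig, sim_config, seed, "sirna")
    sim = simulate_sirna_library(cfg)
    lib = map_reads(sim.iter_reads(), sim.reference, name="simlib")
    trace = cov.build_coverage(lib, sim.gene)
    ratio = cov.cut_ratio(trace, sim.gene, sim.cut, exclusion_pad=exclusion_pad)
    fs = derive_features(sim.gene, cfg.read_length, min_overhang)
    fcov = feat.count_feature_reads(lib, fs, sim.gene)
    if write_files:
        sim.write(out)
        _echo_config(cfg, out, "sirna")
        cov.write_tracks(trace, out / "simlib", chrom=sim.gene.chrom)
        pd.DataFrame(
            [
                {
                    "library": lib.name,
                    "cut": sim.cut.label,
                    "upstream_mean_rpm_per_bp": ratio.upstream_mean_rpm_per_bp,
                    "downstream_mean_rpm_per_bp": ratio.downstream_mean_rpm_per_bp,
                    "ratio": ratio.ratio,
                    "undefined": ratio.undefined,
                    "upstream_bases": ratio.upstream_bases,
                    "downstream_bases": ratio.downstream_bases,
                }
            ]
        ).to_csv(out / "cut_ratio.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"feature": k, "count": fcov.counts[k], "normalized": fcov.normalized[k]}
                for k in fcov.counts
            ]
        ).to_csv(out / "feature_coverage.tsv", sep="\t", index=False)
    return {
        "config": cfg,
        "simulated": sim,
        "library": lib,
        "trace": trace,
        "cut_ratio": ratio,
        "feature_coverage": fcov,
    }


def run_screen_workflow(
    out_dir: str | Path,
    seed: int = 0,
    sim_config: Mapping[str, Any] | None = None,
    span: float = 0.9,
    degree: int = 2,
    write_files: bool = True,
) -> dict[str, Any]:
    """simulate plates -> normalize -> LOESS z-scores -> candidate calls."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _build_config(PlateSimConfig, sim_config, seed, "screen")
    plates, truth = simulate_screen(cfg)
    norm = scr.normalize_plates(plates)
    scored = scr.score_wells(norm, span=span, degree=degree)
    thresholds = scr.control_thresholds(scored)
    candidates = scr.call_candidates(scored, thresholds)
    if write_files:
        _echo_config(cfg, out, "screen")
        plates.to_csv(out / "plates.tsv", sep="\t", index=False)
        scored.to_csv(out / "well_scores.tsv", sep="\t", index=False)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        with open(out / "screen.truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)
    return {
        "config": cfg,
        "plates": plates,
        "truth": truth,
        "scored": scored,
        "thresholds": thresholds,
        "candidates": candidates,
    }


def run_qpcr_workflow(
    out_dir: str | Path,
    seed: int = 0,
    sim_config: Mapping[str, Any] | None = None,
    test_condition: str = "cut",
    control_condition: str = "control",
    write_files: bool = True,
) -> dict[str, Any]:
    """simulate Ct table -> per-amplicon cut/uncut fold changes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _build_config(QpcrSimConfig, sim_config, seed, "qpcr")
    table, truth = simulate_qpcr(cfg)
    test = table[table["condition"] == test_condition]
    control = table[table["condition"] == control_condition]
    amplicons = [a for a in cfg.baseline_ct if a != qp.AMPLICON_TOTAL]
    folds = qp.cut_uncut_ratio(test, control, amplicons)
    if write_files:
        _echo_config(cfg, out, "qpcr")
        table.to_csv(out / "ct_table.tsv", sep="\t", index=False)
        folds.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
        with open(out / "qpcr.truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)
    return {"config": cfg, "ct_table": table, "truth": truth, "folds": folds}


def write_report(out_dir: str | Path, results: Mapping[str, Any]) -> Path:
    """Join stage summaries into one machine-readable report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    if "cut_ratio" in results:
        r = results["cut_ratio"]
        summary["cut_ratio"] = {
            "ratio": r.ratio,
            "undefined": r.undefined,
            "upstream_mean_rpm_per_bp": r.upstream_mean_rpm_per_bp,
            "downstream_mean_rpm_per_bp": r.downstream_mean_rpm_per_bp,
        }
    if "candidates" in results:
        calls = results["candidates"]["call"].value_counts().to_dict()
        summary["screen"] = {str(k): int(v) for k, v in calls.items()}
    if "folds" in results:
        summary["qpcr"] = {
            row["amplicon"]: float(row["fold_change"])
            for _, row in results["folds"].iterrows()
        }
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return path
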