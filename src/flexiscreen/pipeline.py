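"""Orchestration of the full screening funnel.

Two run modes:

* ``fixture`` — consume tabular inputs only (design scores + measured
  ΔRMSF): reproduces the selection logic of the published screen
  (region ranking → ΔΔG selection → high-temperature ΔRMSF stage →
  optimum-temperature sign stage) without any ensemble.
* ``synthetic`` — generate wild-type and mutant ensembles with planted
  flexibility differences and run every stage, including hydrogen-bond and
  secondary-structure summaries, end to end.

Reports are deterministic given config + seed and are serialized as JSON
plus TSV tables.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .geometry import AtomSelection, compute_rmsf
from .hbonds import hbond_occupancy, region_hbond_summary, diff_hbond_reports
from .io import build_hbond_topology, read_delta_rmsf_table, read_design_table
from .regions import (FlexibleRegion, identify_flexible_regions, rank_regions)
from .screen import (DeltaRmsfResult, HIGH_TEMP_DELTA_RMSF_THRESHOLD,
                     OPTIMUM_TEMP_DELTA_RMSF_THRESHOLD, replicate_delta_rmsf,
                     screen_stage, select_designs)
from .secstruct import region_secstruct_percentages
from .synthetic import EnsembleSpec, generate_ensemble, generate_mutant_pair

__all__ = ["PipelineConfig", "ScreeningReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All funnel parameters, with the published defaults."""

    mode: str = "fixture"                      # fixture | synthetic
    design_table: str | None = None            # None → packaged fixture
    delta_rmsf_table: str | None = None        # fixture mode only
    top_k: int = 5
    high_temp_threshold: float = HIGH_TEMP_DELTA_RMSF_THRESHOLD
    optimum_temp_threshold: float = OPTIMUM_TEMP_DELTA_RMSF_THRESHOLD
    catalytic_residues: tuple[int, ...] = datasets.CATALYTIC_RESIDUES
    min_active_site_distance: float = 15.0
    exclusion: tuple[tuple[int, int], ...] = datasets.C_TERMINUS_EXCLUSION
    selection: str = "calpha"
    seed: int = 0
    # synthetic mode
    n_residues: int = 40
    n_frames: int = 200
    n_replicates: int = 3
    base_amplitude: float = 0.4
    flexible_region: tuple[int, int] = (15, 24)
    flexible_amplitude_factor: float = 3.0
    mutant_scales: dict = field(default_factory=lambda: {"M1": 0.5})
    output_dir: str | None = None


@dataclass
class ScreeningReport:
    """Per-stage funnel results plus provenance."""

    config: dict
    stages: dict[str, Any] = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        def _default(obj):
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"not JSON serializable: {type(obj)}")
        return json.dumps({"config": self.config, "stages": self.stages},
                          indent=2, sort_keys=True, default=_default, **kw)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        for name, stage in self.stages.items():
            table = stage.get("table")
            if table:
                pd.DataFrame(table).to_csv(out / f"{name}.tsv", sep="\t", index=False)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config document; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "flexible_region" in raw:
        raw["flexible_region"] = tuple(raw["flexible_region"])
    if "exclusion" in raw:
        raw["exclusion"] = tuple(tuple(x) for x in raw["exclusion"])
    if "catalytic_residues" in raw:
        raw["catalytic_residues"] = tuple(raw["catalytic_residues"])
    return PipelineConfig(**raw)


def _fixture_pipeline(cfg: PipelineConfig, report: ScreeningReport) -> None:
    regions = datasets.table1_region_objects()
    top = rank_regions(regions, cfg.top_k) if cfg.top_k else []
    report.stages["regions"] = {
        "n_regions": len(regions),
        "top_region_ids": sorted(r.region_id for r in top),
        "table": [dataclasses.asdict(r) | {"n_residues": r.n_residues} for r in regions],
    }
    if not top:
        report.stages["design_selection"] = {"n_selected": 0, "labels": []}
        return

    records = (read_design_table(cfg.design_table) if cfg.design_table
               else datasets.table2_designs())
    calls = select_designs(records)
    per_region: dict[int, int] = {}
    for c in calls:
        per_region[c.region_id] = per_region.get(c.region_id, 0) + 1
    report.stages["design_selection"] = {
        "n_table_rows": len(records),
        "n_selected": len(calls),
        "per_region": per_region,
        "labels": [c.label for c in calls],
        "table": [{"label": c.label, "region": c.region_id, "ddG": c.ddG} for c in calls],
    }

    df = (read_delta_rmsf_table(cfg.delta_rmsf_table) if cfg.delta_rmsf_table
          else datasets.table3_delta_rmsf())
    selected = {c.label for c in calls}
    high = [DeltaRmsfResult(r.mutant, "high_temp", float(r.mean_500k), float(r.sem_500k),
                            cfg.high_temp_threshold, r.region)
            for r in df.itertuples() if r.mutant in selected]
    pass_high = screen_stage(high, cfg.high_temp_threshold)
    report.stages["high_temp_screen"] = {
        "threshold": cfg.high_temp_threshold,
        "n_in": len(high), "n_pass": len(pass_high), "pass": pass_high,
        "table": [dataclasses.asdict(r) for r in high],
    }
    opt = [DeltaRmsfResult(r.mutant, "optimum_temp", float(r.mean_313k), float(r.sem_313k),
                           cfg.optimum_temp_threshold, r.region)
           for r in df.itertuples()
           if r.mutant in set(pass_high) and np.isfinite(r.mean_313k)]
    pass_opt = screen_stage(opt, cfg.optimum_temp_threshold)
    report.stages["optimum_temp_screen"] = {
        "threshold": cfg.optimum_temp_threshold,
        "n_in": len(opt), "n_pass": len(pass_opt), "pass": pass_opt,
        "table": [dataclasses.asdict(r) for r in opt],
    }


def _synthetic_pipeline(cfg: PipelineConfig, report: ScreeningReport) -> None:
    selection = AtomSelection(cfg.selection)
    interval = tuple(cfg.flexible_region)
    base_spec = EnsembleSpec(
        n_residues=cfg.n_residues, n_frames=cfg.n_frames,
        amplitude_profile=cfg.base_amplitude,
        region_scaling={interval: cfg.flexible_amplitude_factor},
        base_geometry="helix", seed=cfg.seed)

    def replicate_specs(spec, count, offset):
        return [dataclasses.replace(spec, seed=spec.seed + offset + 7919 * i)
                for i in range(count)]

    scales = {label: float(s) for label, s in cfg.mutant_scales.items()}

    def mutant_replicates(spec, scale, label_index):
        out = []
        for i, rep_spec in enumerate(replicate_specs(spec, cfg.n_replicates, 2)):
            shifted = dataclasses.replace(rep_spec,
                                          seed=rep_spec.seed + 104729 * (label_index + 1))
            out.append(generate_mutant_pair(shifted, interval, scale)[1])
        return out

    # stage 1: wild-type flexibility at "high temperature" → regions
    wt_ensembles = [generate_ensemble(s)
                    for s in replicate_specs(base_spec, cfg.n_replicates, 1)]
    mut_ensembles = {label: mutant_replicates(base_spec, scale, k)
                     for k, (label, scale) in enumerate(scales.items())}

    wt_profiles = [compute_rmsf(e, selection, source_label=f"wt-rep{i}")
                   for i, e in enumerate(wt_ensembles)]
    regions = identify_flexible_regions(wt_profiles, exclusion=cfg.exclusion)
    k = min(cfg.top_k, len(regions))
    top = rank_regions(regions, k) if k else []
    report.stages["regions"] = {
        "n_regions": len(regions),
        "top_region_ids": sorted(r.region_id for r in top),
        "planted_interval": list(interval),
        "table": [dataclasses.asdict(r) | {"n_residues": r.n_residues} for r in regions],
    }
    if not top:
        return
    region = top[0]

    # stage 2: ΔRMSF screen of each mutant against the wild type
    high_results = []
    for label in scales:
        mut_profiles = [compute_rmsf(e, selection, source_label=f"{label}-rep{i}")
                        for i, e in enumerate(mut_ensembles[label])]
        high_results.append(replicate_delta_rmsf(
            mut_profiles, wt_profiles, region, mutant_label=label,
            temperature_label="high_temp", threshold=cfg.high_temp_threshold))
    pass_high = screen_stage(high_results, cfg.high_temp_threshold)
    report.stages["high_temp_screen"] = {
        "threshold": cfg.high_temp_threshold,
        "n_in": len(high_results), "n_pass": len(pass_high), "pass": pass_high,
        "table": [dataclasses.asdict(r) for r in high_results],
    }

    # stage 3: optimum-temperature validation (lower amplitudes, sign threshold)
    opt_spec = dataclasses.replace(base_spec, amplitude_profile=cfg.base_amplitude / 2,
                                   seed=base_spec.seed + 50021)
    opt_wt_profiles = [
        compute_rmsf(generate_ensemble(s), selection)
        for s in replicate_specs(opt_spec, cfg.n_replicates, 3)]
    opt_results = []
    for label in pass_high:
        label_index = list(scales).index(label)
        mut_profiles = [compute_rmsf(e, selection)
                        for e in mutant_replicates(opt_spec, scales[label], label_index)]
        opt_results.append(replicate_delta_rmsf(
            mut_profiles, opt_wt_profiles, region, mutant_label=label,
            temperature_label="optimum_temp", threshold=cfg.optimum_temp_threshold))
    pass_opt = screen_stage(opt_results, cfg.optimum_temp_threshold)
    report.stages["optimum_temp_screen"] = {
        "threshold": cfg.optimum_temp_threshold,
        "n_in": len(opt_results), "n_pass": len(pass_opt), "pass": pass_opt,
        "table": [dataclasses.asdict(r) for r in opt_results],
    }

    # stage 4: hydrogen-bond and secondary-structure explanation for survivors
    explanation = []
    wt_ens = wt_ensembles[0]
    topo = build_hbond_topology(wt_ens.frame(0))
    wt_counts = region_hbond_summary(hbond_occupancy(wt_ens, topo), region)
    wt_ss = region_secstruct_percentages(wt_ensembles, region)
    for label in pass_opt:
        mut_ens = mut_ensembles[label][0]
        mut_counts = region_hbond_summary(hbond_occupancy(mut_ens, topo), region)
        mut_ss = region_secstruct_percentages(mut_ensembles[label], region)
        explanation.append({
            "mutant": label,
            "hbond_deltas": diff_hbond_reports(wt_counts, mut_counts),
            "wildtype_secstruct": dataclasses.asdict(wt_ss),
            "mutant_secstruct": dataclasses.asdict(mut_ss),
        })
    report.stages["explanation"] = {"n_systems": len(explanation),
                                    "systems": explanation}


def run_pipeline(config: PipelineConfig) -> ScreeningReport:
    """Run the configured funnel and return (and optionally write) the report."""
    report = ScreeningReport(config=dataclasses.asdict(config))
    if config.mode == "fixture":
        _fixture_pipeline(config, report)
    elif config.mode == "synthetic":
        _synthetic_pipeline(config, report)
    else:
        raise ValueError(f"unknown pipeline mode {config.mode!r}")
    if config.output_dir:
        report.write(config.output_dir)
    return report
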