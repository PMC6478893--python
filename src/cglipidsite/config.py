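"""YAML pipeline configuration and end-to-end orchestration.

A single config drives the fixed-order pipeline contacts → events →
occupancy → stats; all analysis defaults mirror the published parameters,
so an empty override section reproduces the published analysis settings
exactly.  Validation collects *all* violations rather than stopping at the
first, and every run writes a manifest from which it can be regenerated
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import AnalysisConfig, Trajectory, load_trajectory
from .contacts import residue_contact_occupancy, call_binding_site, write_contact_table
from .kinetics import (
    SiteDefinition,
    default_log_bins,
    detect_events,
    residence_time_distribution,
    write_event_table,
    write_histogram_table,
)
from .stats import bootstrap_time_weighted_mean, mann_whitney
from .volume import align_protein_xy, occupancy_volume, export_grid

log = logging.getLogger("cglipidsite")

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass
class PipelineConfig:
    topology: str
    trajectory: str | None
    output_dir: str
    frame_interval: float = 600.0  # ps
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    species: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"ceramide": ("AM1", "AM2")}
    )
    primary_species: str = "ceramide"
    resamples: int = 10_000
    seed: int = 0
    alternative: str | None = None
    compare_events_with: str | None = None  # path to a second event TSV

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis"] = dataclasses.asdict(self.analysis)
        d["species"] = {k: list(v) for k, v in self.species.items()}
        return d


_ANALYSIS_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config, reporting all violations."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ConfigError([f"malformed YAML{line}: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])

    violations: list[str] = []
    topo = raw.get("topology")
    if not topo:
        violations.append("missing required key 'topology'")
    elif not os.path.exists(topo):
        violations.append(f"topology path does not exist: {topo}")
    traj = raw.get("trajectory")
    if traj is not None and not os.path.exists(traj):
        violations.append(f"trajectory path does not exist: {traj}")

    analysis_raw = raw.get("analysis", {}) or {}
    unknown = set(analysis_raw) - _ANALYSIS_FIELDS
    if unknown:
        violations.append(f"unknown analysis keys: {sorted(unknown)}")
    analysis = None
    try:
        kw = {k: v for k, v in analysis_raw.items() if k in _ANALYSIS_FIELDS}
        if "site_groups" in kw:
            kw["site_groups"] = tuple(tuple(g) for g in kw["site_groups"])
        analysis = AnalysisConfig(**kw)
    except (ValueError, TypeError) as exc:
        violations.append(str(exc))

    species = raw.get("species", {"ceramide": ["AM1", "AM2"]})
    if not isinstance(species, dict) or not species:
        violations.append("'species' must be a non-empty mapping label -> head names")
        species = {}
    species = {k: tuple(v) for k, v in species.items()}
    primary = raw.get("primary_species", next(iter(species), "ceramide"))
    if species and primary not in species:
        violations.append(f"primary_species {primary!r} not among species")

    alternative = raw.get("alternative")
    if alternative is not None and alternative not in ("a_greater", "b_greater"):
        violations.append("alternative must be 'a_greater' or 'b_greater'")

    resamples = int(raw.get("resamples", 10_000))
    if resamples < 1:
        violations.append("resamples must be >= 1")
    frame_interval = float(raw.get("frame_interval", 600.0))
    if frame_interval <= 0:
        violations.append("frame_interval must be positive")

    if violations:
        raise ConfigError(violations)

    return PipelineConfig(
        topology=str(topo),
        trajectory=None if traj is None else str(traj),
        output_dir=str(raw.get("output_dir", "cglipidsite_out")),
        frame_interval=frame_interval,
        analysis=analysis,
        species=species,
        primary_species=primary,
        resamples=resamples,
        seed=int(raw.get("seed", 0)),
        alternative=alternative,
        compare_events_with=raw.get("compare_events_with"),
    )


def run_pipeline(config: PipelineConfig, traj: Trajectory | None = None) -> dict:
    """Run contacts → events → occupancy → stats and write all artifacts.

    Returns the manifest (also written as ``manifest.json``): config echo,
    package versions, seed, frame counts, per-stage outputs and warnings.
    A stage failure aborts with the stage name; artifacts written so far
    are flagged as partial in the manifest.
    """
    import cglipidsite

    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "cglipidsite": cglipidsite.__version__,
            "numpy": np.__version__,
        },
        "seed": config.seed,
        "outputs": {},
        "warnings": [],
        "errors": [],
    }
    stage = "load"
    try:
        if traj is None:
            traj = load_trajectory(
                config.topology, config.trajectory, config.frame_interval
            )
        manifest["n_frames"] = traj.n_frames
        manifest["n_particles"] = traj.n_particles
        log.info("loaded %d frames × %d particles", traj.n_frames, traj.n_particles)

        stage = "contacts"
        site_calls = {}
        for label, heads in config.species.items():
            cmap = residue_contact_occupancy(
                traj, config.analysis, label, head_names=heads
            )
            out = os.path.join(config.output_dir, f"contacts_{label}.tsv")
            write_contact_table(cmap, out)
            manifest["outputs"][f"contacts_{label}"] = out
            site_calls[label] = call_binding_site(cmap, config.analysis)
            log.info(
                "%s: %d residues above the %.0f%% occupancy threshold",
                label, len(site_calls[label]), 100 * config.analysis.occupancy_threshold,
            )
        manifest["binding_site_calls"] = site_calls

        stage = "events"
        site = SiteDefinition.from_config(config.analysis)
        heads = config.species[config.primary_species]
        events = detect_events(
            traj,
            site,
            heads,
            smoothing_window=config.analysis.smoothing_window,
            smoothing_min_true=config.analysis.smoothing_min_true,
        )
        ev_path = os.path.join(config.output_dir, "events.tsv")
        write_event_table(events, ev_path)
        manifest["outputs"]["events"] = ev_path
        manifest["n_events_retained"] = len(events.events)
        manifest["n_end_censored"] = events.n_discarded_end_censored
        hist_path = os.path.join(config.output_dir, "hist.tsv")
        if events.events:
            bins = default_log_bins(traj.frame_interval, events.total_time)
            hist = residence_time_distribution(events, bins=bins)
            write_histogram_table(hist, hist_path)
            manifest["outputs"]["hist"] = hist_path
            manifest["bound_time_fraction"] = hist.bound_fraction
        else:
            manifest["warnings"].append("no retained binding events; histogram skipped")

        stage = "occupancy"
        aligned = align_protein_xy(traj, ref_frame=0)
        for label, heads_ in config.species.items():
            grid = occupancy_volume(aligned, label, config.analysis, head_names=heads_)
            dx = os.path.join(config.output_dir, f"occupancy_{label}.dx")
            export_grid(grid, dx)
            manifest["outputs"][f"occupancy_{label}"] = dx

        stage = "stats"
        stats: dict = {"seed": config.seed}
        if events.events:
            boot = bootstrap_time_weighted_mean(
                events.durations,
                n_resamples=config.resamples,
                ci_level=config.analysis.ci_level,
                seed=config.seed,
            )
            stats["time_weighted_mean_ns"] = boot.point_estimate / 1000.0
            stats["ci_low_ns"] = boot.ci_low / 1000.0
            stats["ci_high_ns"] = boot.ci_high / 1000.0
            stats["n_events"] = len(events.events)
            stats["n_resamples"] = boot.n_resamples
        if config.compare_events_with and config.alternative and events.events:
            import pandas as pd

            other = pd.read_csv(config.compare_events_with, sep="\t", comment="#")
            res = mann_whitney(
                events.durations / 1000.0,
                other["duration_ns"].to_numpy(),
                alternative=config.alternative,
            )
            stats["mww_u"] = res.u
            stats["mww_p"] = res.p_value
            stats["mww_alternative"] = config.alternative
        stats_path = os.path.join(config.output_dir, "stats.json")
        with open(stats_path, "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["outputs"]["stats"] = stats_path
    except Exception as exc:
        manifest["errors"].append(f"stage {stage!r} failed: {exc}")
        manifest["partial"] = True
        _write_manifest(manifest, config.output_dir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, config.output_dir)
    return manifest


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
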