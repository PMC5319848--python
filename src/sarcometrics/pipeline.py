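"""Configuration-driven orchestration: simulate -> measure -> quantify ->
compare, with seeded reproducibility and a human-readable report.

A :class:`RunConfig` (YAML on disk, validated with pydantic) describes a
scenario as a set of optional stages — imaging morphometry, gel
densitometry, qPCR isoform index, force-pCa, postnatal transition — each
parameterised per experimental group. :func:`run_scenario` executes the
enabled stages in a fixed order, derives one child seed per stage from the
scenario seed, writes tidy CSV outputs plus a provenance JSON (config hash,
seed, package version) and a plain-text report comparing recovered against
generating parameters.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__, isoform, morphometry, simulate, stats
from .io import config_hash, params_to_jsonable
from .simulate import CHANNELS, OpticalModelParams, PopulationSpec, QpcrTruth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_scenario", "validate_config", "load_config",
           "load_preset", "available_presets"]


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------


class OpticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pixel_size: float = 0.05
    psf_sigma: float = 0.10
    z_amplitude: float = 1.0
    thin_amplitude: float = 0.5
    epitope_amplitude: float = 1.0
    baseline: float = 0.1
    noise_sd: float = 0.05

    def build(self) -> OpticalModelParams:
        return OpticalModelParams(**self.model_dump())


class MeasurementConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    prominence_frac: float = Field(0.2, gt=0, lt=1)
    min_separation_um: float = Field(0.8, gt=0)
    pointed_min_separation_um: float = Field(0.3, gt=0)
    resolution_limit_um: float = Field(0.2, gt=0)


class GroupPopulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = Field(ge=1)
    n_sarcomeres: int = Field(10, ge=3)
    sl_mean: float = Field(gt=0)
    sl_sd: float = Field(ge=0)
    cell_sl_sd: float = Field(0.0, ge=0)
    tfl_slope: float
    tfl_intercept: float
    tfl_noise_sd: float = Field(ge=0)
    affected_fraction: float = Field(0.0, ge=0, le=1)
    affected_sl_mean: float | None = None
    affected_sl_sd: float | None = None

    @model_validator(mode="after")
    def _tfl_law_not_degenerate(self) -> "GroupPopulationConfig":
        typical_tfl = self.tfl_slope * self.sl_mean + self.tfl_intercept
        if typical_tfl >= self.sl_mean:
            raise ValueError(
                "tfl_slope/tfl_intercept yield TFL >= SL at the typical SL; "
                "degenerate population")
        if typical_tfl <= 0:
            raise ValueError("tfl_slope/tfl_intercept yield non-positive TFL")
        return self

    def build(self) -> PopulationSpec:
        return PopulationSpec(**self.model_dump())


class ImagingStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    groups: dict[str, GroupPopulationConfig]
    channels: list[str] = ["alpha_actinin", "tmod1", "phalloidin"]

    @model_validator(mode="after")
    def _channels_known(self) -> "ImagingStageConfig":
        unknown = [c for c in self.channels if c not in CHANNELS]
        if unknown:
            raise ValueError(f"unknown channel(s) {unknown} in "
                             f"imaging.channels; choose from {CHANNELS}")
        return self


class GelGroupConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pct_n2b: float = Field(ge=0, le=100)
    n_lanes: int = Field(4, ge=1)
    noise_sd: float = Field(0.5, ge=0)
    baseline_slope: float = 0.05
    baseline_offset: float = 2.0


class QpcrGroupConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pct_n2b: float = Field(ge=0, le=100)
    n_samples: int = Field(8, ge=1)
    tech_noise_sd: float = Field(0.2, ge=0)
    replicates: int = Field(3, ge=1)
    efficiency: float = Field(2.0, gt=1, le=2)


class ForceGroupConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pca50: float = Field(ge=4, le=8)
    n_hill: float = Field(2.0, gt=0)
    f_max: float = Field(25.0, gt=0)
    passive_force: float = Field(2.0, ge=0)
    noise_sd: float = Field(0.0, ge=0)


class ForceStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    groups: dict[str, ForceGroupConfig]
    pca_grid: list[float] = [7.0, 6.6, 6.4, 6.2, 6.1, 6.0, 5.9, 5.8, 5.6,
                             5.4, 5.0, 4.6]

    @model_validator(mode="after")
    def _grid_descending(self) -> "ForceStageConfig":
        if not all(a > b for a, b in zip(self.pca_grid, self.pca_grid[1:])):
            raise ValueError("force.pca_grid must be descending in pCa")
        return self


class TransitionStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stages: list[str]
    genotypes: dict[str, list[float]]
    n_per_stage: int = Field(4, ge=2)
    noise_sd: float = Field(3.0, ge=0)

    @model_validator(mode="after")
    def _lengths_match(self) -> "TransitionStageConfig":
        for g, pcts in self.genotypes.items():
            if len(pcts) != len(self.stages):
                raise ValueError(f"transition.genotypes[{g!r}] must list one "
                                 "%N2B per stage")
        return self


class RunConfig(BaseModel):
    """Validated scenario description; see the bundled presets for shape."""

    model_config = ConfigDict(extra="forbid")
    scenario: str
    seed: int | None = None
    optics: OpticsConfig = OpticsConfig()
    measurement: MeasurementConfig = MeasurementConfig()
    imaging: ImagingStageConfig | None = None
    gel: dict[str, GelGroupConfig] | None = None
    qpcr: dict[str, QpcrGroupConfig] | None = None
    force: ForceStageConfig | None = None
    transition: TransitionStageConfig | None = None

    @model_validator(mode="after")
    def _seed_when_stochastic(self) -> "RunConfig":
        if self.seed is None and self._is_stochastic():
            raise ValueError("seed is required: the scenario enables "
                             "stochastic stages")
        if any(s is not None for s in (self.imaging, self.gel, self.qpcr,
                                       self.force, self.transition)) is False:
            raise ValueError("no stage enabled: nothing to run")
        return self

    def _is_stochastic(self) -> bool:
        if self.imaging is not None:
            if self.optics.noise_sd > 0:
                return True
            if any(g.sl_sd > 0 or g.cell_sl_sd > 0 or g.tfl_noise_sd > 0
                   or 0 < g.affected_fraction < 1
                   for g in self.imaging.groups.values()):
                return True
        if self.gel is not None and any(g.noise_sd > 0 for g in self.gel.values()):
            return True
        if self.qpcr is not None and any(g.tech_noise_sd > 0
                                         for g in self.qpcr.values()):
            return True
        if self.force is not None and any(g.noise_sd > 0
                                          for g in self.force.groups.values()):
            return True
        if self.transition is not None and self.transition.noise_sd > 0:
            return True
        return False


# ---------------------------------------------------------------------------
# config loading / validation
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def validate_config(path: str | Path) -> list[str]:
    """Full schema and cross-field validation without executing anything.

    Returns an empty list when the config is valid, otherwise one message
    per offence naming the offending field.
    """
    from pydantic import ValidationError

    try:
        load_config(path)
    except ValidationError as exc:
        return [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in exc.errors()]
    except (OSError, yaml.YAMLError) as exc:
        return [str(exc)]
    return []


def available_presets() -> list[str]:
    root = importlib.resources.files("sarcometrics") / "scenarios"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str) -> RunConfig:
    """Load a bundled scenario preset by name (see available_presets)."""
    root = importlib.resources.files("sarcometrics") / "scenarios"
    path = root / f"{name}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}; available: "
                         f"{available_presets()}") from None
    return RunConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def _measure_group(specs: PopulationSpec, optics: OpticalModelParams,
                   channels: list[str], meas: MeasurementConfig,
                   rng: np.random.Generator, group: str):
    """Simulate one group's cells, render profiles, run the measurement
    chain; returns (truths, per-cell results, TFL~SL pair table)."""
    truths = simulate.simulate_population(specs, rng=rng)
    results, pair_frames = [], []
    for truth in truths:
        profiles = simulate.simulate_profile(truth, optics, channels, rng=rng)
        result = morphometry.measure_cell(
            profiles, truth.cell_id,
            prominence_frac=meas.prominence_frac,
            min_separation_um=meas.min_separation_um,
            pointed_min_separation_um=meas.pointed_min_separation_um,
            resolution_limit_um=meas.resolution_limit_um)
        results.append(result)
        if "alpha_actinin" in profiles and "tmod1" in profiles:
            z = morphometry.detect_peaks(profiles["alpha_actinin"],
                                         meas.prominence_frac,
                                         meas.min_separation_um)
            t = morphometry.detect_peaks(profiles["tmod1"],
                                         meas.prominence_frac,
                                         meas.pointed_min_separation_um)
            pairs = morphometry.measure_tfl_pairs(z, t)
            if not pairs.empty:
                pairs.insert(0, "cell_id", truth.cell_id)
                pairs.insert(0, "group", group)
                pair_frames.append(pairs)
    pairs = (pd.concat(pair_frames, ignore_index=True) if pair_frames
             else pd.DataFrame(columns=["group", "cell_id", "tfl_um",
                                        "local_sl_um", "z_index", "flank"]))
    return truths, results, pairs


def _comparison_record(cmp_: stats.GroupComparison) -> dict:
    return {"test": cmp_.test, "statistic": cmp_.statistic,
            "p_raw": cmp_.p_raw, "p_adjusted": cmp_.p_adjusted,
            "adjustment": cmp_.adjustment, "gates": cmp_.gates}


def run_scenario(config: RunConfig, output_dir: str | Path) -> dict[str, Any]:
    """Execute every enabled stage of a scenario and write the report bundle.

    Outputs (per enabled stage) are tidy CSVs plus ``stats.json``,
    ``provenance.json`` and a human-readable ``report.txt``. The same config
    and seed always produce byte-identical measurement CSVs. Returns the
    in-memory results keyed by stage.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("scenario %r: seed=%s thresholds=%s", config.scenario,
                config.seed, config.measurement.model_dump())
    seed_root = np.random.SeedSequence(0 if config.seed is None else config.seed)
    stage_seeds = dict(zip(("imaging", "gel", "qpcr", "force", "transition"),
                           seed_root.spawn(5)))
    results: dict[str, Any] = {}
    stats_report: dict[str, Any] = {}
    report_lines = [f"scenario: {config.scenario}", f"seed: {config.seed}", ""]

    if config.imaging is not None:
        rng = np.random.default_rng(stage_seeds["imaging"])
        optics = config.optics.build()
        all_truth, all_cells, all_pairs, group_results = [], [], [], {}
        for group, gcfg in config.imaging.groups.items():
            truths, cell_results, pairs = _measure_group(
                gcfg.build(), optics, config.imaging.channels,
                config.measurement, rng, group)
            tt = simulate.truth_table(truths)
            tt.insert(0, "group", group)
            all_truth.append(tt)
            for r in cell_results:
                rec = r.to_record()
                rec["group"] = group
                all_cells.append(rec)
            all_pairs.append(pairs)
            group_results[group] = cell_results
        truth_df = pd.concat(all_truth, ignore_index=True)
        cells_df = pd.DataFrame(all_cells)
        pairs_df = pd.concat(all_pairs, ignore_index=True)
        truth_df.to_csv(out / "ground_truth.csv", index=False)
        cells_df.to_csv(out / "cell_measurements.csv", index=False)
        pairs_df.to_csv(out / "tfl_sl_pairs.csv", index=False)
        (out / "cell_measurements.json").write_text(json.dumps(
            params_to_jsonable(all_cells), indent=2))
        flat_results = [r for rs in group_results.values() for r in rs]
        flat_groups = [g for g, rs in group_results.items() for _ in rs]
        pop = morphometry.aggregate_cells(flat_results, flat_groups)
        pop_df = pd.DataFrame([vars(p) for p in pop.values()])
        pop_df.to_csv(out / "population_stats.csv", index=False)
        imaging_stats: dict[str, Any] = {}
        groups = list(config.imaging.groups)
        if len(groups) == 2:
            a = [r.sl_mean for r in group_results[groups[0]]]
            b = [r.sl_mean for r in group_results[groups[1]]]
            imaging_stats["sl_comparison"] = _comparison_record(
                stats.gate_and_test(a, b))
            sub = {g: pairs_df[pairs_df["group"] == g] for g in groups}
            if all(len(s) >= 3 for s in sub.values()):
                cmp_ = stats.compare_regressions(
                    sub[groups[0]]["local_sl_um"], sub[groups[0]]["tfl_um"],
                    sub[groups[1]]["local_sl_um"], sub[groups[1]]["tfl_um"],
                    labels=(groups[0], groups[1]))
                imaging_stats["tfl_sl_regression"] = {
                    "slopes": {groups[0]: cmp_.fit_a.slope,
                               groups[1]: cmp_.fit_b.slope},
                    "intercepts": {groups[0]: cmp_.fit_a.intercept,
                                   groups[1]: cmp_.fit_b.intercept},
                    "p_slope": cmp_.p_slope,
                    "p_elevation": cmp_.p_elevation,
                    "p_intercept": cmp_.p_intercept,
                }
        stats_report["imaging"] = imaging_stats
        results["imaging"] = {"population_stats": pop, "pairs": pairs_df,
                              "cells": cells_df}
        for group, p in pop.items():
            gcfg = config.imaging.groups[group]
            report_lines.append(
                f"[imaging] {group}: SL mean {p.mean:.3f} um "
                f"(generating {gcfg.sl_mean:.3f}), n={p.n} cells")
        report_lines.append("")

    if config.gel is not None:
        rng = np.random.default_rng(stage_seeds["gel"])
        rows = []
        for group, gcfg in config.gel.items():
            for li in range(gcfg.n_lanes):
                lane = simulate.simulate_gel_lane(
                    gcfg.pct_n2b, noise_sd=gcfg.noise_sd,
                    baseline_slope=gcfg.baseline_slope,
                    baseline_offset=gcfg.baseline_offset,
                    rng=rng, lane_id=f"{group}_lane{li}", group=group)
                m = isoform.quantify_lane(isoform.subtract_baseline(lane))
                rows.append({"group": group, "lane_id": m.sample_id,
                             "pct_n2b": m.pct_n2b,
                             "true_pct_n2b": gcfg.pct_n2b})
        gel_df = pd.DataFrame(rows)
        gel_df.to_csv(out / "gel_results.csv", index=False)
        stats_report["gel"] = {
            g: {"mean_pct_n2b": float(sub["pct_n2b"].mean()),
                "true_pct_n2b": float(sub["true_pct_n2b"].iloc[0])}
            for g, sub in gel_df.groupby("group", sort=False)}
        results["gel"] = gel_df
        for g, rec in stats_report["gel"].items():
            report_lines.append(f"[gel] {g}: %N2B {rec['mean_pct_n2b']:.2f} "
                                f"(generating {rec['true_pct_n2b']:.2f})")
        report_lines.append("")

    if config.qpcr is not None:
        rng = np.random.default_rng(stage_seeds["qpcr"])
        rows = []
        for group, qcfg in config.qpcr.items():
            for si in range(qcfg.n_samples):
                truth = QpcrTruth(pct_n2b=qcfg.pct_n2b,
                                  tech_noise_sd=qcfg.tech_noise_sd,
                                  efficiency=qcfg.efficiency,
                                  replicates=qcfg.replicates)
                table = simulate.simulate_ct_table(
                    truth, sample_id=f"{group}_s{si}", rng=rng)
                (m,) = isoform.pct_n2b_from_ct(table, qcfg.efficiency)
                rows.append({"group": group, "sample_id": m.sample_id,
                             "pct_n2b": m.pct_n2b,
                             "true_pct_n2b": qcfg.pct_n2b})
        qpcr_df = pd.DataFrame(rows)
        qpcr_df.to_csv(out / "qpcr_results.csv", index=False)
        qstats: dict[str, Any] = {
            g: {"mean_pct_n2b": float(sub["pct_n2b"].mean()),
                "true_pct_n2b": float(sub["true_pct_n2b"].iloc[0])}
            for g, sub in qpcr_df.groupby("group", sort=False)}
        groups = list(config.qpcr)
        if len(groups) == 2 and all(
                (qpcr_df["group"] == g).sum() >= 3 for g in groups):
            cmp_ = stats.gate_and_test(
                qpcr_df.loc[qpcr_df["group"] == groups[0], "pct_n2b"],
                qpcr_df.loc[qpcr_df["group"] == groups[1], "pct_n2b"])
            qstats["comparison"] = _comparison_record(cmp_)
        stats_report["qpcr"] = qstats
        results["qpcr"] = qpcr_df
        for g in groups:
            rec = qstats[g]
            report_lines.append(f"[qpcr] {g}: %N2B {rec['mean_pct_n2b']:.2f} "
                                f"(generating {rec['true_pct_n2b']:.2f})")
        report_lines.append("")

    if config.force is not None:
        rng = np.random.default_rng(stage_seeds["force"])
        rows = []
        for group, fcfg in config.force.groups.items():
            curve = simulate.simulate_force_pca(
                fcfg.pca50, fcfg.n_hill, fcfg.f_max, fcfg.passive_force,
                config.force.pca_grid, noise_sd=fcfg.noise_sd, rng=rng)
            fit = stats.fit_force_pca(curve)
            rows.append({"group": group, "pca50": fit.pca50,
                         "n_hill": fit.n_hill, "f_max": fit.f_max,
                         "rss": fit.rss, "true_pca50": fcfg.pca50})
        force_df = pd.DataFrame(rows)
        force_df.to_csv(out / "force_pca_results.csv", index=False)
        stats_report["force"] = force_df.to_dict(orient="records")
        results["force"] = force_df
        for rec in stats_report["force"]:
            report_lines.append(
                f"[force] {rec['group']}: pCa50 {rec['pca50']:.3f} "
                f"(generating {rec['true_pca50']:.3f}), "
                f"n_H {rec['n_hill']:.2f}")
        report_lines.append("")

    if config.transition is not None:
        rng = np.random.default_rng(stage_seeds["transition"])
        genotypes = dict(config.transition.genotypes)
        series = simulate.simulate_transition_series(
            config.transition.stages, genotypes,
            n_per_stage=config.transition.n_per_stage,
            noise_sd=config.transition.noise_sd, rng=rng)
        series.to_csv(out / "transition_samples.csv", index=False)
        if len(genotypes) == 2:
            tr = isoform.transition_series(series, config.transition.stages)
            tr.summary.to_csv(out / "transition_summary.csv", index=False)
            tr.tests.to_csv(out / "transition_tests.csv", index=False)
            stats_report["transition"] = {
                "earliest_divergence": tr.earliest_divergence}
            results["transition"] = tr
            report_lines.append(f"[transition] earliest divergence: "
                                f"{tr.earliest_divergence}")
            report_lines.append("")
        else:
            results["transition"] = series

    (out / "stats.json").write_text(
        json.dumps(params_to_jsonable(stats_report), indent=2))
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    provenance = {
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": config_hash(config.model_dump()),
        "version": __version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["stats"] = stats_report
    results["provenance"] = provenance
    return results
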