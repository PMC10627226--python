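"""End-to-end pipeline: simulate or load transients → JIP engine →
treatment statistics → report tables, correlation matrix and a run manifest.

The pipeline is a plain library function (:func:`run_pipeline`) over a
:class:`PipelineConfig`; the ``ojip`` command line is a thin wrapper.  One
top-level seed deterministically derives the per-stage substreams, so the
same config + seed always produces byte-identical text outputs, recorded as
SHA-256 hashes in the manifest (image outputs are written but not hashed —
plot-backend bytes are not guaranteed stable).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .errors import ConfigurationError
from .jip import DeexcitationConvention, compute_parameter_table
from .growth import biomass_summary, read_harvest_table, harvest_frame
from .simulate import (
    DAY_LENGTH_SCENARIOS,
    DEFAULT_MATURITY_GROUPS,
    KineticPreset,
    ScenarioEffect,
    TEMPERATURE_SCENARIOS,
    generate_experiment,
    generate_harvests,
)
from .stats import (
    DEFAULT_CORRELATION_PARAMETERS,
    DEFAULT_TABLE_PARAMETERS,
    correlation_matrix,
    plot_correlation_heatmap,
    summarize_treatment_table,
)
from .transients import read_transient_table, write_transient_table

log = logging.getLogger("ojip")


@dataclass
class SimulationBlock:
    """Simulation settings: which treatment axis, levels and sizes."""

    axis: str = "temperature"
    levels: list = field(default_factory=lambda: list(TEMPERATURE_SCENARIOS))
    scenarios: dict = field(default_factory=dict)  # level -> ScenarioEffect kwargs
    maturity_groups: list = field(
        default_factory=lambda: list(DEFAULT_MATURITY_GROUPS)
    )
    n_reps: int = 5
    n_meas: int = 15
    preset: dict = field(default_factory=dict)  # KineticPreset overrides
    harvests: bool = True

    def resolve_scenarios(self) -> dict:
        defaults = (TEMPERATURE_SCENARIOS if self.axis == "temperature"
                    else DAY_LENGTH_SCENARIOS)
        out = dict(defaults)
        for level, eff in self.scenarios.items():
            key = float(level) if self.axis == "day_length" else str(level)
            out[key] = (eff if isinstance(eff, ScenarioEffect)
                        else ScenarioEffect(**eff))
        if self.axis == "day_length":
            self.levels = [float(lv) for lv in self.levels]
        return out


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from YAML or JSON."""

    input_path: str | None = None
    harvest_path: str | None = None
    simulation: SimulationBlock | None = None
    merge: bool = False
    fiducial_times: dict = field(default_factory=dict)
    tolerance_factor: float = 1.25
    convention: dict = field(default_factory=dict)
    alpha: float = 0.05
    use_replicate_means: bool = True
    table_parameters: list = field(
        default_factory=lambda: list(DEFAULT_TABLE_PARAMETERS)
    )
    correlation_parameters: list = field(
        default_factory=lambda: list(DEFAULT_CORRELATION_PARAMETERS)
    )
    output_dir: str = "ojip_out"
    seed: int = 0
    heatmap: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_path and self.simulation and not self.merge:
            raise ConfigurationError(
                "config sets both input_path and a simulation block; "
                "set merge: true to combine them"
            )
        if not self.input_path and self.simulation is None:
            self.simulation = SimulationBlock()
        if not isinstance(self.seed, int):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            raw = (json.load(fh) if path.suffix.lower() == ".json"
                   else yaml.safe_load(fh)) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationBlock(**sim)
            cfg.__post_init__()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest.

    Outputs under ``config.output_dir``: ``parameters.csv`` (one JIP row per
    trace), ``report_<axis>.csv``/``.txt`` treatment tables with Duncan
    letters and stars, ``correlation.csv`` (cluster-ordered), optional
    ``correlation_heatmap.png``, ``growth_report.csv`` when harvest data are
    present, ``simulated_transients.csv`` for simulation runs, and
    ``manifest.json`` with seed, versions and output hashes.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    outputs: dict[str, str] = {}

    fiducials = {"O": 50.0, "K": 300.0, "J": 2000.0, "I": 30000.0}
    fiducials.update({k: float(v) for k, v in config.fiducial_times.items()})
    conv = DeexcitationConvention(**config.convention)

    # --- stage: acquire transients -------------------------------------
    traces = []
    harvests = []
    axis = "temperature"
    if config.simulation is not None:
        sim = config.simulation
        axis = sim.axis
        scenarios = sim.resolve_scenarios()
        preset = KineticPreset(**sim.preset)
        t0 = time.perf_counter()
        traces = generate_experiment(
            levels=sim.levels, scenarios=scenarios,
            maturity_groups=sim.maturity_groups, axis=sim.axis,
            n_reps=sim.n_reps, n_meas=sim.n_meas,
            seed=config.seed, preset=preset,
        )
        log.info("simulated %d transients in %.2fs", len(traces),
                 time.perf_counter() - t0)
        sim_path = out_dir / "simulated_transients.csv"
        write_transient_table(traces, sim_path)
        outputs["simulated_transients.csv"] = _sha256(sim_path)
        if sim.harvests:
            harvests = generate_harvests(
                levels=sim.levels, scenarios=scenarios,
                maturity_groups=sim.maturity_groups, axis=sim.axis,
                n_reps=sim.n_reps, seed=config.seed,
            )
    if config.input_path:
        loaded = read_transient_table(config.input_path)
        log.info("loaded %d transients from %s", len(loaded), config.input_path)
        traces = traces + loaded if config.merge else loaded
    if config.harvest_path:
        harvests = read_harvest_table(config.harvest_path)

    # --- stage: JIP engine ---------------------------------------------
    t0 = time.perf_counter()
    params = compute_parameter_table(
        traces, conv, fiducials, config.tolerance_factor
    )
    log.info("computed %d JIP parameter rows in %.2fs", len(params),
             time.perf_counter() - t0)
    params_path = out_dir / "parameters.csv"
    params.to_csv(params_path, index=False)
    outputs["parameters.csv"] = _sha256(params_path)

    # --- stage: treatment statistics ------------------------------------
    t0 = time.perf_counter()
    report, _results = summarize_treatment_table(
        params, axis=axis, columns=config.table_parameters,
        alpha=config.alpha, use_replicate_means=config.use_replicate_means,
    )
    report_path = out_dir / f"report_{axis}.csv"
    report.to_csv(report_path, index=False)
    outputs[report_path.name] = _sha256(report_path)
    txt_path = out_dir / f"report_{axis}.txt"
    txt_path.write_text(report.to_string(index=False) + "\n", encoding="utf-8")
    outputs[txt_path.name] = _sha256(txt_path)

    corr = correlation_matrix(params, subset=config.correlation_parameters)
    corr_path = out_dir / "correlation.csv"
    corr.ordered_frame().to_csv(corr_path)
    outputs["correlation.csv"] = _sha256(corr_path)
    if config.heatmap:
        plot_correlation_heatmap(corr, out_dir / "correlation_heatmap.png")
    log.info("statistics finished in %.2fs", time.perf_counter() - t0)

    # --- stage: growth traits -------------------------------------------
    if harvests:
        growth = biomass_summary(harvests, axis=axis)
        growth_path = out_dir / "growth_report.csv"
        growth.to_csv(growth_path, index=False)
        outputs["growth_report.csv"] = _sha256(growth_path)
        harvest_path = out_dir / "harvests.csv"
        harvest_frame(harvests).to_csv(harvest_path, index=False)
        outputs["harvests.csv"] = _sha256(harvest_path)

    manifest = {
        "ojip_version": __version__,
        "seed": config.seed,
        "n_traces": len(traces),
        "axis": axis,
        "alpha": config.alpha,
        "inputs": {
            "input_path": config.input_path,
            "harvest_path": config.harvest_path,
            "simulated": config.simulation is not None,
        },
        "outputs_sha256": outputs,
        "elapsed_s": round(time.perf_counter() - t_start, 3),
    }
    stable = {k: v for k, v in manifest.items() if k != "elapsed_s"}
    (out_dir / "manifest.json").write_text(
        json.dumps(stable, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    log.info("pipeline complete in %.2fs; outputs in %s",
             manifest["elapsed_s"], out_dir)
    return manifest
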