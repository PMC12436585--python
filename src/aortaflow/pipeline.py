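"""Config-driven orchestration: geometry -> flow -> residence time -> metrics.

A ``ScenarioConfig`` (typically loaded from YAML) fully determines one run:
geometry parameters, surgical scenario, valve size, waveform, Windkessel,
solver and residence-time settings, plus a fidelity profile.  Profiles bundle
resolution defaults:

* ``ci``   — planar 2-D root, 1.6 mm edges, dt 2 ms (desk-scale regression runs);
* ``desk`` — coarse 3-D root, 2.5 mm edges, dt 2 ms;
* ``paper``— 3-D root at 1 mm edges and dt 0.8 ms (publication-grade runs).

In 2-D mode all volumetric fluxes are scaled by the width/area factor of the
annulus disc, and the Windkessel is driven by the equivalent volumetric flux
reconstructed with the same reference diameter, so the printed R and C give
physiological pressures in both modes.

Every run writes its resolved configuration, mesh, traces, fields, metrics
and a JSONL stage log into the output directory; reruns with the same config
and seed are bit-identical in their metric values.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bcs as cbc
from . import io as aio
from . import metrics as M
from .geometry import (ParameterError, RootParameters, Scenario,
                       apply_scenario, build_root_mesh)
from .rt import RTConfig, RTField, run_rt
from .solver import (FluidProperties, SolverConfig, check_mass_balance,
                     run_cycles)

PROFILES = {
    "ci": dict(mode="2d", edge_length=1.6, dt=2.0e-3, cycles=3,
               snapshot_stride=4, rt_dt_factor=4),
    "desk": dict(mode="3d", edge_length=2.5, dt=2.0e-3, cycles=3,
                 snapshot_stride=4, rt_dt_factor=4),
    "paper": dict(mode="3d", edge_length=1.0, dt=8.0e-4, cycles=3,
                  snapshot_stride=8, rt_dt_factor=4),
}


@dataclass
class ScenarioConfig:
    """Validated, fully-resolved description of one pipeline run."""

    label: str = "baseline"
    scenario: str = "baseline"             # baseline | yaae | tavr_in_savr
    valve_diameter: float = 23.0           # implanted internal diameter, mm
    goa_reduction: float = 0.20            # TAVR orifice-area reduction
    profile: str = "ci"
    mode: str = None                       # 2d | 3d (profile default)
    edge_length: float = None              # mm (profile default)
    seed: int = 0
    geometry: dict = dfield(default_factory=dict)
    waveform: dict = dfield(default_factory=dict)
    windkessel: dict = dfield(default_factory=dict)
    flow: dict = dfield(default_factory=dict)
    rt: dict = dfield(default_factory=dict)
    fluid: dict = dfield(default_factory=dict)
    coronary: bool = True

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ParameterError(
                f"unknown profile {self.profile!r}; choose from {list(PROFILES)}")
        prof = PROFILES[self.profile]
        if self.mode is None:
            self.mode = prof["mode"]
        if self.edge_length is None:
            self.edge_length = prof["edge_length"]
        self.flow = {**dict(dt=prof["dt"], cycles=prof["cycles"],
                            snapshot_stride=prof["snapshot_stride"]),
                     **self.flow}
        self.rt = {**dict(rt_dt_factor=prof["rt_dt_factor"]), **self.rt}
        self.scenario = Scenario(self.scenario).value
        # validate eagerly: geometry, valve, waveform, solver settings
        self.resolved_params()
        self.make_waveform()
        self.solver_config()
        self.rt_config()
        self.fluid_properties()

    # -- constructors for the stage objects ------------------------------
    def base_params(self) -> RootParameters:
        return RootParameters(**self.geometry)

    def valve(self) -> cbc.ValveSpec:
        return cbc.ValveSpec(implanted_internal_diameter=self.valve_diameter)

    def resolved_params(self) -> RootParameters:
        return apply_scenario(self.base_params(), self.scenario, self.valve(),
                              goa_reduction=self.goa_reduction)

    def make_waveform(self) -> cbc.CycleWaveform:
        return cbc.CycleWaveform(**self.waveform)

    def windkessel_params(self) -> cbc.WindkesselParams:
        return cbc.WindkesselParams(**self.windkessel)

    def solver_config(self) -> SolverConfig:
        return SolverConfig(**self.flow)

    def rt_config(self) -> RTConfig:
        return RTConfig(**self.rt)

    def fluid_properties(self) -> FluidProperties:
        return FluidProperties(**self.fluid)

    def flux_scales(self, params: RootParameters):
        """(flux_scale, wk_flux_scale) for the chosen mode; the annulus disc
        is the single reference diameter for both directions."""
        if self.mode == "3d":
            return 1.0, 1.0
        d_ref = params.effective_annulus_diameter
        f = cbc.planar_flux_factor(d_ref)
        return f, 1.0 / f

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "label", "scenario", "valve_diameter", "goa_reduction", "profile",
            "mode", "edge_length", "seed", "geometry", "waveform",
            "windkessel", "flow", "rt", "fluid", "coronary")}
        return out

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    mesh: object
    history: object
    rt_field: RTField
    rt_report: pd.DataFrame
    report: M.MetricsReport
    mass_balance: pd.DataFrame
    artifacts: dict


class _StageLog:
    def __init__(self, path: Path | None):
        self.path = path
        self.records = []

    def emit(self, stage: str, **info):
        rec = {"stage": stage, "wall_time_s": round(info.pop("wall", 0.0), 3),
               **info}
        self.records.append(rec)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec, default=str) + "\n")


def run_scenario(config: ScenarioConfig, outdir=None,
                 progress: bool = False) -> ScenarioResult:
    """Execute all stages for one scenario; write artifacts when ``outdir``
    is given.  Any stage failure propagates with the stage recorded in the
    JSONL log (partial artifacts are left in place)."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.resolved.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True))
    log = _StageLog(outdir / "log.jsonl" if outdir else None)

    t0 = time.perf_counter()
    params = config.resolved_params()
    valve = config.valve()
    mesh = build_root_mesh(params, config.edge_length, config.mode,
                           seed=config.seed)
    mesh.validate()
    log.emit("mesh", wall=time.perf_counter() - t0, **mesh.summary())
    artifacts = {}
    if outdir is not None:
        artifacts.update(aio.save_mesh(outdir, "mesh", mesh))

    waveform = config.make_waveform()
    schedule = waveform.schedule()
    wk = config.windkessel_params()
    props = config.fluid_properties()
    solver_cfg = config.solver_config()
    flux_scale, wk_flux_scale = config.flux_scales(params)

    t0 = time.perf_counter()
    try:
        history = run_cycles(mesh, waveform, valve, schedule, props,
                             solver_cfg, wk_params=wk, flux_scale=flux_scale,
                             wk_flux_scale=wk_flux_scale,
                             coronary=config.coronary, progress=progress)
    except Exception as exc:
        log.emit("flow", wall=time.perf_counter() - t0, error=str(exc))
        raise
    log.emit("flow", wall=time.perf_counter() - t0,
             converged=history.converged, note=history.convergence_note)
    balance = check_mass_balance(history, mesh)
    if outdir is not None:
        history.trace_frame().to_csv(outdir / "flow_traces.csv", index=False)
        history.summaries.to_csv(outdir / "flow_cycles.csv", index=False)
        balance.to_csv(outdir / "mass_balance.csv", index=False)
        ipk = int(np.argmax(history.vmax_down))
        isnap = int(np.argmin(np.abs(history.snap_times
                                     - history.times[ipk])))
        aio.write_vtu(outdir / "fields_peak_systole.vtu", mesh, {
            "velocity": history.snap_v[isnap], "pressure": history.snap_p[isnap]})
        np.savez_compressed(outdir / "flow_snapshots.npz",
                            times=history.snap_times, v=history.snap_v,
                            p=history.snap_p, period=history.period,
                            dt=history.dt)
        artifacts["snapshots"] = outdir / "flow_snapshots.npz"

    t0 = time.perf_counter()
    rt_cfg = config.rt_config()
    try:
        rt_field, rt_report = run_rt(history, mesh, rt_cfg, progress=progress)
    except Exception as exc:
        log.emit("rt", wall=time.perf_counter() - t0, error=str(exc))
        raise
    log.emit("rt", wall=time.perf_counter() - t0,
             converged=rt_report.attrs["converged"],
             clipped_fraction=rt_field.clipped_fraction)
    if outdir is not None:
        rt_report.to_csv(outdir / "rt_cycles.csv", index=False)
        aio.write_vtu(outdir / "rt_field.vtu", mesh, {
            "phi": rt_field.phi, "relative_rt": rt_field.relative_rt})
        np.savez_compressed(outdir / "rt_field.npz", phi=rt_field.phi,
                            total_time=rt_field.total_time)

    report = M.build_report(config.label, history, mesh, rt_field, rt_report,
                            valve=valve, config_hash=config.config_hash())
    log.emit("metrics", **report.to_dict())
    if outdir is not None:
        (outdir / "metrics.json").write_text(
            json.dumps(report.to_dict(), indent=2))
    return ScenarioResult(config, mesh, history, rt_field, rt_report, report,
                          balance, artifacts)


@dataclass
class ComparisonReport:
    control: str
    table: pd.DataFrame
    unconverged: list

    def to_csv(self, path):
        self.table.to_csv(path)


def compare_scenarios(reports: list, control: str) -> ComparisonReport:
    """Raw, normalized and percent-change comparison across scenarios.

    ``reports`` are MetricsReports (or ScenarioResults); scenarios whose flow
    or RT run did not meet the cycle-convergence criterion are flagged."""
    reps = [r.report if isinstance(r, ScenarioResult) else r for r in reports]
    if len(reps) < 2:
        raise M.UndefinedComparisonError("need at least two scenarios")
    table = M.comparison_table(reps, control)
    unconv = [r.scenario for r in reps
              if not (r.flow_converged and r.rt_converged)]
    return ComparisonReport(control=control, table=table, unconverged=unconv)
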