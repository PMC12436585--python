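"""Quantitative hemodynamic metrics.

Mirrors the clinical-style quantities used to compare aortic-root scenarios:

* peak velocity — maximum velocity magnitude downstream of the valve plane
  (capped at the 30 mm measurement plane, the jet region an echocardiogram
  would interrogate), over the final cardiac cycle;
* mean TPG — time average, over the forward-flow (valve-open) window, of the
  positive part of the area-averaged pressure difference between the inlet
  plane and the plane 30 mm downstream of the valve;
* relative residence-time statistics — volume-weighted mean, pointwise max,
  and the percentage of lumen volume with relative RT above 0.2;
* group normalization and percent-change reporting conventions.

Pressures are kept in Pa; mmHg values use 1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .bcs import MMHG_PA
from .geometry import ParameterError, TaggedMesh


class UndefinedComparisonError(ValueError):
    """Percent change or normalization against a degenerate reference."""


@dataclass
class MetricsReport:
    scenario: str
    peak_velocity: float          # mm/s
    mean_tpg: float               # Pa
    rt_mean: float                # dimensionless (relative RT)
    rt_max: float
    pct_vol_rt_gt_02: float       # %
    flow_converged: bool = True
    rt_converged: bool = True
    config_hash: str = ""

    def __post_init__(self):
        vals = [self.peak_velocity, self.mean_tpg, self.rt_mean, self.rt_max,
                self.pct_vol_rt_gt_02]
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ParameterError(f"metrics must be finite and >= 0: {vals}")
        if not (0.0 <= self.pct_vol_rt_gt_02 <= 100.0):
            raise ParameterError("pct_vol_rt_gt_02 must lie in [0, 100]")

    @property
    def mean_tpg_mmhg(self) -> float:
        return self.mean_tpg / MMHG_PA

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_tpg_mmhg"] = self.mean_tpg_mmhg
        return d


def _downstream_nodes(mesh: TaggedMesh):
    z_valve = mesh.meta.get("z_valve")
    z_meas = mesh.meta.get("z_meas")
    if z_valve is None:
        raise ParameterError("mesh has no valve plane metadata")
    z = mesh.vertices[:, mesh.axis]
    nodes = np.flatnonzero((z > z_valve) & (z <= z_meas + 1e-9))
    if len(nodes) == 0:
        raise ParameterError("empty region downstream of the valve plane")
    return nodes


def peak_velocity(history, mesh: TaggedMesh, valve=None,
                  cycle: int = -1) -> float:
    """Maximum |v| downstream of the valve over the chosen cycle (default
    last).  Uses the per-step downstream trace recorded by the cycle driver;
    falls back to the stored snapshots when traces are absent."""
    if getattr(history, "vmax_down", None) is not None \
            and len(history.vmax_down):
        cycles = history.cycle
        c = cycles.max() if cycle == -1 else cycle
        sel = cycles == c
        if not sel.any():
            raise ParameterError(f"history has no cycle {cycle}")
        return float(history.vmax_down[sel].max())
    nodes = _downstream_nodes(mesh)
    speeds = np.linalg.norm(history.snap_v[:, nodes, :], axis=2)
    return float(speeds.max())


def peak_velocity_field(v: np.ndarray, mesh: TaggedMesh) -> float:
    """Maximum |v| downstream of the valve for a single velocity field."""
    nodes = _downstream_nodes(mesh)
    return float(np.linalg.norm(v[nodes], axis=1).max())


def mean_tpg(history, mesh: TaggedMesh = None, valve=None,
             cycle: int = -1) -> float:
    """Forward-flow time average of max(P_inlet - P_30mm, 0), in Pa.

    The plane averages are area-weighted; the forward-flow window is the
    valve-open phase.  Gauge invariant: a constant pressure offset cancels
    in the difference.
    """
    cycles = history.cycle
    c = cycles.max() if cycle == -1 else cycle
    sel = (cycles == c) & history.valve_open
    if not sel.any():
        return 0.0
    dp = history.p_in_avg[sel] - history.p_meas_avg[sel]
    return float(np.mean(np.maximum(dp, 0.0)))


def rt_stats(rt, mesh: TaggedMesh) -> dict:
    """Relative residence-time statistics on the lumen.

    Cell values are nodal averages; the mean is cell-volume weighted, the max
    is the pointwise nodal max, and the high-RT volume percentage counts
    cells whose average relative RT exceeds 0.2.
    """
    fd = mesh.fem()
    rel = rt.relative_rt if hasattr(rt, "relative_rt") else np.asarray(rt)
    cell_avg = rel[fd.cells].mean(axis=1)
    vol = fd.vol
    total = vol.sum()
    return {
        "rt_mean": float(np.dot(vol, cell_avg) / total),
        "rt_max": float(rel.max()),
        "pct_vol_rt_gt_02": float(100.0 * vol[cell_avg > 0.2].sum() / total),
    }


def percent_change(treatment: float, control: float) -> float:
    """Percent decrease of treatment vs control: positive when the treatment
    value is lower (the clinical-reporting 'X% decrease' convention)."""
    if control == 0:
        raise UndefinedComparisonError("percent change against a zero control")
    return 100.0 * (control - treatment) / control


def group_normalize(values) -> list:
    """Divide each value by the group's maximum (the max element maps to 1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise UndefinedComparisonError("cannot normalize an empty group")
    m = arr.max()
    if m <= 0:
        raise UndefinedComparisonError("group maximum must be positive")
    return list(arr / m)


def build_report(scenario: str, history, mesh: TaggedMesh, rt_field,
                 rt_report=None, valve=None, config_hash: str = "") \
        -> MetricsReport:
    stats = rt_stats(rt_field, mesh)
    return MetricsReport(
        scenario=scenario,
        peak_velocity=peak_velocity(history, mesh, valve),
        mean_tpg=mean_tpg(history, mesh, valve),
        rt_mean=stats["rt_mean"],
        rt_max=stats["rt_max"],
        pct_vol_rt_gt_02=stats["pct_vol_rt_gt_02"],
        flow_converged=bool(history.converged),
        rt_converged=bool(rt_report.attrs.get("converged", True))
        if rt_report is not None else True,
        config_hash=config_hash,
    )


def comparison_table(reports: list, control: str) -> pd.DataFrame:
    """Raw, group-normalized and percent-change table across scenarios."""
    labels = [r.scenario for r in reports]
    if control not in labels:
        raise UndefinedComparisonError(
            f"control scenario {control!r} not among {labels}")
    ctrl = reports[labels.index(control)]
    cols = ["peak_velocity", "mean_tpg", "rt_mean", "rt_max",
            "pct_vol_rt_gt_02"]
    rows = []
    for r in reports:
        row = {"scenario": r.scenario}
        for c in cols:
            row[c] = getattr(r, c)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("scenario")
    for c in cols:
        vals = df[c].to_numpy()
        if vals.max() > 0:
            df[f"{c}_normalized"] = vals / vals.max()
        ref = getattr(ctrl, c)
        df[f"{c}_pct_change_vs_{control}"] = [
            percent_change(v, ref) if ref != 0 else np.nan for v in vals]
    return df
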