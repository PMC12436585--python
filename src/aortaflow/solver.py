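"""Stabilized P1-P1 finite-element solver for incompressible Navier-Stokes.

Momentum and continuity are discretized with equal-order linear elements made
inf-sup stable by residual-based SUPG/PSPG terms (plus an element-Reynolds
scaled grad-div term), backward-Euler time stepping and Picard linearization
of advection.  The Cauchy stress uses the standard incompressible form
sigma = mu (grad v + grad v^T) - p I.  Outflow boundaries carry a Neumann
traction -P n driven by a two-element Windkessel updated inside the Picard
loop (implicit coupling), plus a backflow penalty that stabilizes flow
reversal during deceleration.  The aortic valve is an orifice plane whose
Dirichlet constraint set flips instantaneously at the systole boundaries.

Units: mm-g-s (velocity mm/s, pressure Pa).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from dataclasses import dataclass

from . import bcs as cbc
from .fem import FemData
from .geometry import FacetTag, ParameterError, TaggedMesh


class StepFailureError(RuntimeError):
    """Nonlinear divergence inside a time step; carries the increment history."""

    def __init__(self, message, residual_history=None, time=None):
        super().__init__(message)
        self.residual_history = residual_history or []
        self.time = time


class ConfigurationError(RuntimeError):
    """Mesh/BC inconsistency (missing tags, singular system setup)."""


@dataclass(frozen=True)
class FluidProperties:
    """Blood as an incompressible Newtonian fluid (1.026 g/ml, 4 mPa·s)."""

    density: float = 1.026e-3     # g/mm^3
    viscosity: float = 0.004      # Pa·s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ParameterError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass
class SolverConfig:
    dt: float = 8e-4                    # s
    cycles: int = 3
    nonlinear_tolerance: float = 1e-3   # relative velocity increment
    max_nonlinear_iters: int = 10
    convergence_threshold: float = 0.05  # cycle-to-cycle, peak velocity & TPG
    supg: bool = True
    grad_div: bool = True
    backflow_penalty: bool = True
    wk_subiter_tol: float = 1e-6
    snapshot_stride: int = 4

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.cycles < 1:
            raise ParameterError("cycles must be >= 1")
        if not (0.0 < self.convergence_threshold < 1.0):
            raise ParameterError("convergence_threshold must lie in (0,1)")


@dataclass
class FlowState:
    v: np.ndarray       # (n, d) mm/s
    p: np.ndarray       # (n,) Pa
    time: float = 0.0

    @classmethod
    def zero(cls, mesh: TaggedMesh, time: float = 0.0) -> "FlowState":
        n = mesh.vertices.shape[0]
        return cls(np.zeros((n, mesh.dim)), np.zeros(n), time)


@dataclass
class FlowHistory:
    """Per-step traces, final-cycle snapshots and per-cycle summaries."""

    times: np.ndarray
    q_in: np.ndarray
    q_out: np.ndarray
    q_cor: np.ndarray
    vmax_down: np.ndarray
    p_in_avg: np.ndarray
    p_meas_avg: np.ndarray
    p_wk: np.ndarray
    valve_open: np.ndarray
    cycle: np.ndarray
    snap_times: np.ndarray
    snap_v: np.ndarray          # (ns, n, d)
    snap_p: np.ndarray          # (ns, n)
    summaries: pd.DataFrame
    converged: bool
    convergence_note: str
    period: float
    dt: float

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times, "cycle": self.cycle, "valve_open": self.valve_open,
            "Q_in": self.q_in, "Q_out": self.q_out, "Q_cor": self.q_cor,
            "P_wk": self.p_wk, "vmax_downstream": self.vmax_down,
            "P_inlet_avg": self.p_in_avg, "P_meas_avg": self.p_meas_avg,
        })


# ---------------------------------------------------------------------------
# boundary-condition resolution
# ---------------------------------------------------------------------------

@dataclass
class StepBC:
    """Resolved boundary data for one time step."""

    dirichlet_nodes: np.ndarray          # (k,)
    dirichlet_values: np.ndarray         # (k, d)
    neumann: list                        # [(FacetGroup, pressure Pa)]
    backflow_groups: list                # [FacetGroup]
    wk_outlet_index: int | None = None   # which neumann entry the WK drives
    tie_pairs: np.ndarray | None = None  # (k, 2) node twins merged (open valve)


def valve_constraints(mesh: TaggedMesh, valve, phase) -> np.ndarray:
    """Node set pinned to zero velocity by the orifice-plane valve.

    CLOSED blocks the whole plane; OPEN blocks only the annulus ring outside
    the geometric orifice (empty for funnel-insert meshes, where the ring is
    already a structural wall).
    """
    orifice = mesh.nodes_with_tag(FacetTag.VALVE_ORIFICE)
    annulus = mesh.nodes_with_tag(FacetTag.VALVE_ANNULUS)
    if len(orifice) == 0:
        raise ConfigurationError("mesh has no VALVE_ORIFICE facets")
    if valve is not None and not mesh.meta.get("has_insert", False):
        lateral = mesh.vertices[orifice, :-1]
        r = np.linalg.norm(lateral, axis=1) if mesh.dim == 3 \
            else np.abs(lateral[:, 0])
        if r.max() > 0.5 * valve.goa_diameter + 1e-9:
            raise ConfigurationError(
                "orifice facets extend beyond the valve's geometric orifice")
    phase = cbc.ValvePhase(phase)
    if phase is cbc.ValvePhase.CLOSED:
        return np.union1d(orifice, annulus)
    return annulus


class BoundarySuite:
    """Maps the cardiac waveform/schedule onto the mesh tags.

    ``flux_scale`` converts physiological volumetric fluxes to the mesh's
    flux units (1 for 3-D; width/area of the inlet disc for planar 2-D).
    ``wk_flux_scale`` converts the mesh outlet flux back to mm^3/s to drive
    the Windkessel (the reciprocal factor, for 2-D).
    """

    def __init__(self, mesh: TaggedMesh, waveform: cbc.CycleWaveform,
                 schedule: cbc.ValveSchedule, wk_params: cbc.WindkesselParams,
                 valve=None, flux_scale: float = 1.0,
                 wk_flux_scale: float = 1.0, coronary: bool = True,
                 wk_initial_pressure: float | None = None):
        self.mesh = mesh
        self.fd = mesh.fem()
        self.waveform = waveform
        self.schedule = schedule
        self.wk_params = wk_params
        self.valve = valve
        self.flux_scale = flux_scale
        self.wk_flux_scale = wk_flux_scale

        self.inlet = mesh.group(FacetTag.INLET)
        self.outlet = mesh.group(FacetTag.OUTLET)
        if len(self.inlet.facets) == 0 or len(self.outlet.facets) == 0:
            raise ConfigurationError("mesh lacks INLET/OUTLET facets")
        self.cor_groups = []
        if coronary:
            for tag in (FacetTag.CORONARY_L, FacetTag.CORONARY_R):
                g = mesh.group(tag)
                if len(g.facets):
                    self.cor_groups.append(g)
        self.wall_nodes = mesh.nodes_with_tag(FacetTag.WALL)
        self.orifice_nodes = mesh.nodes_with_tag(FacetTag.VALVE_ORIFICE)
        self.annulus_nodes = mesh.nodes_with_tag(FacetTag.VALVE_ANNULUS)

        # inlet plug shape, normalized to unit inflow through the plane
        n = mesh.vertices.shape[0]
        self.axis = mesh.axis
        shape = np.zeros(n)
        shape[self.inlet.nodes] = 1.0
        shape[self.wall_nodes] = 0.0
        sv = np.zeros((n, mesh.dim))
        sv[:, self.axis] = shape
        f = self.inlet.flux(sv)        # negative: the inlet normal is -z
        if abs(f) < 1e-14:
            raise ConfigurationError("inlet plug shape has zero flux")
        self.inlet_shape = shape / (-f)
        # per-ostium outward shapes, normalized to unit outflow
        self.cor_shapes = []
        for g in self.cor_groups:
            nrm = np.zeros((n, mesh.dim))
            for a in range(g.facets.shape[1]):
                np.add.at(nrm, g.facets[:, a], g.normals)
            keep = np.zeros(n, dtype=bool)
            keep[g.nodes] = True
            nrm[~keep] = 0.0
            lens = np.linalg.norm(nrm, axis=1)
            nz = lens > 0
            nrm[nz] /= lens[nz][:, None]
            f = g.flux(nrm)
            if abs(f) < 1e-14:
                raise ConfigurationError("coronary ostium has zero flux shape")
            self.cor_shapes.append(nrm / f)

        p0 = (cbc.wk2_steady_pressure(waveform.mean_cardiac_output, wk_params)
              if wk_initial_pressure is None else wk_initial_pressure)
        self.wk_state = cbc.WindkesselState(pressure=p0, time=0.0)

    def phase_at(self, t: float) -> cbc.ValvePhase:
        return self.schedule.state(t)

    def conditions_at(self, t: float, wk_pressure: float) -> StepBC:
        mesh = self.mesh
        n, d = mesh.vertices.shape[0], mesh.dim
        open_ = self.phase_at(t) is cbc.ValvePhase.OPEN

        vals = np.zeros((n, d))
        pinned = np.zeros(n, dtype=bool)
        pinned[self.wall_nodes] = True
        pinned[self.annulus_nodes] = True
        if not open_:
            pinned[self.orifice_nodes] = True

        neumann = [(self.outlet, wk_pressure)]
        backflow = [self.outlet]
        if open_:
            q = float(self.waveform.inlet_flux(t)) * self.flux_scale
            free_inlet = self.inlet.nodes[~pinned[self.inlet.nodes]]
            vals[free_inlet, self.axis] = q * self.inlet_shape[free_inlet]
            pinned[self.inlet.nodes] = True
        else:
            p_in = float(self.waveform.diastolic_inlet_pressure(t))
            neumann.append((self.inlet, p_in))
            backflow.append(self.inlet)

        q_cor = float(self.waveform.coronary_flux(t)) * self.flux_scale
        for g, shp in zip(self.cor_groups, self.cor_shapes):
            free = g.nodes[~pinned[g.nodes]]
            if q_cor > 0:
                vals[free] = (q_cor / len(self.cor_shapes)) * shp[free]
            pinned[g.nodes] = True

        nodes = np.flatnonzero(pinned)
        ties = self.mesh.node_pairs if open_ else None
        return StepBC(nodes, vals[nodes], neumann, backflow,
                      wk_outlet_index=0, tie_pairs=ties)

    def wk_candidate(self, q_out_mesh: float, dt: float):
        """Windkessel state advanced with the given (mesh-units) outlet flux."""
        return cbc.wk2_advance(self.wk_state, q_out_mesh * self.wk_flux_scale,
                               dt, self.wk_params)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class _Assembler:
    """Precomputed dof-index arrays and local matrices for one mesh."""

    def __init__(self, fd: FemData):
        d, nl = fd.dim, fd.dim + 1
        self.n_u = fd.n_nodes * d
        self.n_dofs = fd.n_nodes * (d + 1)
        cells = fd.cells
        udof = (cells[:, :, None] * d + np.arange(d)).reshape(-1, nl * d)
        pdof = self.n_u + cells
        self.udof, self.pdof = udof, pdof

        def grid(r, c):
            return (np.repeat(r[:, :, None], c.shape[1], axis=2),
                    np.repeat(c[:, None, :], r.shape[1], axis=1))

        self.uu = grid(udof, udof)
        self.up = grid(udof, pdof)
        self.pu = grid(pdof, udof)
        self.pp = grid(pdof, pdof)
        self.mloc = (1.0 + np.eye(nl)) / ((nl) * (nl + 1))
        self.gg = np.einsum("mak,mbk->mab", fd.grads, fd.grads)
        self.eye_d = np.eye(d)


def _element_tau(fd: FemData, props: FluidProperties, abar, dt):
    nu = props.kinematic_viscosity
    anorm = np.linalg.norm(abar, axis=1)
    terms = (2.0 * anorm / fd.h) ** 2 + (12.0 * nu / fd.h ** 2) ** 2
    if dt is not None:
        terms = terms + (2.0 / dt) ** 2
    return 1.0 / np.sqrt(terms)


def _assemble_blocks(fd: FemData, props: FluidProperties, cfg: SolverConfig,
                     asm: _Assembler, v_adv, v_old, dt):
    """Element matrices/RHS of the stabilized weak form for one iteration."""
    d, nl, m = fd.dim, fd.dim + 1, fd.n_cells
    V, g = fd.vol, fd.grads
    rho, mu = props.density, props.viscosity
    abar = v_adv[fd.cells].mean(axis=1)
    tau = _element_tau(fd, props, abar, dt)
    adv = np.einsum("mk,mak->ma", abar, g)     # (m, a) = a·grad(phi_a)
    Vc = V[:, None, None]

    # scalar (delta_ij) coefficient of the velocity block
    s = mu * asm.gg * Vc
    s = s + rho * (Vc / nl) * adv[:, None, :]
    if dt is not None:
        s = s + (rho / dt) * Vc * asm.mloc[None, :, :]
    if cfg.supg:
        s = s + rho * tau[:, None, None] * Vc * adv[:, :, None] * adv[:, None, :]
        if dt is not None:
            s = s + (rho / dt) * (tau[:, None, None] * Vc / nl) \
                * np.broadcast_to(adv[:, :, None], (m, nl, nl))

    Auu = np.einsum("mab,ij->maibj", s, asm.eye_d)
    # symmetric-gradient coupling: mu V g_b[i] g_a[j]
    Auu = Auu + mu * V[:, None, None, None, None] \
        * np.einsum("mbi,maj->maibj", g, g)
    if cfg.grad_div:
        anorm = np.linalg.norm(abar, axis=1)
        re_h = rho * anorm * fd.h / (2.0 * mu)
        nu_l = 0.5 * rho * anorm * fd.h * np.minimum(re_h / 3.0, 1.0)
        Auu = Auu + (nu_l * V)[:, None, None, None, None] \
            * np.einsum("mai,mbj->maibj", g, g)

    # velocity-pressure block: Galerkin -V/nl g_a[i], SUPG tau (a·g_a) g_b[i]
    Aup = np.broadcast_to(-(V[:, None, None] / nl * g)[:, :, :, None],
                          (m, nl, d, nl)).copy()
    if cfg.supg:
        Aup = Aup + tau[:, None, None, None] * V[:, None, None, None] \
            * adv[:, :, None, None] * np.transpose(g, (0, 2, 1))[:, None, :, :]

    # pressure-velocity block: Galerkin V/nl g_b[j], PSPG mass + advection
    Apu = np.broadcast_to((V[:, None, None, None] / nl) * g[:, None, :, :],
                          (m, nl, nl, d)).copy()
    if dt is not None:
        Apu = Apu + (tau / dt)[:, None, None, None] \
            * (V[:, None, None, None] / nl) \
            * np.broadcast_to(g[:, :, None, :], (m, nl, nl, d))
    Apu = Apu + tau[:, None, None, None] * V[:, None, None, None] \
        * adv[:, None, :, None] * g[:, :, None, :]

    App = (tau / rho)[:, None, None] * Vc * asm.gg

    bu = np.zeros((m, nl, d))
    bp = np.zeros((m, nl))
    if dt is not None:
        uold = v_old[fd.cells]
        ubar = uold.mean(axis=1)
        bu = bu + (rho / dt) * Vc * np.einsum("ab,mbi->mai", asm.mloc, uold)
        if cfg.supg:
            bu = bu + (rho / dt) * (tau[:, None] * V[:, None])[:, :, None] \
                * adv[:, :, None] * ubar[:, None, :]
        bp = bp + (tau / dt)[:, None] * V[:, None] \
            * np.einsum("mak,mk->ma", g, ubar)

    return (Auu.reshape(m, nl * d, nl * d), Aup.reshape(m, nl * d, nl),
            Apu.reshape(m, nl, nl * d), App,
            bu.reshape(m, nl * d), bp)


class FlowProblem:
    """Stabilized Navier-Stokes problem bound to one mesh."""

    def __init__(self, mesh: TaggedMesh, props: FluidProperties,
                 config: SolverConfig):
        self.mesh = mesh
        self.props = props
        self.config = config
        self.fd = mesh.fem()
        self.asm = _Assembler(self.fd)

    def _linear_system(self, v_adv, v_old, dt, bc: StepBC):
        fd, asm, d = self.fd, self.asm, self.fd.dim
        Auu, Aup, Apu, App, bu_el, bp_el = _assemble_blocks(
            fd, self.props, self.config, asm, v_adv, v_old, dt)
        rows = [asm.uu[0], asm.up[0], asm.pu[0], asm.pp[0]]
        cols = [asm.uu[1], asm.up[1], asm.pu[1], asm.pp[1]]
        vals = [Auu, Aup, Apu, App]
        b = np.zeros(asm.n_dofs)
        np.add.at(b, asm.udof.ravel(), bu_el.ravel())
        np.add.at(b, asm.pdof.ravel(), bp_el.ravel())

        # Neumann tractions t = -P n
        for group, pressure in bc.neumann:
            if len(group.facets) == 0:
                continue
            nlf = group.facets.shape[1]
            contrib = -pressure * group.normals * (group.measures / nlf)[:, None]
            dofs = group.facets[:, :, None] * d + np.arange(d)  # (f, nlf, d)
            valsb = np.broadcast_to(contrib[:, None, :], dofs.shape)
            np.add.at(b, dofs.ravel(), valsb.ravel())

        # backflow penalty on Neumann boundaries
        rho = self.props.density
        extra_r, extra_c, extra_v = [], [], []
        if self.config.backflow_penalty:
            for group in bc.backflow_groups:
                if len(group.facets) == 0:
                    continue
                nlf = group.facets.shape[1]
                mloc_f = (1.0 + np.eye(nlf)) / (nlf * (nlf + 1))
                vn = np.einsum("fi,fi->f", v_adv[group.facets].mean(axis=1),
                               group.normals)
                beta = -0.5 * rho * np.minimum(vn, 0.0) * group.measures
                if not np.any(beta > 0):
                    continue
                blk = beta[:, None, None] * mloc_f[None, :, :]  # (f,a,b)
                for i in range(d):
                    fdof = group.facets * d + i                 # (f, nlf)
                    r = np.repeat(fdof[:, :, None], nlf, axis=2)
                    c = np.repeat(fdof[:, None, :], nlf, axis=1)
                    extra_r.append(r)
                    extra_c.append(c)
                    extra_v.append(blk)

        r_all = np.concatenate([x.ravel() for x in rows + extra_r])
        c_all = np.concatenate([x.ravel() for x in cols + extra_c])
        v_all = np.concatenate([x.astype(float).ravel()
                                for x in vals + extra_v])

        # merge valve-plane twin dofs when the orifice is open
        tie_up = None
        if bc.tie_pairs is not None and len(bc.tie_pairs):
            lo, up = bc.tie_pairs[:, 0], bc.tie_pairs[:, 1]
            mmap = np.arange(asm.n_dofs)
            for i in range(d):
                mmap[up * d + i] = lo * d + i
            mmap[asm.n_u + up] = asm.n_u + lo
            r_all = mmap[r_all]
            c_all = mmap[c_all]
            tie_up = np.concatenate([(up[:, None] * d
                                      + np.arange(d)).ravel(),
                                     asm.n_u + up])
            tie_lo = np.concatenate([(lo[:, None] * d
                                      + np.arange(d)).ravel(),
                                     asm.n_u + lo])
            np.add.at(b, mmap[tie_up], b[tie_up])
            b[tie_up] = 0.0

        # Dirichlet velocity rows -> identity
        udirs = (bc.dirichlet_nodes[:, None] * d + np.arange(d)).ravel()
        uvals = bc.dirichlet_values.ravel()
        mask = np.zeros(asm.n_dofs, dtype=bool)
        mask[udirs] = True
        keep = ~mask[r_all]
        r_all = np.concatenate([r_all[keep], udirs])
        c_all = np.concatenate([c_all[keep], udirs])
        v_all = np.concatenate([v_all[keep], np.ones(len(udirs))])
        b[udirs] = uvals

        # twin equality rows x_up - x_lo = 0 (skip Dirichlet-owned rows)
        if tie_up is not None:
            free = ~mask[tie_up]
            tu, tl = tie_up[free], tie_lo[free]
            r_all = np.concatenate([r_all, tu, tu])
            c_all = np.concatenate([c_all, tu, tl])
            v_all = np.concatenate([v_all, np.ones(len(tu)),
                                    -np.ones(len(tu))])
            b[tu] = 0.0

        A = sp.coo_matrix((v_all, (r_all, c_all)),
                          shape=(asm.n_dofs, asm.n_dofs)).tocsr()
        return A, b

    def _solve(self, A, b):
        x = spla.spsolve(A, b)
        if not np.all(np.isfinite(x)):
            raise ConfigurationError(
                "singular or ill-posed system (is the pressure level pinned "
                "by any Neumann boundary?)")
        return x

    def _split(self, x):
        n, d = self.fd.n_nodes, self.fd.dim
        return x[:n * d].reshape(n, d), x[n * d:]

    def step(self, state: FlowState, bc: StepBC, dt: float | None = None,
             wk_suite: BoundarySuite | None = None) -> FlowState:
        """One backward-Euler step with Picard sub-iterations.

        When ``wk_suite`` is given, the outlet Windkessel pressure is updated
        from the current iterate's outlet flux inside the loop, giving the
        implicit flow/Windkessel coupling.
        """
        cfg = self.config
        dt = cfg.dt if dt is None else dt
        v_adv = state.v
        v_new, p_new = state.v, state.p
        neumann = list(bc.neumann)
        history = []
        wk_new = None
        for _ in range(cfg.max_nonlinear_iters):
            cur_bc = StepBC(bc.dirichlet_nodes, bc.dirichlet_values,
                            neumann, bc.backflow_groups, bc.wk_outlet_index,
                            bc.tie_pairs)
            A, rhs = self._linear_system(v_adv, state.v, dt, cur_bc)
            x = self._solve(A, rhs)
            v_new, p_new = self._split(x)
            incr = np.linalg.norm(v_new - v_adv) \
                / max(np.linalg.norm(v_new), 1e-12)
            history.append(incr)
            v_adv = v_new
            wk_rel = 0.0
            if wk_suite is not None and bc.wk_outlet_index is not None:
                q_out = wk_suite.outlet.flux(v_new)
                wk_new = wk_suite.wk_candidate(q_out, dt)
                idx = bc.wk_outlet_index
                old_p = neumann[idx][1]
                wk_rel = abs(wk_new.pressure - old_p) \
                    / max(abs(wk_new.pressure), 1.0)
                neumann[idx] = (neumann[idx][0], wk_new.pressure)
            if incr < cfg.nonlinear_tolerance and wk_rel < cfg.wk_subiter_tol:
                break
        if not np.all(np.isfinite(v_new)) or (
                len(history) >= 3 and history[-1] > max(1.0, 2.0 * history[0])):
            raise StepFailureError(
                f"nonlinear divergence at t={state.time + dt:.5f}s",
                residual_history=history, time=state.time + dt)
        if wk_suite is not None and wk_new is not None:
            wk_suite.wk_state = wk_new
        return FlowState(v_new, p_new, state.time + dt)

    def solve_steady(self, bc: StepBC, picard_iters: int = 20,
                     tol: float = 1e-9) -> FlowState:
        """Steady solution (time terms dropped) by Picard iteration from rest."""
        n = self.fd.n_nodes
        v_adv = np.zeros((n, self.fd.dim))
        p_new = np.zeros(n)
        for _ in range(picard_iters):
            A, rhs = self._linear_system(v_adv, v_adv, None, bc)
            x = self._solve(A, rhs)
            v_new, p_new = self._split(x)
            incr = np.linalg.norm(v_new - v_adv) \
                / max(np.linalg.norm(v_new), 1e-12)
            v_adv = v_new
            if incr < tol:
                break
        return FlowState(v_adv, p_new, 0.0)

    def divergence_norm(self, v: np.ndarray) -> float:
        """L2 norm of the discrete divergence of a nodal velocity field."""
        fd = self.fd
        div = np.einsum("mak,mak->m", fd.grads, v[fd.cells])
        return float(np.sqrt(np.sum(div ** 2 * fd.vol)))


def step_flow(state: FlowState, mesh: TaggedMesh, bc: StepBC,
              props: FluidProperties, config: SolverConfig) -> FlowState:
    """One time step with fixed, pre-resolved boundary data."""
    return FlowProblem(mesh, props, config).step(state, bc)


# ---------------------------------------------------------------------------
# cycle driver
# ---------------------------------------------------------------------------

def run_cycles(mesh: TaggedMesh, waveform: cbc.CycleWaveform, valve,
               schedule: cbc.ValveSchedule, props: FluidProperties,
               config: SolverConfig, wk_params: cbc.WindkesselParams = None,
               flux_scale: float = 1.0, wk_flux_scale: float = 1.0,
               coronary: bool = True, progress: bool = False) -> FlowHistory:
    """Integrate cardiac cycles with phase-switched boundary conditions and
    the implicitly coupled Windkessel, recording per-step traces, final-cycle
    snapshots and per-cycle summaries with a convergence verdict."""
    wk_params = wk_params or cbc.WindkesselParams()
    suite = BoundarySuite(mesh, waveform, schedule, wk_params, valve=valve,
                          flux_scale=flux_scale, wk_flux_scale=wk_flux_scale,
                          coronary=coronary)
    problem = FlowProblem(mesh, props, config)
    fd = mesh.fem()
    dt = config.dt
    period = waveform.period
    steps_per_cycle = max(1, int(round(period / dt)))
    dt = period / steps_per_cycle      # snap to an integer cycle division
    n_steps = steps_per_cycle * config.cycles

    axis = mesh.axis
    z_valve = mesh.meta.get("z_valve")
    if z_valve is not None:
        z = mesh.vertices[:, axis]
        z_meas = mesh.meta["z_meas"]
        down_nodes = np.flatnonzero((z > z_valve) & (z <= z_meas + 1e-9))
        meas_facets = mesh.plane_facets(z_meas)
        if len(meas_facets) == 0:
            raise ConfigurationError(
                "no mesh plane 30 mm downstream of the valve")
        meas_group = fd.facet_group(meas_facets, orient_axis=axis)
    else:
        down_nodes = np.arange(mesh.vertices.shape[0])
        meas_group = suite.outlet

    state = FlowState.zero(mesh)
    rec = {k: [] for k in ("t", "q_in", "q_out", "q_cor", "vmax", "p_in",
                           "p_meas", "p_wk", "open", "cycle")}
    snap_t, snap_v, snap_p = [], [], []
    last_cycle_start = (config.cycles - 1) * steps_per_cycle

    def snapshot(st):
        snap_t.append(st.time)
        snap_v.append(st.v.copy())
        snap_p.append(st.p.copy())

    if config.cycles == 1:
        snapshot(state)
    for k in range(n_steps):
        t_new = (k + 1) * dt
        bc = suite.conditions_at(t_new, suite.wk_state.pressure)
        state = problem.step(state, bc, dt=dt, wk_suite=suite)

        rec["t"].append(t_new)
        rec["q_in"].append(-suite.inlet.flux(state.v))
        rec["q_out"].append(suite.outlet.flux(state.v))
        rec["q_cor"].append(sum(g.flux(state.v) for g in suite.cor_groups))
        rec["p_wk"].append(suite.wk_state.pressure)
        rec["open"].append(suite.phase_at(t_new) is cbc.ValvePhase.OPEN)
        rec["cycle"].append(k // steps_per_cycle)
        rec["vmax"].append(
            float(np.linalg.norm(state.v[down_nodes], axis=1).max()))
        rec["p_in"].append(suite.inlet.average(state.p))
        rec["p_meas"].append(meas_group.average(state.p))

        r = k + 1 - last_cycle_start
        if r >= 0 and (r % config.snapshot_stride == 0 or r == steps_per_cycle):
            snapshot(state)
        if progress and (k + 1) % steps_per_cycle == 0:
            print(f"  cycle {k // steps_per_cycle + 1}/{config.cycles} done "
                  f"(P_wk={suite.wk_state.pressure:.0f} Pa)")

    arr = {k: np.asarray(v) for k, v in rec.items()}
    summaries = _cycle_summaries(arr, steps_per_cycle, config.cycles, dt,
                                 waveform, flux_scale)
    converged, note = _convergence_verdict(summaries,
                                           config.convergence_threshold)
    return FlowHistory(
        times=arr["t"], q_in=arr["q_in"], q_out=arr["q_out"],
        q_cor=arr["q_cor"], vmax_down=arr["vmax"], p_in_avg=arr["p_in"],
        p_meas_avg=arr["p_meas"], p_wk=arr["p_wk"], valve_open=arr["open"],
        cycle=arr["cycle"], snap_times=np.asarray(snap_t),
        snap_v=np.asarray(snap_v), snap_p=np.asarray(snap_p),
        summaries=summaries, converged=converged, convergence_note=note,
        period=period, dt=dt)


def _cycle_summaries(arr, steps_per_cycle, cycles, dt, waveform, flux_scale):
    rows = []
    sv_mesh = waveform.stroke_volume * flux_scale
    for c in range(cycles):
        s = slice(c * steps_per_cycle, (c + 1) * steps_per_cycle)
        open_ = arr["open"][s]
        dp = arr["p_in"][s] - arr["p_meas"][s]
        mean_tpg = float(np.mean(np.maximum(dp[open_], 0.0))) \
            if open_.any() else 0.0
        vin = float(np.sum(arr["q_in"][s]) * dt)
        vout = float(np.sum(arr["q_out"][s]) * dt)
        vcor = float(np.sum(arr["q_cor"][s]) * dt)
        imb = vin - vout - vcor
        rows.append(dict(
            cycle=c + 1,
            peak_velocity=float(arr["vmax"][s].max()),
            mean_tpg=mean_tpg,
            inflow_volume=vin, outflow_volume=vout, coronary_volume=vcor,
            imbalance=imb, imbalance_fraction=imb / sv_mesh,
        ))
    return pd.DataFrame(rows)


def _convergence_verdict(summaries: pd.DataFrame, threshold: float):
    if len(summaries) < 2:
        return False, "insufficient cycles (need >= 2 to compare)"
    pv = summaries["peak_velocity"].to_numpy()
    tpg = summaries["mean_tpg"].to_numpy()
    dpv = abs(pv[-1] - pv[-2]) / max(abs(pv[-1]), 1e-12)
    dtpg = abs(tpg[-1] - tpg[-2]) / max(abs(tpg[-1]), 1e-12)
    ok = (dpv < threshold) and (dtpg < threshold)
    note = (f"peak-velocity delta {dpv:.3%}, mean-TPG delta {dtpg:.3%} "
            f"(threshold {threshold:.0%})")
    return bool(ok), note


def check_mass_balance(history: FlowHistory, mesh: TaggedMesh = None
                       ) -> pd.DataFrame:
    """Per-cycle volume bookkeeping: integral of (Q_in - Q_out - Q_cor) dt as
    an absolute volume and as a fraction of the prescribed stroke volume."""
    if len(history.times) == 0:
        raise ParameterError("empty history")
    cols = ["cycle", "inflow_volume", "outflow_volume", "coronary_volume",
            "imbalance", "imbalance_fraction"]
    return history.summaries[cols].copy()
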