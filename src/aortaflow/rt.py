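"""Blood residence-time transport: source-driven advection of a clock field.

The residence time phi satisfies  d(phi)/dt + v·grad(phi) - div(D grad phi) = 1
with phi = 0 on the inflow and outflow planes and zero diffusive flux
elsewhere; the diffusivity D defaults to zero (pure advection).  The unit
source makes phi grow one second per second unless washed out, so phi/T (the
relative residence time, in [0,1]) maps stasis: 1 means the fluid never left
the domain, 0 means immediate washout.

The advective field replays the stored final cardiac cycle of a flow solution
periodically (linear interpolation between snapshots).  Discretization: P1
elements with streamline-upwind (SUPG) stabilization and backward-Euler
stepping; with v = 0 and D = 0 the consistent formulation grows phi by
exactly dt per step away from the Dirichlet boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import FemData
from .geometry import FacetTag, ParameterError, TaggedMesh


class RTPeriodicityError(ValueError):
    """The stored velocity record is not (approximately) cycle-periodic."""


@dataclass
class RTConfig:
    diffusivity: float = 0.0            # mm^2/s
    rt_cycles: int = 14
    convergence_threshold: float = 0.05  # relative change of mean RT per cycle
    rt_dt_factor: int = 4               # RT step = factor x flow step
    stabilization: str = "upwind"       # upwind (monotone) | supg
    dirichlet_coronary: bool = False    # phi = 0 at coronary ostia too
    periodicity_tol: float = 0.25       # relative first/last snapshot mismatch
    cfl_warn: float = 20.0              # warn above this advective CFL

    def __post_init__(self):
        if self.diffusivity < 0:
            raise ParameterError("diffusivity must be >= 0")
        if self.rt_cycles < 2:
            raise ParameterError("rt_cycles must be >= 2")
        if self.stabilization not in ("upwind", "supg"):
            raise ParameterError(
                f"stabilization must be 'upwind' or 'supg', "
                f"got {self.stabilization!r}")


@dataclass
class RTField:
    """Residence-time field phi (seconds) and its relative form phi/T."""

    phi: np.ndarray
    total_time: float
    clip_tolerance: float = 1e-6

    @property
    def relative_rt(self) -> np.ndarray:
        return np.clip(self.phi / self.total_time, 0.0, 1.0)

    @property
    def clipped_fraction(self) -> float:
        """Fraction of nodes whose phi/T fell outside [0,1] (stabilization
        under/overshoot) and was clipped."""
        r = self.phi / self.total_time
        return float(np.mean((r < -self.clip_tolerance)
                             | (r > 1.0 + self.clip_tolerance)))


def _rt_dirichlet_nodes(mesh: TaggedMesh, config: RTConfig) -> np.ndarray:
    tags = [FacetTag.INLET, FacetTag.OUTLET]
    if config.dirichlet_coronary:
        tags += [FacetTag.CORONARY_L, FacetTag.CORONARY_R]
    return mesh.nodes_with_tag(*tags)


class RTProblem:
    """Stabilized scalar transport bound to one mesh."""

    def __init__(self, mesh: TaggedMesh, config: RTConfig):
        self.mesh = mesh
        self.config = config
        self.fd: FemData = mesh.fem()
        fd = self.fd
        nl = fd.dim + 1
        # valve-plane twin nodes (the flow solver's sealing crack) are always
        # merged for the scalar: residence time advects through an open valve
        self.master = np.arange(fd.n_nodes)
        if mesh.node_pairs is not None and len(mesh.node_pairs):
            self.master[mesh.node_pairs[:, 1]] = mesh.node_pairs[:, 0]
        cells = self.master[fd.cells]
        self.conn = cells
        self.rows = np.repeat(cells[:, :, None], nl, axis=2)
        self.cols = np.repeat(cells[:, None, :], nl, axis=1)
        self.mloc = (1.0 + np.eye(nl)) / (nl * (nl + 1))
        self.gg = np.einsum("mak,mbk->mab", fd.grads, fd.grads)
        self.dirichlet = np.unique(self.master[_rt_dirichlet_nodes(mesh, config)])
        self.orphans = np.flatnonzero(self.master != np.arange(fd.n_nodes))

    def _tau(self, abar, dt):
        anorm = np.linalg.norm(abar, axis=1)
        terms = (2.0 / dt) ** 2 + (2.0 * anorm / self.fd.h) ** 2
        if self.config.diffusivity > 0:
            terms = terms + (12.0 * self.config.diffusivity / self.fd.h ** 2) ** 2
        return 1.0 / np.sqrt(terms)

    def check_cfl(self, velocity: np.ndarray, dt: float):
        fd = self.fd
        abar = velocity[fd.cells].mean(axis=1)
        cfl = float((np.linalg.norm(abar, axis=1) * dt / fd.h).max())
        if cfl > self.config.cfl_warn:
            warnings.warn(
                f"advective CFL {cfl:.1f} exceeds {self.config.cfl_warn}; "
                f"consider dt <= {dt * self.config.cfl_warn / cfl:.2e} s "
                f"for accuracy", stacklevel=2)
        return cfl

    def _lumped_mass(self) -> np.ndarray:
        fd = self.fd
        nl = fd.dim + 1
        w = np.zeros(fd.n_nodes)
        np.add.at(w, self.conn.ravel(),
                  np.repeat(fd.vol / nl, nl))
        return w

    def system(self, velocity: np.ndarray, dt: float):
        """CSR matrix (Dirichlet rows as identity) for an advective field,
        plus the data needed for right-hand sides.

        Default scheme: Galerkin advection rendered monotone by edge-based
        artificial diffusion (the algebraic low-order operator: for every
        node pair, d_ij = max(0, k_ij, k_ji) is subtracted off-diagonal and
        lumped onto the diagonal) with a lumped mass matrix.  This preserves
        the discrete maximum principle, so phi stays within [0, t] and the
        relative residence time within [0, 1].  The optional SUPG scheme is
        the consistent streamline-upwind alternative (sharper fronts, but no
        boundedness guarantee in recirculating flow).
        """
        fd, cfg = self.fd, self.config
        nl = fd.dim + 1
        V, g = fd.vol, fd.grads
        abar = velocity[fd.cells].mean(axis=1)
        tau = self._tau(abar, dt)
        adv = np.einsum("mk,mak->ma", abar, g)
        Vc = V[:, None, None]
        n = fd.n_nodes

        if cfg.stabilization == "upwind":
            m = fd.n_cells
            kel = np.broadcast_to((Vc / nl) * adv[:, None, :],
                                  (m, nl, nl)).copy()    # Galerkin advection
            if cfg.diffusivity > 0:
                kel = kel + cfg.diffusivity * Vc * self.gg
            K = sp.coo_matrix(
                (kel.ravel(), (self.rows.ravel(), self.cols.ravel())),
                shape=(n, n)).tocsr()
            S = K.maximum(K.T).maximum(0.0).tocsr()      # d_ij, symmetric
            S.setdiag(0.0)
            S.eliminate_zeros()
            L = K - S + sp.diags(np.asarray(S.sum(axis=1)).ravel())
            ml = self._lumped_mass()
            A = sp.diags(ml / dt) + L
            A = A.tolil()
            pin = np.concatenate([self.dirichlet, self.orphans])
            A[pin, :] = 0.0
            A[pin, pin] = 1.0
            return A.tocsr(), ("upwind", ml)

        A = (1.0 / dt) * Vc * self.mloc[None, :, :]
        A = A + (Vc / nl) * adv[:, None, :]
        if cfg.diffusivity > 0:
            A = A + cfg.diffusivity * Vc * self.gg
        A = A + tau[:, None, None] * Vc * adv[:, :, None] * adv[:, None, :]
        A = A + (tau[:, None, None] * Vc / (nl * dt)) \
            * np.broadcast_to(adv[:, :, None], A.shape)

        rows, cols, vals = self.rows.ravel(), self.cols.ravel(), A.ravel()
        mask = np.zeros(n, dtype=bool)
        mask[self.dirichlet] = True
        keep = ~mask[rows]
        pin = np.concatenate([self.dirichlet, self.orphans])
        rows = np.concatenate([rows[keep], pin])
        cols = np.concatenate([cols[keep], pin])
        vals = np.concatenate([vals[keep], np.ones(len(pin))])
        mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        return mat, ("supg", (abar, tau, adv))

    def rhs(self, phi_old: np.ndarray, dt: float, elem_data) -> np.ndarray:
        fd, cfg = self.fd, self.config
        kind, data = elem_data
        if kind == "upwind":
            ml = data
            b = ml / dt * phi_old + ml            # lumped source: 1 s per s
            b[self.dirichlet] = 0.0
            b[self.orphans] = 0.0
            return b
        nl = fd.dim + 1
        V = fd.vol
        abar, tau, adv = data
        pold = phi_old[self.conn]                       # (m, nl)
        pbar = pold.mean(axis=1)
        bel = (1.0 / dt) * V[:, None] * np.einsum("ab,mb->ma", self.mloc, pold)
        bel = bel + V[:, None] / nl                      # unit source
        bel = bel + tau[:, None] * V[:, None] * adv \
            * (pbar[:, None] / dt + 1.0)
        b = np.zeros(fd.n_nodes)
        np.add.at(b, self.conn.ravel(), bel.ravel())
        b[self.dirichlet] = 0.0
        b[self.orphans] = 0.0
        return b

    def step(self, phi: np.ndarray, velocity: np.ndarray, dt: float
             ) -> np.ndarray:
        A, elem = self.system(velocity, dt)
        b = self.rhs(phi, dt, elem)
        out = spla.spsolve(A, b)
        if not np.all(np.isfinite(out)):
            raise RuntimeError("residence-time solve produced non-finite values")
        out[self.orphans] = out[self.master[self.orphans]]
        return out


def step_rt(phi: np.ndarray, velocity: np.ndarray, dt: float,
            mesh: TaggedMesh, config: RTConfig = None) -> np.ndarray:
    """One stabilized advection(-diffusion) step with the unit source."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    config = config or RTConfig()
    prob = RTProblem(mesh, config)
    prob.check_cfl(velocity, dt)
    return prob.step(np.asarray(phi, dtype=float), velocity, dt)


class CycleVelocityReplay:
    """Periodic linear-in-time interpolation of stored cycle snapshots."""

    def __init__(self, snap_times: np.ndarray, snap_v: np.ndarray,
                 period: float, tol: float):
        if len(snap_times) < 2:
            raise ParameterError("need at least two velocity snapshots")
        self.phases = np.asarray(snap_times) - snap_times[0]
        self.v = np.asarray(snap_v)
        self.period = period
        vmax = max(float(np.linalg.norm(self.v[0])), 1e-30)
        scale = max(float(np.max([np.linalg.norm(s) for s in self.v])), 1e-30)
        if abs(self.phases[-1] - period) < 1e-9 * period:
            mismatch = float(np.linalg.norm(self.v[-1] - self.v[0])) / scale
            if mismatch > tol:
                raise RTPeriodicityError(
                    f"first/last snapshot mismatch {mismatch:.3f} exceeds "
                    f"tolerance {tol}; the flow record is not periodic")

    def at(self, t: float) -> np.ndarray:
        q = float(np.mod(t, self.period))
        ph = self.phases
        if q <= ph[0]:
            return self.v[0]
        j = int(np.searchsorted(ph, q))
        if j >= len(ph):           # wrap segment: last -> first (+period)
            t0, t1 = ph[-1], self.period
            if t1 - t0 < 1e-12:
                return self.v[-1]
            w = (q - t0) / (t1 - t0)
            return (1 - w) * self.v[-1] + w * self.v[0]
        t0, t1 = ph[j - 1], ph[j]
        w = (q - t0) / (t1 - t0)
        return (1 - w) * self.v[j - 1] + w * self.v[j]


def run_rt(flow_history, mesh: TaggedMesh, config: RTConfig = None,
           progress: bool = False):
    """Advect the residence-time field through ``rt_cycles`` replays of the
    stored flow cycle.

    Returns (RTField, report) where the report is a per-cycle DataFrame with
    the volume-weighted mean residence time, its relative change, and the
    convergence flag (change below the threshold over the final cycle pair).
    """
    config = config or RTConfig()
    prob = RTProblem(mesh, config)
    fd = mesh.fem()
    period = flow_history.period
    replay = CycleVelocityReplay(flow_history.snap_times, flow_history.snap_v,
                                 period, config.periodicity_tol)

    dt = flow_history.dt * config.rt_dt_factor
    steps_per_cycle = max(2, int(round(period / dt)))
    dt = period / steps_per_cycle
    prob.check_cfl(replay.at(0.25 * period), dt)

    wvol = fd.lumped_node_volumes()
    wsum = wvol.sum()
    phi = np.zeros(fd.n_nodes)

    # cache one factorization per phase index; the advective field repeats
    lus = {}
    elems = {}
    mean_rt = []
    for cyc in range(config.rt_cycles):
        for k in range(steps_per_cycle):
            t_mid = (k + 0.5) * dt          # velocity sampled mid-step
            if k not in lus:
                A, elem = prob.system(replay.at(t_mid), dt)
                lus[k] = spla.splu(A.tocsc())
                elems[k] = elem
            b = prob.rhs(phi, dt, elems[k])
            phi = lus[k].solve(b)
            phi[prob.orphans] = phi[prob.master[prob.orphans]]
        mean_rt.append(float(np.dot(wvol, phi) / wsum))
        if progress:
            print(f"  RT cycle {cyc + 1}/{config.rt_cycles}: "
                  f"mean RT {mean_rt[-1]:.4f} s")

    mean_rt = np.asarray(mean_rt)
    change = np.full(len(mean_rt), np.nan)
    change[1:] = np.abs(np.diff(mean_rt)) / np.maximum(mean_rt[:-1], 1e-30)
    converged = bool(change[-1] < config.convergence_threshold)
    first = np.flatnonzero(change[1:] < config.convergence_threshold)
    report = pd.DataFrame({
        "cycle": np.arange(1, len(mean_rt) + 1),
        "mean_rt": mean_rt,
        "rel_change": change,
    })
    report.attrs["converged"] = converged
    report.attrs["first_converged_cycle"] = int(first[0] + 2) if len(first) else None
    total_time = config.rt_cycles * period
    return RTField(phi, total_time), report
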