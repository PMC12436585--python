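"""Parametric idealized aortic-root geometry and mesh synthesis.

Patient CT anatomies are replaced by a parametric body of revolution: an LVOT
tube, a sinus bulge region (the three sinuses collapsed to an axisymmetric
bulge), a sinotubular junction and an ascending aorta, with two coronary ostia
on the sinus wall.  Meshes are generated as mapped structured grids (triangles
in the planar 2-D mode, Kuhn-split tetrahedra in the revolved 3-D mode) so
that the valve plane, the orifice rim and the downstream measurement plane
fall exactly on mesh layers.  The TAVR-in-SAVR variant inserts a funnel whose
throat is the reduced geometric orifice; the skirt volume between the funnel
and the LVOT wall below the surgical ring is excluded from the fluid domain,
and the pocket between the funnel and the sinus wall above the ring forms the
neo-sinus.

All lengths are in mm.  The axial coordinate is the last one (z), with the
inflow (LVOT) plane at z = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, replace
from enum import Enum, IntEnum

import numpy as np

from .fem import FemData, facet_census


class ParameterError(ValueError):
    """Invalid or infeasible geometry/scenario parameters."""


class MeshingError(RuntimeError):
    """Mesh generation failed; message echoes the offending parameters."""


class FacetTag(IntEnum):
    INLET = 1
    OUTLET = 2
    WALL = 3
    CORONARY_L = 4
    CORONARY_R = 5
    VALVE_ORIFICE = 6
    VALVE_ANNULUS = 7


TAG_TABLE = {int(t): t.name for t in FacetTag}


class Scenario(str, Enum):
    BASELINE = "baseline"
    YAAE = "yaae"
    TAVR_IN_SAVR = "tavr_in_savr"


class FixtureKind(str, Enum):
    PIPE = "pipe"
    CHANNEL = "channel"
    CAVITY = "cavity"


@dataclass(frozen=True)
class FunnelInsert:
    """Idealized transcatheter valve frame deployed inside the surgical valve.

    The funnel converges from ``inlet_diameter`` at its bottom rim (sealed
    against the LVOT wall ``axial_offset`` mm below the surgical valve plane)
    to ``throat_diameter`` (the post-TAVR geometric orifice) at the top of
    the skirt.
    """

    inlet_diameter: float
    throat_diameter: float
    axial_offset: float = 4.0
    skirt_height: float = 13.0

    def __post_init__(self):
        if min(self.inlet_diameter, self.throat_diameter,
               self.axial_offset, self.skirt_height) <= 0:
            raise ParameterError(f"funnel dimensions must be positive: {self}")
        if self.throat_diameter >= self.inlet_diameter:
            raise ParameterError(
                f"funnel throat ({self.throat_diameter} mm) must be smaller "
                f"than its inlet ({self.inlet_diameter} mm)")


@dataclass(frozen=True)
class RootParameters:
    """Dimensions of the idealized aortic root (all mm).

    ``sinus_bulge_radius`` is the maximal radius of the sinus bulge;
    ``goa_diameter`` is the geometric orifice of the implanted valve
    (defaults to the annulus diameter minus the 6 mm internal-diameter
    offset when unset).  ``enlargement_factor`` scales the annulus and sinus
    radii (annular enlargement); the sinotubular junction and the ascending
    aorta are left unchanged.  ``coronary_positions`` are (angle deg,
    fraction of sinus height) placements of the two ostia; in 2-D mode the
    first maps to the left wall and the second to the right.
    """

    annulus_diameter: float = 23.0
    sinus_bulge_radius: float = 16.5
    sinus_height: float = 22.0
    stj_diameter: float = 27.0
    aorta_diameter: float = 30.0
    lvot_length: float = 20.0
    aorta_length: float = 48.0
    coronary_diameter: float = 3.0
    coronary_positions: tuple = ((90.0, 0.6), (270.0, 0.6))
    enlargement_factor: float = 1.0
    goa_diameter: float | None = None
    tavr_insert: FunnelInsert | None = None

    def __post_init__(self):
        lengths = dict(
            annulus_diameter=self.annulus_diameter,
            sinus_bulge_radius=self.sinus_bulge_radius,
            sinus_height=self.sinus_height,
            stj_diameter=self.stj_diameter,
            aorta_diameter=self.aorta_diameter,
            lvot_length=self.lvot_length,
            aorta_length=self.aorta_length,
            coronary_diameter=self.coronary_diameter,
        )
        for name, val in lengths.items():
            if val <= 0:
                raise ParameterError(f"{name} must be > 0, got {val}")
        if not (1.0 <= self.enlargement_factor <= 2.0):
            raise ParameterError(
                f"enlargement_factor must be in [1, 2], "
                f"got {self.enlargement_factor}")
        if self.stj_diameter > 2.0 * self.sinus_bulge_radius * self.enlargement_factor:
            raise ParameterError(
                "sinotubular junction wider than the maximal sinus bulge")
        if self.aorta_length < 30.0:
            raise ParameterError(
                "aorta_length must be at least 30 mm so the downstream "
                "pressure-gradient plane exists")
        if self.goa_diameter is not None:
            if not (0.0 < self.goa_diameter < self.effective_annulus_diameter):
                raise ParameterError(
                    f"geometric orifice ({self.goa_diameter} mm) must be "
                    f"positive and smaller than the (enlarged) annulus "
                    f"({self.effective_annulus_diameter} mm)")
        if self.tavr_insert is not None:
            goa = self.resolved_goa_diameter
            if self.tavr_insert.inlet_diameter > goa + 1e-9:
                raise ParameterError(
                    "funnel inlet wider than the surgical orifice it passes "
                    f"through ({self.tavr_insert.inlet_diameter} > {goa} mm)")
            if self.tavr_insert.axial_offset >= self.lvot_length:
                raise ParameterError("funnel bottom lies below the inflow plane")

    @property
    def effective_annulus_diameter(self) -> float:
        return self.annulus_diameter * self.enlargement_factor

    @property
    def resolved_goa_diameter(self) -> float:
        if self.goa_diameter is not None:
            return self.goa_diameter
        return self.effective_annulus_diameter - 6.0

    @property
    def total_length(self) -> float:
        return self.lvot_length + self.sinus_height + self.aorta_length

    @property
    def valve_plane_z(self) -> float:
        return self.lvot_length

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coronary_positions"] = [list(p) for p in self.coronary_positions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RootParameters":
        d = dict(d)
        if d.get("tavr_insert") is not None and not isinstance(
                d["tavr_insert"], FunnelInsert):
            d["tavr_insert"] = FunnelInsert(**d["tavr_insert"])
        if "coronary_positions" in d:
            d["coronary_positions"] = tuple(
                tuple(p) for p in d["coronary_positions"])
        return cls(**d)


class RootProfile:
    """Axial lumen-radius profile r(z) and the internal separator path.

    The separator x_s(z) is the radial coordinate at which the structured
    grid places a node column/ring; it follows the orifice rim fraction
    without an insert, and the funnel wall across the insert's axial span.
    """

    def __init__(self, params: RootParameters):
        p = params
        self.params = p
        ef = p.enlargement_factor
        self.r_ann = 0.5 * p.annulus_diameter * ef
        self.r_bulge = p.sinus_bulge_radius * ef
        self.r_stj = 0.5 * p.stj_diameter
        self.r_aorta = 0.5 * p.aorta_diameter
        self.z_valve = p.lvot_length
        self.z_sinus_end = p.lvot_length + p.sinus_height
        self.trans_len = min(10.0, p.aorta_length / 3.0)
        self.z_trans_end = self.z_sinus_end + self.trans_len
        self.length = p.total_length
        self.bulge_amp = self.r_bulge - 0.5 * (self.r_ann + self.r_stj)
        if self.bulge_amp < 0:
            raise ParameterError(
                "sinus bulge radius smaller than the annulus/STJ average")
        goa = p.resolved_goa_diameter
        self.orifice_radius = 0.5 * goa
        ins = p.tavr_insert
        if ins is not None:
            self.z_funnel_bot = self.z_valve - ins.axial_offset
            self.z_funnel_top = self.z_funnel_bot + ins.skirt_height
            self.throat_radius = 0.5 * ins.throat_diameter
            self.funnel_inlet_radius = 0.5 * ins.inlet_diameter
            if self.z_funnel_top >= self.z_sinus_end:
                raise ParameterError("funnel extends past the sinotubular junction")
        else:
            self.z_funnel_bot = self.z_funnel_top = None
            self.throat_radius = self.orifice_radius
            self.funnel_inlet_radius = None
        self.z_meas = self.z_valve + 30.0

    def radius(self, z):
        z = np.asarray(z, dtype=float)
        r = np.empty_like(z)
        # LVOT tube
        m = z <= self.z_valve
        r[m] = self.r_ann
        # sinus bulge: linear blend annulus->STJ plus sine bump
        m = (z > self.z_valve) & (z <= self.z_sinus_end)
        zeta = (z[m] - self.z_valve) / self.params.sinus_height
        base = self.r_ann + (self.r_stj - self.r_ann) * zeta
        r[m] = base + self.bulge_amp * np.sin(np.pi * zeta)
        # STJ -> aorta cosine transition
        m = (z > self.z_sinus_end) & (z <= self.z_trans_end)
        s = (z[m] - self.z_sinus_end) / self.trans_len
        r[m] = self.r_stj + (self.r_aorta - self.r_stj) * 0.5 * (1 - np.cos(np.pi * s))
        # ascending aorta
        m = z > self.z_trans_end
        r[m] = self.r_aorta
        return r

    def funnel_radius(self, z):
        """Funnel wall radius across the insert's axial span."""
        ins = self.params.tavr_insert
        s = (np.asarray(z, dtype=float) - self.z_funnel_bot) / ins.skirt_height
        return self.funnel_inlet_radius + (
            self.throat_radius - self.funnel_inlet_radius) * np.clip(s, 0.0, 1.0)

    def separator(self, z):
        z = np.asarray(z, dtype=float)
        r = self.radius(z)
        if self.params.tavr_insert is None:
            frac = self.orifice_radius / self.r_ann
            return frac * r
        xs = np.empty_like(z)
        m_lo = z <= self.z_funnel_bot
        xs[m_lo] = self.funnel_inlet_radius * r[m_lo] / self.radius(self.z_funnel_bot)
        m_f = (z > self.z_funnel_bot) & (z < self.z_funnel_top)
        xs[m_f] = self.funnel_radius(z[m_f])
        m_hi = z >= self.z_funnel_top
        xs[m_hi] = self.throat_radius * r[m_hi] / self.radius(self.z_funnel_top)
        return xs

    def breakpoints(self):
        pts = {0.0, self.z_valve, self.z_sinus_end, self.z_trans_end,
               self.length, self.z_meas}
        if self.params.tavr_insert is not None:
            pts.update({self.z_funnel_bot, self.z_funnel_top})
        return np.array(sorted(pts))

    def section_area(self, z, mode: str):
        """Fluid cross-section area (3-D) or width (2-D planar) at z."""
        z = np.asarray(z, dtype=float)
        r = self.radius(z)
        area = np.pi * r ** 2 if mode == "3d" else 2.0 * r
        if self.params.tavr_insert is not None:
            # below the surgical ring the skirt pocket is excluded
            m = (z > self.z_funnel_bot) & (z < self.z_valve)
            xf = self.funnel_radius(z[m])
            area[m] = np.pi * xf ** 2 if mode == "3d" else 2.0 * xf
        return area


def analytic_lumen_volume(params: RootParameters, mode: str = "3d",
                          n: int = 4001) -> float:
    """Volume (3-D, mm^3) or planar area (2-D, mm^2) of the parametric lumen,
    by dense Simpson quadrature of the cross-section profile."""
    from scipy.integrate import simpson
    prof = RootProfile(params)
    z = np.linspace(0.0, prof.length, n)
    return float(simpson(prof.section_area(z, mode), x=z))


@dataclass
class TaggedMesh:
    """Unstructured simplicial mesh with tagged boundary and interior facets.

    ``facets`` holds boundary facets plus tagged interior facets (the valve
    plane and any internal structural walls); ``facet_tags`` are FacetTag
    integers.  ``meta`` records provenance (parameters, seed) and the axial
    stations used downstream (valve plane, measurement plane).
    """

    vertices: np.ndarray
    cells: np.ndarray
    facets: np.ndarray
    facet_tags: np.ndarray
    characteristic_edge_length: float
    meta: dict
    node_pairs: np.ndarray = None   # (k, 2) [below, above] valve-plane twins

    _fem: FemData = None

    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    @property
    def axis(self) -> int:
        return self.dim - 1

    def fem(self) -> FemData:
        if self._fem is None:
            self._fem = FemData(self.vertices, self.cells)
        return self._fem

    @property
    def volume(self) -> float:
        return self.fem().total_volume

    def facets_with_tag(self, *tags) -> np.ndarray:
        want = {int(t) for t in tags}
        mask = np.isin(self.facet_tags, list(want))
        return self.facets[mask]

    def nodes_with_tag(self, *tags) -> np.ndarray:
        f = self.facets_with_tag(*tags)
        return np.unique(f) if len(f) else np.array([], dtype=int)

    def group(self, *tags, orient_axis: int | None = None):
        return self.fem().facet_group(self.facets_with_tag(*tags),
                                      orient_axis=orient_axis)

    def nearest_axial_plane(self, z: float) -> float:
        """Axial coordinate of the mesh layer closest to z."""
        zc = self.vertices[:, self.axis]
        return float(zc[np.argmin(np.abs(zc - z))])

    def plane_facets(self, z: float, tol: float = None) -> np.ndarray:
        """Interior facets lying exactly on the axial plane z (cross-section)."""
        if tol is None:
            tol = 1e-6 * max(1.0, float(np.abs(self.vertices).max()))
        uniq, counts, _, _ = self.fem().census()
        onplane = np.all(
            np.abs(self.vertices[uniq, self.axis] - z) < tol, axis=1)
        return uniq[onplane & (counts == 2)]

    def boundary_census(self):
        """(facets, counts) for every unique facet of the cell complex."""
        uniq, counts, _, _ = self.fem().census()
        return uniq, counts

    def validate(self) -> None:
        """Check watertightness and single-tag coverage of the boundary."""
        uniq, counts = self.boundary_census()
        if counts.max() > 2:
            raise MeshingError("non-manifold facet (shared by >2 cells)")
        boundary = uniq[counts == 1]
        key = lambda arr: set(map(tuple, np.sort(arr, axis=1)))
        tagged = {}
        for f, t in zip(np.sort(self.facets, axis=1), self.facet_tags):
            tf = tuple(f)
            if tf in tagged and tagged[tf] != t:
                raise MeshingError("facet carries more than one tag")
            tagged[tf] = t
        missing = key(boundary) - set(tagged)
        if missing:
            raise MeshingError(
                f"{len(missing)} boundary facets carry no tag")

    def summary(self) -> dict:
        return {
            "n_vertices": int(self.vertices.shape[0]),
            "n_cells": int(self.cells.shape[0]),
            "dim": self.dim,
            "volume": self.volume,
            "edge_length": self.characteristic_edge_length,
            "tags": {TAG_TABLE[int(t)]: int((self.facet_tags == t).sum())
                     for t in np.unique(self.facet_tags)},
        }


# ---------------------------------------------------------------------------
# structured grid helpers
# ---------------------------------------------------------------------------

def _axial_rows(breaks: np.ndarray, edge: float) -> np.ndarray:
    rows = [np.array([breaks[0]])]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(round((b - a) / edge)))
        rows.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(rows)


def _row_positions_2d(r: float, xs: float, n_out: int, n_core: int) -> np.ndarray:
    left = np.linspace(-r, -xs, n_out + 1)
    core = np.linspace(-xs, xs, n_core + 1)
    right = np.linspace(xs, r, n_out + 1)
    return np.concatenate([left, core[1:], right[1:]])


def _grid_triangles(nz: int, nc: int) -> np.ndarray:
    """Alternating-diagonal (union-jack) triangulation of an (nz x nc) quad
    grid: checkerboard diagonal flips give symmetric node stencils, which
    keeps low-order upwind transport exact for linear fields along the grid."""
    i, j = np.meshgrid(np.arange(nz), np.arange(nc), indexing="ij")
    par = ((i + j) % 2 == 0).ravel()
    v00 = (i * (nc + 1) + j).ravel()
    v01 = v00 + 1
    v10 = v00 + (nc + 1)
    v11 = v10 + 1
    t1 = np.where(par[:, None], np.stack([v00, v01, v11], axis=1),
                  np.stack([v00, v01, v10], axis=1))
    t2 = np.where(par[:, None], np.stack([v00, v11, v10], axis=1),
                  np.stack([v01, v11, v10], axis=1))
    return np.concatenate([t1, t2], axis=0)


def _build_layered_2d(zrows, radius_fn, sep_fn, n_out, n_core):
    nzr = len(zrows)
    nc = 2 * n_out + n_core
    verts = np.empty((nzr * (nc + 1), 2))
    for i, z in enumerate(zrows):
        x = _row_positions_2d(float(radius_fn(z)), float(sep_fn(z)),
                              n_out, n_core)
        verts[i * (nc + 1):(i + 1) * (nc + 1), 0] = x
        verts[i * (nc + 1):(i + 1) * (nc + 1), 1] = z
    cells = _grid_triangles(nzr - 1, nc)
    return verts, cells, nc


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _build_revolved_3d(zrows, radius_fn, sep_fn, n_out, n_core, n_theta):
    """Revolve the profile into tetrahedra: centre spine + rings per layer.

    Ring ``n_core`` sits on the separator path; rings are uniform inside and
    outside it.  Hexahedral blocks are split with the Kuhn template (all
    face diagonals low-to-high corner), wedges at the axis with a matching
    3-tet split, which yields a globally consistent tetrahedralization.
    """
    nzr = len(zrows)
    nr = n_core + n_out
    npr = 1 + nr * n_theta
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    ct, st = np.cos(theta), np.sin(theta)

    verts = np.empty((nzr * npr, 3))
    for i, z in enumerate(zrows):
        r = float(radius_fn(z))
        xs = float(sep_fn(z))
        radii = np.concatenate([
            np.linspace(0.0, xs, n_core + 1)[1:],
            np.linspace(xs, r, n_out + 1)[1:],
        ])
        base = i * npr
        verts[base, :] = (0.0, 0.0, z)
        ring = base + 1 + np.arange(nr * n_theta)
        rr = np.repeat(radii, n_theta)
        verts[ring, 0] = rr * np.tile(ct, nr)
        verts[ring, 1] = rr * np.tile(st, nr)
        verts[ring, 2] = z

    def nid(i, j, k):
        """Node id at layer i, ring j (0 = centre), angle index k (mod)."""
        i = np.asarray(i)
        j = np.asarray(j)
        k = np.mod(np.asarray(k), n_theta)
        return np.where(j == 0, i * npr, i * npr + 1 + (j - 1) * n_theta + k)

    tets = []
    ii = np.arange(nzr - 1)
    kk = np.arange(n_theta)
    I, K = np.meshgrid(ii, kk, indexing="ij")
    # axis wedges: prism (c,a,b)-(c',a',b') -> 3 tets, diagonals low-to-high
    c, cp = nid(I, 0, 0), nid(I + 1, 0, 0)
    a, b = nid(I, 1, K), nid(I, 1, K + 1)
    ap, bp = nid(I + 1, 1, K), nid(I + 1, 1, K + 1)
    tets.append(np.stack([c, a, b, bp], axis=-1).reshape(-1, 4))
    tets.append(np.stack([c, a, bp, ap], axis=-1).reshape(-1, 4))
    tets.append(np.stack([c, ap, bp, cp], axis=-1).reshape(-1, 4))
    # ring hexes, Kuhn split with main diagonal (i,j,k)->(i+1,j+1,k+1)
    if nr > 1:
        jj = np.arange(1, nr)
        I, J, K = np.meshgrid(ii, jj, kk, indexing="ij")
        corner = {}
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    corner[(di, dj, dk)] = nid(I + di, J + dj, K + dk)
        e = {0: (1, 0, 0), 1: (0, 1, 0), 2: (0, 0, 1)}
        v000 = corner[(0, 0, 0)]
        v111 = corner[(1, 1, 1)]
        for p1, p2, p3 in _KUHN_PERMS:
            c1 = tuple(np.add(e[p1], (0, 0, 0)))
            c2 = tuple(np.add(e[p1], e[p2]))
            tets.append(np.stack(
                [v000, corner[c1], corner[c2], v111], axis=-1).reshape(-1, 4))
    cells = np.concatenate(tets, axis=0)
    return verts, cells, nid


def _compact(vertices, cells, facet_lists, pairs=None):
    """Drop unreferenced vertices and renumber cells/facets/node pairs."""
    used = np.zeros(len(vertices), dtype=bool)
    used[cells.ravel()] = True
    for f, _ in facet_lists:
        if len(f):
            used[np.asarray(f).ravel()] = True
    new_id = -np.ones(len(vertices), dtype=int)
    new_id[used] = np.arange(used.sum())
    vertices = vertices[used]
    cells = new_id[cells]
    facet_lists = [(new_id[np.asarray(f)] if len(f) else np.asarray(f), t)
                   for f, t in facet_lists]
    if pairs is not None and len(pairs):
        keep = used[pairs[:, 0]] & used[pairs[:, 1]]
        pairs = new_id[pairs[keep]]
    return vertices, cells, facet_lists, pairs


def _crack_plane(verts, cells, z_plane, axis, tol):
    """Duplicate the nodes on an axial plane; cells above use the copies.

    Creates a zero-width crack so the orifice-plane valve can seal exactly
    (no element spans the plane, so the stabilization terms cannot pump mass
    across a closed valve, and the transvalvular pressure jump is
    representable).  Returns (verts, cells, pairs[below, above], mapping).
    """
    on = np.abs(verts[:, axis] - z_plane) < tol
    plane_ids = np.flatnonzero(on)
    n = len(verts)
    new_ids = n + np.arange(len(plane_ids))
    mapping = np.arange(n + len(plane_ids))
    mapping[plane_ids] = new_ids
    cmid = verts[cells].mean(axis=1)[:, axis]
    above = cmid > z_plane
    cells = cells.copy()
    cells[above] = mapping[cells[above]]
    verts = np.vstack([verts, verts[plane_ids]])
    pairs = np.stack([plane_ids, new_ids], axis=1)
    return verts, cells, pairs, mapping


# ---------------------------------------------------------------------------
# root mesh builder
# ---------------------------------------------------------------------------

def build_root_mesh(params: RootParameters, edge_length: float,
                    mode: str = "2d", seed: int = 0) -> TaggedMesh:
    """Generate the idealized aortic-root mesh.

    ``mode='2d'`` gives a planar (unit-thickness) symmetric channel whose
    half-width follows the lumen radius profile; ``mode='3d'`` revolves the
    profile into tetrahedra.  The generator is deterministic; ``seed`` is
    recorded in the metadata for provenance only.
    """
    if mode not in ("2d", "3d"):
        raise ParameterError(f"mode must be '2d' or '3d', got {mode!r}")
    if edge_length >= params.annulus_diameter / 4.0:
        raise ParameterError(
            f"edge_length {edge_length} mm too coarse: must be below a "
            f"quarter of the annulus diameter ({params.annulus_diameter} mm)")
    prof = RootProfile(params)
    goa_r = prof.orifice_radius
    r_ann = prof.r_ann
    n_core = max(4, int(round(2.0 * goa_r / edge_length)))
    n_out = max(2, int(round((r_ann - goa_r) / edge_length)))
    zrows = _axial_rows(prof.breakpoints(), edge_length)

    try:
        if mode == "2d":
            mesh = _root_mesh_2d(prof, zrows, n_out, n_core, edge_length)
        else:
            n_theta = max(12, int(round(2.0 * np.pi * r_ann / edge_length)))
            mesh = _root_mesh_3d(prof, zrows, n_out, n_core, n_theta,
                                 edge_length)
    except ParameterError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise MeshingError(
            f"root meshing failed for params={params!r}, "
            f"edge={edge_length}, mode={mode}: {exc}") from exc
    mesh.meta["seed"] = seed
    mesh.meta["params"] = params.to_dict()
    return mesh


def _classify_root_boundary(mesh_verts, bfacets, prof, mode):
    """Assign INLET/OUTLET/WALL/CORONARY tags to boundary facets."""
    axis = mesh_verts.shape[1] - 1
    tol = 1e-6 * prof.length
    zc = mesh_verts[bfacets, axis]
    tags = np.full(len(bfacets), int(FacetTag.WALL))
    tags[np.all(zc < tol, axis=1)] = int(FacetTag.INLET)
    tags[np.all(zc > prof.length - tol, axis=1)] = int(FacetTag.OUTLET)
    # coronary ostia on the sinus wall
    mid = mesh_verts[bfacets].mean(axis=1)
    wall = tags == int(FacetTag.WALL)
    cor_tags = (int(FacetTag.CORONARY_L), int(FacetTag.CORONARY_R))
    for (ang, frac), ct in zip(prof.params.coronary_positions, cor_tags):
        z0 = prof.z_valve + frac * prof.params.sinus_height
        half = 0.5 * prof.params.coronary_diameter * prof.params.enlargement_factor
        if mode == "2d":
            # first ostium -> left wall, second -> right wall
            side = -1.0 if ct == int(FacetTag.CORONARY_L) else 1.0
            sel = wall & (np.abs(mid[:, axis] - z0) < half) \
                & (np.sign(mid[:, 0]) == side)
        else:
            th = np.arctan2(mid[:, 1], mid[:, 0])
            dth = np.angle(np.exp(1j * (th - np.radians(ang))))
            rmid = np.hypot(mid[:, 0], mid[:, 1])
            dist = np.hypot(mid[:, axis] - z0, rmid * dth)
            sel = wall & (dist < half)
        tags[sel] = ct
    return tags


def _finalize_root_mesh(verts, cells, extra_facets, prof, mode, edge_length):
    """Crack the valve plane, classify boundaries, tag the orifice and
    assemble the TaggedMesh (shared by the 2-D and 3-D builders)."""
    axis = verts.shape[1] - 1
    tol = 1e-6 * prof.length
    verts, cells, pairs, mapping = _crack_plane(verts, cells, prof.z_valve,
                                               axis, tol)
    facet_lists = [(mapping[f] if above else f, t)
                   for f, t, above in extra_facets]

    uniq, counts, _, _ = facet_census(cells, verts.shape[1])
    bfacets = uniq[counts == 1]
    # valve plane: boundary facets (both crack sides) with all nodes at z_v
    onplane = np.all(np.abs(verts[bfacets, axis] - prof.z_valve) < tol, axis=1)
    plane, lateral = bfacets[onplane], bfacets[~onplane]
    xs_v = float(prof.separator(prof.z_valve))
    lat = verts[plane][:, :, :-1]
    rad = np.linalg.norm(lat, axis=2) if verts.shape[1] == 3 \
        else np.abs(lat[:, :, 0])
    inside = np.all(rad <= xs_v + tol, axis=1)
    facet_lists.append((plane[inside], int(FacetTag.VALVE_ORIFICE)))
    facet_lists.append((plane[~inside], int(FacetTag.VALVE_ANNULUS)))

    btags = _classify_root_boundary(verts, lateral, prof, mode)
    for t in np.unique(btags):
        facet_lists.append((lateral[btags == t], int(t)))

    verts, cells, facet_lists, pairs = _compact(verts, cells, facet_lists,
                                                pairs)
    facets = np.concatenate([f for f, _ in facet_lists if len(f)])
    tags = np.concatenate([np.full(len(f), t)
                           for f, t in facet_lists if len(f)])
    meta = _root_meta(prof, mode, edge_length)
    return TaggedMesh(verts, cells, facets, tags, edge_length, meta,
                      node_pairs=pairs)


def _root_mesh_2d(prof, zrows, n_out, n_core, edge_length):
    params = prof.params
    verts, cells, nc = _build_layered_2d(
        zrows, prof.radius, prof.separator, n_out, n_core)
    tol = 1e-6 * prof.length
    j_sep_lo, j_sep_hi = n_out, n_out + n_core
    i_valve = int(np.argmin(np.abs(zrows - prof.z_valve)))

    extra_facets = []   # (facets, tag, above_plane)
    if params.tavr_insert is not None:
        i_top = int(np.argmin(np.abs(zrows - prof.z_funnel_top)))
        # remove skirt-pocket cells (between funnel and LVOT wall, below ring)
        cmid = verts[cells].mean(axis=1)
        zmid = cmid[:, 1]
        band = (zmid > prof.z_funnel_bot + tol) & (zmid < prof.z_valve - tol)
        pocket = band & (np.abs(cmid[:, 0]) > prof.separator(zmid) + tol)
        cells = cells[~pocket]
        # funnel wall above the ring (neo-sinus side) is an interior wall
        nid = lambda i, j: i * (nc + 1) + j
        wall_edges = [(nid(i, j), nid(i + 1, j))
                      for j in (j_sep_lo, j_sep_hi)
                      for i in range(i_valve, i_top)]
        extra_facets.append((np.array(wall_edges, dtype=int),
                             int(FacetTag.WALL), True))
    return _finalize_root_mesh(verts, cells, extra_facets, prof, "2d",
                               edge_length)


def _root_mesh_3d(prof, zrows, n_out, n_core, n_theta, edge_length):
    params = prof.params
    # radial counts: n_core rings inside the separator, n_out outside
    n_core_r = max(2, int(round(n_core / 2)))
    verts, cells, nid = _build_revolved_3d(
        zrows, prof.radius, prof.separator, n_out, n_core_r, n_theta)
    tol = 1e-6 * prof.length
    i_valve = int(np.argmin(np.abs(zrows - prof.z_valve)))
    extra_facets = []
    if params.tavr_insert is not None:
        i_top = int(np.argmin(np.abs(zrows - prof.z_funnel_top)))
        cmid = verts[cells].mean(axis=1)
        zmid = cmid[:, 2]
        rmid = np.hypot(cmid[:, 0], cmid[:, 1])
        band = (zmid > prof.z_funnel_bot + tol) & (zmid < prof.z_valve - tol)
        pocket = band & (rmid > prof.separator(zmid) + tol)
        cells = cells[~pocket]
        # funnel wall above the ring: ring-j_sep surface triangles
        tris = []
        for i in range(i_valve, i_top):
            for k in range(n_theta):
                a = nid(i, n_core_r, k); b = nid(i, n_core_r, k + 1)
                ap = nid(i + 1, n_core_r, k); bp = nid(i + 1, n_core_r, k + 1)
                tris.append((a, b, bp)); tris.append((a, bp, ap))
        extra_facets.append((np.array(tris, dtype=int),
                             int(FacetTag.WALL), True))
    return _finalize_root_mesh(verts, cells, extra_facets, prof, "3d",
                               edge_length)


def _root_meta(prof, mode, edge_length):
    return {
        "kind": "root",
        "mode": mode,
        "z_valve": prof.z_valve,
        "z_meas": prof.z_meas,
        "orifice_radius": float(prof.separator(prof.z_valve)),
        "throat_radius": prof.throat_radius,
        "goa_diameter": prof.params.resolved_goa_diameter,
        "length": prof.length,
        "edge_length": edge_length,
        "has_insert": prof.params.tavr_insert is not None,
    }


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def apply_scenario(params: RootParameters, scenario: Scenario, valve,
                   goa_reduction: float = 0.20) -> RootParameters:
    """Specialize baseline root parameters to a surgical scenario.

    BASELINE keeps the geometry and records the valve's orifice.  YAAE scales
    the annulus/sinuses by the ratio of the implanted to the native valve
    diameter.  TAVR_IN_SAVR attaches a funnel insert whose throat reduces
    the geometric orifice area by ``goa_reduction`` (default 20%).
    ``valve`` is a ``cardiac_bcs.ValveSpec``.
    """
    scenario = Scenario(scenario)
    if scenario is Scenario.BASELINE:
        if valve.implanted_internal_diameter > params.annulus_diameter + 1e-9:
            raise ParameterError(
                "baseline scenario with a valve larger than the native annulus")
        return replace(params, goa_diameter=valve.goa_diameter)
    if scenario is Scenario.YAAE:
        ratio = valve.implanted_internal_diameter / params.annulus_diameter
        if ratio < 1.0:
            raise ParameterError(
                "YAAE scenario requires a valve at least as large as the "
                "native annulus")
        ef = params.enlargement_factor
        if ef > 1.0 and ef < ratio - 1e-9:
            warnings.warn(
                f"enlargement_factor {ef:.3f} below the valve-size ratio "
                f"{ratio:.3f}; using the ratio", stacklevel=2)
        return replace(params, enlargement_factor=max(ef, ratio),
                       goa_diameter=valve.goa_diameter)
    # TAVR-in-SAVR: funnel throat set so the orifice AREA drops by goa_reduction
    if not (0.0 < goa_reduction < 1.0):
        raise ParameterError(f"goa_reduction must be in (0,1), got {goa_reduction}")
    if valve.implanted_internal_diameter > params.annulus_diameter + 1e-9:
        # a valve above the native annulus implies an enlarged (Y-AAE) root
        params = apply_scenario(params, Scenario.YAAE, valve)
    goa = valve.goa_diameter
    throat = goa * math.sqrt(1.0 - goa_reduction)
    insert = FunnelInsert(inlet_diameter=goa, throat_diameter=throat)
    return replace(params, goa_diameter=goa, tavr_insert=insert)


# ---------------------------------------------------------------------------
# verification fixtures
# ---------------------------------------------------------------------------

def build_fixture_mesh(kind, dims, edge_length: float,
                       seed: int = 0) -> TaggedMesh:
    """Small analytic meshes for verification.

    PIPE: straight 3-D cylinder, dims=(radius, length);
    CHANNEL: 2-D rectangle, dims=(length, width), flow along z;
    CAVITY: closed 2-D box, dims=(width, height), all walls.
    """
    kind = FixtureKind(kind if isinstance(kind, FixtureKind) else str(kind).lower())
    dims = tuple(float(d) for d in dims)
    if any(d <= 0 for d in dims) or edge_length <= 0:
        raise ParameterError(f"fixture dims/edge must be positive: {dims}, "
                             f"{edge_length}")
    if kind is FixtureKind.PIPE:
        radius, length = dims
        nz = max(2, int(round(length / edge_length)))
        zrows = np.linspace(0.0, length, nz + 1)
        n_half = max(1, int(round(0.5 * radius / edge_length)))
        n_theta = max(8, int(round(2.0 * np.pi * radius / edge_length)))
        verts, cells, _ = _build_revolved_3d(
            zrows, lambda z: radius, lambda z: 0.5 * radius,
            n_half, n_half, n_theta)
        meta = {"kind": "pipe", "mode": "3d", "radius": radius,
                "length": length}
    elif kind is FixtureKind.CHANNEL:
        length, width = dims
        zrows = np.linspace(0.0, length,
                            max(2, int(round(length / edge_length))) + 1)
        n_half = max(1, int(round(0.25 * width / edge_length)))
        verts, cells, _ = _build_layered_2d(
            zrows, lambda z: 0.5 * width, lambda z: 0.25 * width,
            n_half, 2 * n_half)
        meta = {"kind": "channel", "mode": "2d", "length": length,
                "width": width}
    else:
        width, height = dims
        zrows = np.linspace(0.0, height,
                            max(2, int(round(height / edge_length))) + 1)
        n_half = max(1, int(round(0.25 * width / edge_length)))
        verts, cells, _ = _build_layered_2d(
            zrows, lambda z: 0.5 * width, lambda z: 0.25 * width,
            n_half, 2 * n_half)
        meta = {"kind": "cavity", "mode": "2d", "width": width,
                "height": height}

    dim = verts.shape[1]
    uniq, counts, _, _ = facet_census(cells, dim)
    bfacets = uniq[counts == 1]
    length_ax = zrows[-1]
    tol = 1e-6 * max(1.0, length_ax)
    zc = verts[bfacets, dim - 1]
    tags = np.full(len(bfacets), int(FacetTag.WALL))
    if kind is not FixtureKind.CAVITY:
        tags[np.all(zc < tol, axis=1)] = int(FacetTag.INLET)
        tags[np.all(zc > length_ax - tol, axis=1)] = int(FacetTag.OUTLET)
    meta["seed"] = seed
    meta["edge_length"] = edge_length
    meta["length_axial"] = float(length_ax)
    return TaggedMesh(verts, cells, bfacets, tags, edge_length, meta)
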