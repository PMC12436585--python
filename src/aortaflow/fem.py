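"""Linear (P1) simplex finite-element kernels on triangles and tetrahedra.

Everything downstream (the stabilized Navier-Stokes solver, the residence-time
transport solver, plane/flux quadrature in the metrics) is built on the small
set of vectorized primitives in this module:

* per-cell geometry: measures and constant basis-function gradients,
* boundary/interior facet extraction by an adjacency census,
* facet measures, outward normals and P1 flux quadrature,
* COO assembly helpers for element-block matrices.

Units are mm-g-s throughout (pressure in Pa, 1 Pa = 1 g/(mm.s^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

# local faces: face i is opposite local node i
_TRI_FACES = np.array([[1, 2], [0, 2], [0, 1]])
_TET_FACES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


def local_faces(dim: int) -> np.ndarray:
    return _TRI_FACES if dim == 2 else _TET_FACES


def cell_geometry(vertices: np.ndarray, cells: np.ndarray):
    """Measures and P1 basis gradients for each simplex.

    Returns
    -------
    vol : (m,) cell measures (area in 2-D, volume in 3-D)
    grads : (m, d+1, d) gradient of each barycentric basis function
    """
    d = vertices.shape[1]
    x = vertices[cells]                       # (m, d+1, d)
    edges = x[:, 1:, :] - x[:, :1, :]          # (m, d, d)
    det = np.linalg.det(edges)
    vol = np.abs(det) / math.factorial(d)
    if np.any(vol <= 0.0):
        raise ValueError("degenerate cell (zero measure) in mesh")
    inv = np.linalg.inv(edges)                 # (m, d, d)
    grads = np.empty((cells.shape[0], d + 1, d))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return vol, grads


def facet_census(cells: np.ndarray, dim: int):
    """Enumerate unique facets of the mesh with their sharing counts.

    Returns (facets, counts, owner_cell, owner_local) where `facets` holds the
    *sorted* node tuples, and the owner is the first incident cell.
    """
    faces = local_faces(dim)
    m = cells.shape[0]
    all_facets = cells[:, faces]                       # (m, d+1, d)
    all_facets = all_facets.reshape(m * (dim + 1), dim)
    owner_cell = np.repeat(np.arange(m), dim + 1)
    owner_local = np.tile(np.arange(dim + 1), m)
    key = np.sort(all_facets, axis=1)
    uniq, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    return uniq, counts, owner_cell[first], owner_local[first]


def facet_measures(vertices: np.ndarray, facets: np.ndarray) -> np.ndarray:
    """Length (2-D) or area (3-D) of each facet."""
    x = vertices[facets]
    if facets.shape[1] == 2:
        return np.linalg.norm(x[:, 1] - x[:, 0], axis=1)
    c = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    return 0.5 * np.linalg.norm(c, axis=1)


def facet_normals(vertices, facets, owner_cell, owner_local, cells, grads):
    """Unit outward normals (w.r.t. the owner cell) of the given facets."""
    g = grads[owner_cell, owner_local, :]        # gradient of the opposite node
    n = -g / np.linalg.norm(g, axis=1)[:, None]
    return n


def facet_flux(v: np.ndarray, facets: np.ndarray, normals: np.ndarray,
               measures: np.ndarray) -> float:
    """∫ v·n over the facet set for a P1 nodal vector field (exact)."""
    if len(facets) == 0:
        return 0.0
    vmean = v[facets].mean(axis=1)               # (f, d)
    return float(np.sum(measures * np.einsum("fi,fi->f", vmean, normals)))


def facet_scalar_integral(s: np.ndarray, facets: np.ndarray,
                          measures: np.ndarray) -> float:
    """∫ s over the facet set for a P1 nodal scalar field (exact)."""
    if len(facets) == 0:
        return 0.0
    return float(np.sum(measures * s[facets].mean(axis=1)))


def element_sizes(vol: np.ndarray, dim: int) -> np.ndarray:
    """Isotropic element length scale h_e = (d! * measure)^(1/d)."""
    return (math.factorial(dim) * vol) ** (1.0 / dim)


def assemble_coo(n_dofs: int, rows, cols, vals) -> sp.csr_matrix:
    """Build a CSR matrix from lists of (m, a, b)-shaped block index/value arrays."""
    r = np.concatenate([x.ravel() for x in rows])
    c = np.concatenate([x.ravel() for x in cols])
    v = np.concatenate([x.ravel() for x in vals])
    return sp.coo_matrix((v, (r, c)), shape=(n_dofs, n_dofs)).tocsr()


def block_indices(dofs_row: np.ndarray, dofs_col: np.ndarray):
    """Expand (m, a) and (m, b) dof arrays to (m, a, b) row/col index grids."""
    rows = np.repeat(dofs_row[:, :, None], dofs_col.shape[1], axis=2)
    cols = np.repeat(dofs_col[:, None, :], dofs_row.shape[1], axis=1)
    return rows, cols


@dataclass
class FacetGroup:
    """A tagged set of facets with precomputed quadrature data."""
    facets: np.ndarray          # (f, d) node indices
    measures: np.ndarray        # (f,)
    normals: np.ndarray         # (f, d) unit, outward for boundary groups
    nodes: np.ndarray = field(default=None)  # unique node indices

    def __post_init__(self):
        if self.nodes is None:
            self.nodes = (np.unique(self.facets) if len(self.facets)
                          else np.array([], dtype=int))

    @property
    def total_measure(self) -> float:
        return float(self.measures.sum())

    def flux(self, v: np.ndarray) -> float:
        return facet_flux(v, self.facets, self.normals, self.measures)

    def average(self, s: np.ndarray) -> float:
        if self.total_measure == 0.0:
            raise ValueError("empty facet group has no average")
        return facet_scalar_integral(s, self.facets, self.measures) / self.total_measure


class FemData:
    """Precomputed geometric data for a simplicial mesh."""

    def __init__(self, vertices: np.ndarray, cells: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.cells = np.asarray(cells, dtype=int)
        self.dim = self.vertices.shape[1]
        self.n_nodes = self.vertices.shape[0]
        self.n_cells = self.cells.shape[0]
        self.vol, self.grads = cell_geometry(self.vertices, self.cells)
        self.h = element_sizes(self.vol, self.dim)
        self.total_volume = float(self.vol.sum())
        self._census = None

    def census(self):
        if self._census is None:
            self._census = facet_census(self.cells, self.dim)
        return self._census

    def facet_group(self, facets: np.ndarray, orient_axis: int | None = None):
        """Build a FacetGroup; normals oriented outward w.r.t. the owner cell,
        or flipped to point along +axis when `orient_axis` is given (for
        interior cross-section planes)."""
        facets = np.asarray(facets, dtype=int).reshape(-1, self.dim)
        if len(facets) == 0:
            return FacetGroup(facets, np.zeros(0), np.zeros((0, self.dim)))
        meas = facet_measures(self.vertices, facets)
        # find an owner cell for each facet via the (cached) census
        uniq, counts, owner_cell, owner_local = self.census()
        key = np.sort(facets, axis=1)
        uniq_v = np.ascontiguousarray(uniq).view([("", uniq.dtype)] * self.dim).ravel()
        key_v = np.ascontiguousarray(key).view([("", key.dtype)] * self.dim).ravel()
        idx = np.searchsorted(uniq_v, key_v)
        if np.any(uniq_v[np.clip(idx, 0, len(uniq_v) - 1)] != key_v):
            raise ValueError("facet not present in mesh")
        normals = facet_normals(self.vertices, facets, owner_cell[idx],
                                owner_local[idx], self.cells, self.grads)
        if orient_axis is not None:
            flip = normals[:, orient_axis] < 0
            normals[flip] *= -1.0
        return FacetGroup(facets, meas, normals)

    def lumped_node_volumes(self) -> np.ndarray:
        w = np.zeros(self.n_nodes)
        np.add.at(w, self.cells.ravel(),
                  np.repeat(self.vol / (self.dim + 1), self.dim + 1))
        return w
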