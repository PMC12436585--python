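"""Mesh and field output: ASCII VTU, Gmsh MSH 4.1 and sidecar metadata.

Writers are intentionally minimal, self-contained ASCII emitters for the two
interchange formats used by the pipeline: VTU (XML unstructured grid, for
fields and ParaView) and Gmsh MSH 4.1 (mesh plus facet tags as physical
groups).  ``read_msh`` parses the same subset it writes, giving a lossless
round trip of vertices, cells, tagged facets and the tag table (persisted in
a sidecar JSON next to the mesh).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import TAG_TABLE, TaggedMesh

_VTK_CELL = {(2, 3): 5, (3, 4): 10}       # triangle, tetra
_MSH_CELL = {2: 1, 3: 2, 4: 4}            # line, triangle, tetra (by n nodes)


def write_vtu(path, mesh: TaggedMesh, point_data: dict | None = None) -> None:
    """ASCII XML VTU with optional nodal fields (scalars or vectors).

    2-D vector fields are padded to three components so ParaView renders
    them as vectors.
    """
    path = Path(path)
    verts = mesh.vertices
    cells = mesh.cells
    n, d = verts.shape
    m, nl = cells.shape
    pts3 = np.zeros((n, 3))
    pts3[:, :d] = verts
    ctype = _VTK_CELL[(d, nl)]

    def arr(a, fmt="%.9g"):
        return "\n".join(" ".join(fmt % x for x in row) for row in a)

    pieces = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        '<Points>',
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(pts3),
        '</DataArray>', '</Points>', '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(cells, "%d"),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str((i + 1) * nl) for i in range(m)),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(ctype) for _ in range(m)),
        '</DataArray>', '</Cells>',
    ]
    if point_data:
        pieces.append('<PointData>')
        for name, data in point_data.items():
            data = np.asarray(data, dtype=float)
            if data.ndim == 1:
                pieces += [
                    f'<DataArray type="Float64" Name="{name}" format="ascii">',
                    " ".join("%.9g" % x for x in data), '</DataArray>']
            else:
                v3 = np.zeros((data.shape[0], 3))
                v3[:, :data.shape[1]] = data
                pieces += [
                    f'<DataArray type="Float64" Name="{name}" '
                    f'NumberOfComponents="3" format="ascii">',
                    arr(v3), '</DataArray>']
        pieces.append('</PointData>')
    pieces += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    path.write_text("\n".join(pieces))


def write_tag_table(path, mesh: TaggedMesh) -> None:
    """Sidecar JSON: tag id <-> name table plus mesh provenance metadata."""
    meta = {k: v for k, v in mesh.meta.items()}
    payload = {"facet_tags": TAG_TABLE, "meta": meta,
               "characteristic_edge_length": mesh.characteristic_edge_length}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def write_msh(path, mesh: TaggedMesh) -> None:
    """Gmsh MSH 4.1 ASCII: cells on one volume entity, facets grouped into
    one surface/curve entity per tag (physical group = FacetTag value)."""
    path = Path(path)
    verts = mesh.vertices
    cells = mesh.cells
    n, d = verts.shape
    coords3 = np.zeros((n, 3))
    coords3[:, :d] = verts
    tags_used = sorted({int(t) for t in mesh.facet_tags})
    fdim = d - 1
    vol_entity = 1
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]

    lines.append("$PhysicalNames")
    lines.append(str(len(tags_used) + 1))
    for t in tags_used:
        lines.append(f'{fdim} {t} "{TAG_TABLE[t]}"')
    lines.append(f'{d} 100 "lumen"')
    lines.append("$EndPhysicalNames")

    lo = coords3.min(axis=0)
    hi = coords3.max(axis=0)
    box = " ".join("%.9g" % x for x in np.concatenate([lo, hi]))
    npt = ncv = nsf = nvl = 0
    if d == 2:
        ncv, nsf = len(tags_used), 1
    else:
        nsf, nvl = len(tags_used), 1
    lines.append("$Entities")
    lines.append(f"{npt} {ncv} {nsf} {nvl}")
    for t in tags_used:                       # facet entities (entity tag = t)
        lines.append(f"{t} {box} 1 {t} 0")
    lines.append(f"{vol_entity} {box} 1 100 0")  # cell entity
    lines.append("$EndEntities")

    lines.append("$Nodes")
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"{d} {vol_entity} 0 {n}")
    lines += [str(i + 1) for i in range(n)]
    lines += [" ".join("%.9g" % x for x in row) for row in coords3]
    lines.append("$EndNodes")

    lines.append("$Elements")
    blocks = []
    eid = 1
    for t in tags_used:
        f = mesh.facets[mesh.facet_tags == t]
        etype = _MSH_CELL[f.shape[1]]
        blk = [f"{fdim} {t} {etype} {len(f)}"]
        for row in f:
            blk.append(f"{eid} " + " ".join(str(x + 1) for x in row))
            eid += 1
        blocks.append(blk)
    etype = _MSH_CELL[cells.shape[1]]
    blk = [f"{d} {vol_entity} {etype} {len(cells)}"]
    for row in cells:
        blk.append(f"{eid} " + " ".join(str(x + 1) for x in row))
        eid += 1
    blocks.append(blk)
    lines.append(f"{len(blocks)} {eid - 1} 1 {eid - 1}")
    for blk in blocks:
        lines += blk
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_msh(path, sidecar=None) -> TaggedMesh:
    """Read a mesh written by ``write_msh`` (MSH 4.1 subset)."""
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def until(tag):
        out = []
        for line in it:
            if line.strip() == tag:
                return out
            out.append(line.strip())
        raise ValueError(f"missing {tag} section")

    def seek(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"missing {tag} section")

    seek("$Nodes")
    body = until("$EndNodes")
    _, n_nodes, _, _ = (int(x) for x in body[0].split())
    dim, _, _, blk_n = (int(x) for x in body[1].split())
    coords = np.array([[float(x) for x in row.split()]
                       for row in body[2 + blk_n: 2 + 2 * blk_n]])
    verts = coords[:, :dim]

    seek("$Elements")
    body = until("$EndElements")
    n_blocks = int(body[0].split()[0])
    pos = 1
    facets, tags, cells = [], [], None
    for _ in range(n_blocks):
        edim, etag, etype, count = (int(x) for x in body[pos].split())
        rows = [np.array([int(x) - 1 for x in body[pos + 1 + i].split()[1:]])
                for i in range(count)]
        pos += 1 + count
        if edim == dim:
            cells = np.array(rows, dtype=int)
        else:
            facets += rows
            tags += [etag] * count
    if cells is None:
        raise ValueError("mesh file contains no volume elements")
    meta = {}
    edge = float(np.nan)
    if sidecar is not None and Path(sidecar).exists():
        payload = json.loads(Path(sidecar).read_text())
        meta = payload.get("meta", {})
        edge = payload.get("characteristic_edge_length", edge)
    return TaggedMesh(verts, cells, np.array(facets, dtype=int),
                      np.array(tags, dtype=int), edge, meta)


def save_mesh(outdir, name, mesh: TaggedMesh) -> dict:
    """Write mesh as MSH + VTU + tag sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "msh": outdir / f"{name}.msh",
        "vtu": outdir / f"{name}.vtu",
        "tags": outdir / f"{name}.tags.json",
    }
    write_msh(paths["msh"], mesh)
    write_vtu(paths["vtu"], mesh)
    write_tag_table(paths["tags"], mesh)
    return paths
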