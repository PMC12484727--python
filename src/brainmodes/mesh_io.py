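"""Read/write labeled tetrahedral meshes as text.

Two formats:

* an Abaqus-``.inp`` dialect — ``*NODE``, ``*ELEMENT, TYPE=C3D4`` with one
  ``ELSET`` per region, ``*NSET`` per named node set, and ``PARCEL_<k>``
  node sets carrying the parcel labels.  1-based ids on disk, 0-based in
  memory.
* VTK legacy unstructured grid — region label as cell data, parcel id as
  point data, node sets as 0/1 point-data masks (``nodeset_<name>``).

Coordinates are printed with 17 significant digits so a round trip is
bit-exact.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .mesh import REGION_LABELS, LabeledMesh, MeshError

__all__ = ["write_mesh", "read_mesh"]

_FORMATS = ("abaqus-inp", "vtk-legacy")


class MeshFileError(MeshError):
    """Malformed mesh file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def write_mesh(mesh: LabeledMesh, path, format: str | None = None) -> None:
    """Write a mesh; format inferred from the suffix when not given."""
    path = Path(path)
    if format is None:
        format = "vtk-legacy" if path.suffix.lower() == ".vtk" else "abaqus-inp"
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if format == "abaqus-inp":
        _write_inp(mesh, path)
    else:
        _write_vtk(mesh, path)


def read_mesh(path) -> LabeledMesh:
    """Read a mesh written by :func:`write_mesh` (format auto-detected)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.lstrip().startswith("# vtk"):
        return _read_vtk(path)
    return _read_inp(path)


# -- Abaqus .inp dialect --------------------------------------------------


def _chunk(ids, per_line=8):
    for i in range(0, len(ids), per_line):
        yield ", ".join(str(v) for v in ids[i:i + per_line])


def _write_inp(mesh: LabeledMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("*HEADING\nbrainmodes labeled tetrahedral mesh\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {x:.17g}, {y:.17g}, {z:.17g}\n")
        fh.write("*ELEMENT, TYPE=C3D4\n")
        for eid, tet in enumerate(mesh.tets, start=1):
            a, b, c, d = (int(v) + 1 for v in tet)
            fh.write(f"{eid}, {a}, {b}, {c}, {d}\n")
        for region in mesh.regions:
            fh.write(f"*ELSET, ELSET={region}\n")
            for line in _chunk(np.flatnonzero(mesh.region_labels == region) + 1):
                fh.write(line + "\n")
        for name in sorted(mesh.node_sets):
            fh.write(f"*NSET, NSET={name}\n")
            for line in _chunk(np.asarray(mesh.node_sets[name]) + 1):
                fh.write(line + "\n")
        parcels = np.unique(mesh.parcel_labels[mesh.parcel_labels >= 0])
        for p in parcels:
            fh.write(f"*NSET, NSET=PARCEL_{p}\n")
            ids = np.flatnonzero(mesh.parcel_labels == p) + 1
            for line in _chunk(ids):
                fh.write(line + "\n")


def _read_inp(path: Path) -> LabeledMesh:
    nodes: list[tuple[float, float, float]] = []
    node_ids: list[int] = []
    tets: list[tuple[int, int, int, int]] = []
    elem_ids: list[int] = []
    elem_elset: list[str | None] = []
    nsets: dict[str, list[int]] = {}
    elsets: dict[str, list[int]] = {}
    section = None
    current_elset = None
    current_nset: list[int] | None = None
    current_elset_list: list[int] | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                kw = line.split(",")[0].strip().upper()
                opts = {
                    k.strip().upper(): v.strip()
                    for k, v in re.findall(r"(\w+)\s*=\s*([^,]+)", line)
                }
                if kw == "*NODE":
                    section = "node"
                elif kw == "*ELEMENT":
                    section = "element"
                    current_elset = opts.get("ELSET")
                elif kw == "*ELSET":
                    section = "elset"
                    name = opts.get("ELSET")
                    if not name:
                        raise MeshFileError(path, lineno, "*ELSET without ELSET=")
                    current_elset_list = elsets.setdefault(name, [])
                elif kw == "*NSET":
                    section = "nset"
                    name = opts.get("NSET")
                    if not name:
                        raise MeshFileError(path, lineno, "*NSET without NSET=")
                    current_nset = nsets.setdefault(name, [])
                else:
                    section = None  # *HEADING body etc.
                continue
            try:
                if section == "node":
                    parts = line.split(",")
                    node_ids.append(int(parts[0]))
                    nodes.append(tuple(float(v) for v in parts[1:4]))
                elif section == "element":
                    parts = [int(v) for v in line.split(",")]
                    if len(parts) != 5:
                        raise ValueError("expected 5 comma-separated ids")
                    elem_ids.append(parts[0])
                    tets.append(tuple(parts[1:5]))
                    elem_elset.append(current_elset)
                elif section == "elset":
                    current_elset_list.extend(
                        int(v) for v in line.split(",") if v.strip())
                elif section == "nset":
                    current_nset.extend(
                        int(v) for v in line.split(",") if v.strip())
            except (ValueError, IndexError) as exc:
                raise MeshFileError(path, lineno, str(exc)) from exc

    if not nodes:
        raise MeshFileError(path, 0, "no *NODE section found")
    order = np.argsort(node_ids)
    id_to_index = {node_ids[i]: rank for rank, i in enumerate(order)}
    coords = np.asarray(nodes)[order]

    def remap(ids):
        try:
            return [id_to_index[i] for i in ids]
        except KeyError as exc:
            raise MeshFileError(path, 0, f"undefined node id {exc}") from exc

    tet_arr = np.array([remap(t) for t in tets], dtype=np.int64).reshape(-1, 4)

    # region labels: from an *ELEMENT ELSET= option or *ELSET blocks
    labels = [lbl if lbl in REGION_LABELS else None for lbl in elem_elset]
    eid_to_pos = {eid: i for i, eid in enumerate(elem_ids)}
    for name, ids in elsets.items():
        if name not in REGION_LABELS:
            continue
        for eid in ids:
            if eid not in eid_to_pos:
                raise MeshFileError(path, 0, f"ELSET {name}: undefined element {eid}")
            labels[eid_to_pos[eid]] = name
    labels = [lbl if lbl is not None else "HOMOG" for lbl in labels]

    parcel = np.full(len(coords), -1, dtype=np.int64)
    node_sets = {}
    for name, ids in nsets.items():
        idx = np.sort(np.asarray(remap(ids), dtype=np.int64))
        m = re.fullmatch(r"PARCEL_(\d+)", name)
        if m:
            parcel[idx] = int(m.group(1))
        else:
            node_sets[name] = idx

    mesh = LabeledMesh(
        nodes=coords, tets=tet_arr,
        region_labels=np.asarray(labels, dtype="U6"),
        node_sets=node_sets, parcel_labels=parcel,
    )
    mesh.validate()
    return mesh


# -- VTK legacy unstructured grid ----------------------------------------


def _write_vtk(mesh: LabeledMesh, path: Path) -> None:
    regions = list(mesh.regions)
    region_code = {r: i for i, r in enumerate(regions)}
    setnames = sorted(mesh.node_sets)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("brainmodes mesh; regions=" + ",".join(regions) + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {5 * m}\n")
        for tet in mesh.tets:
            fh.write("4 " + " ".join(str(int(v)) for v in tet) + "\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["10"] * m) + "\n")
        fh.write(f"CELL_DATA {m}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(region_code[r]) for r in mesh.region_labels))
        fh.write("\n")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("SCALARS parcel int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(p)) for p in mesh.parcel_labels) + "\n")
        for name in setnames:
            mask = np.zeros(mesh.n_nodes, dtype=int)
            mask[np.asarray(mesh.node_sets[name])] = 1
            fh.write(f"SCALARS nodeset_{name} int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(v) for v in mask) + "\n")


def _read_vtk(path: Path) -> LabeledMesh:
    with open(path) as fh:
        lines = fh.read().split("\n")
    it = iter(enumerate(lines, start=1))

    def tokens():
        for lineno, line in it:
            line = line.strip()
            if line:
                yield lineno, line

    tk = tokens()
    _, _header = next(tk)
    _, title = next(tk)
    m = re.search(r"regions=([\w,]+)", title)
    regions = m.group(1).split(",") if m else []
    nodes = tets = region_codes = parcel = None
    nodeset_masks: dict[str, np.ndarray] = {}
    n_points = n_cells = 0

    def read_values(count, cast, lineno):
        vals = []
        while len(vals) < count:
            try:
                ln, line = next(tk)
            except StopIteration:
                raise MeshFileError(path, lineno, "unexpected end of file")
            vals.extend(cast(v) for v in line.split())
        return vals

    for lineno, line in tk:
        up = line.upper()
        if up.startswith("POINTS"):
            n_points = int(line.split()[1])
            vals = read_values(3 * n_points, float, lineno)
            nodes = np.asarray(vals).reshape(n_points, 3)
        elif up.startswith("CELLS"):
            n_cells = int(line.split()[1])
            vals = read_values(5 * n_cells, int, lineno)
            arr = np.asarray(vals).reshape(n_cells, 5)
            if not (arr[:, 0] == 4).all():
                raise MeshFileError(path, lineno, "non-tetrahedral cell found")
            tets = arr[:, 1:]
        elif up.startswith("CELL_TYPES"):
            read_values(n_cells, int, lineno)
        elif up.startswith("SCALARS"):
            name = line.split()[1]
            count = n_cells if name == "region" else n_points
            next(tk)  # LOOKUP_TABLE line
            vals = np.asarray(read_values(count, int, lineno))
            if name == "region":
                region_codes = vals
            elif name == "parcel":
                parcel = vals
            elif name.startswith("nodeset_"):
                nodeset_masks[name[len("nodeset_"):]] = vals

    if nodes is None or tets is None or region_codes is None:
        raise MeshFileError(path, 0, "incomplete VTK unstructured grid")
    labels = np.asarray(
        [regions[c] if c < len(regions) else "HOMOG" for c in region_codes],
        dtype="U6")
    node_sets = {
        name: np.flatnonzero(mask) for name, mask in nodeset_masks.items()}
    mesh = LabeledMesh(
        nodes=nodes, tets=tets, region_labels=labels,
        node_sets=node_sets, parcel_labels=parcel)
    mesh.validate()
    return mesh
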