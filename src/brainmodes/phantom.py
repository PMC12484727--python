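"""Synthetic multi-compartment head phantoms and benchmark geometries.

A stand-in for a segmentation-derived head mesh: concentric quasi-ellipsoidal
shells (WM core, GM shell, CSF layer, skull shell) voxelised on a regular
lattice, each cell split into six Freudenthal tetrahedra.  The Freudenthal
split is face-conformal under lattice translation, so a neck or spine
cylinder extended on the same lattice joins the skull base conformally, and
meshes derived from one phantom (skull-stripped, cylinder-attached) share
node coordinates exactly — which is what makes quantitative cross-scenario
mode comparison on common DOFs possible.

Node sets produced:

``base``
    nodes within a tolerance band of the lowest z-extent of the skull
    (fixed in the skull-base scenario);
``base_back_sides``
    skull-surface nodes at the base plus back and side sectors, emulating
    head immobilisation by scanner cushions;
``exterior``
    all outer-surface nodes;
``cylinder_base``
    far-end nodes of an attached neck/spine cylinder.

GM-surface nodes additionally carry parcel ids: nearest-direction assignment
to a spherical Fibonacci lattice of ``n_parcels`` directions, giving
approximately equal-solid-angle cortical sectors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import BRAIN_REGIONS, LabeledMesh, MeshError

__all__ = [
    "PhantomConfig",
    "build_layered_phantom",
    "build_bar_mesh",
    "attach_cylinder",
    "strip_skull",
    "fibonacci_directions",
]

# 8 cube corners, index = dx + 2 dy + 4 dz
_CORNERS = np.array(list(itertools.product((0, 1), repeat=3)))[:, ::-1]


def _freudenthal_table() -> np.ndarray:
    """Corner-index table of the 6-tet split of a cube, positively oriented."""
    corner_id = {tuple(c): i for i, c in enumerate(_CORNERS)}
    tets = []
    for perm in itertools.permutations(range(3)):
        v = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in perm:
            cur[ax] += 1
            v.append(tuple(cur))
        tet = [corner_id[c] for c in v]
        x = _CORNERS[tet].astype(float)
        if np.linalg.det(x[1:] - x[0]) < 0:
            tet[2], tet[3] = tet[3], tet[2]
        tets.append(tet)
    return np.array(tets)


_TETS_PER_CELL = 6
_FREUDENTHAL = _freudenthal_table()


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _key_jitter(keys: np.ndarray, seed: int, amplitude: float) -> np.ndarray:
    """Deterministic per-lattice-node jitter, independent of node numbering."""
    if amplitude == 0.0:
        return np.zeros((len(keys), 3))
    k = keys.astype(np.int64)
    base = (
        k[:, 0] * np.int64(73856093)
        ^ k[:, 1] * np.int64(19349663)
        ^ k[:, 2] * np.int64(83492791)
        ^ np.int64(seed)
    ).astype(np.uint64)
    out = np.empty((len(keys), 3))
    for d in range(3):
        v = _splitmix64(base + np.uint64(d) * np.uint64(0x2545F4914F6CDD1D))
        out[:, d] = v.astype(np.float64) / 2.0**64 * 2.0 - 1.0
    return amplitude * out


def _mesh_from_cells(
    cell_ijk: np.ndarray,
    cell_labels: np.ndarray,
    origin: np.ndarray,
    spacing: np.ndarray,
    *,
    jitter_amplitude: float = 0.0,
    seed: int = 0,
) -> LabeledMesh:
    """Tetrahedralise a set of lattice cells (deterministic numbering)."""
    cell_ijk = np.asarray(cell_ijk, dtype=np.int64).reshape(-1, 3)
    cell_labels = np.asarray(cell_labels, dtype="U6")
    order = np.lexsort((cell_ijk[:, 2], cell_ijk[:, 1], cell_ijk[:, 0]))
    cell_ijk, cell_labels = cell_ijk[order], cell_labels[order]

    corners = cell_ijk[:, None, :] + _CORNERS[None, :, :]  # (C, 8, 3)
    flat = corners.reshape(-1, 3)
    keys, inverse = np.unique(flat, axis=0, return_inverse=True)
    inverse = np.asarray(inverse).reshape(-1)
    nodes = origin[None, :] + keys * spacing[None, :]
    nodes = nodes + _key_jitter(keys, seed, jitter_amplitude)

    cell_nodes = inverse.reshape(-1, 8)  # (C, 8)
    tets = cell_nodes[:, _FREUDENTHAL].reshape(-1, 4)
    labels = np.repeat(cell_labels, _TETS_PER_CELL)

    mesh = LabeledMesh(nodes=nodes, tets=tets, region_labels=labels)
    # orientation safeguard: jitter is far below the cell size, but keep the
    # positive-volume convention airtight
    vols = mesh.signed_volumes()
    flip = np.flatnonzero(vols < 0)
    if flip.size:
        mesh.tets[flip[:, None], [2, 3]] = mesh.tets[flip[:, None], [3, 2]]
    mesh.meta = {
        "origin": origin.copy(),
        "spacing": spacing.copy(),
        "cell_ijk": cell_ijk,
        "cell_labels": cell_labels,
        "node_keys": keys,
        "seed": seed,
        "jitter_amplitude": jitter_amplitude,
    }
    return mesh


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` unit vectors approximately equally spaced on the sphere."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry recipe for a layered head phantom.

    ``shell_radii`` are outer radii in mm of the successive compartments:
    a single radius gives a homogeneous body (label HOMOG); three give
    WM/GM/CSF; four add the skull shell.  The default skull shell is the
    CSF outer surface offset by ``skull_thickness`` (5 mm).  ``axis_ratios``
    scale the x/y/z semi-axes to make the phantom head-like rather than
    spherical (which also splits most eigenvalue degeneracies); a tiny
    seeded node jitter (``jitter_frac`` of the outer radius) removes the
    rest.
    """

    shell_radii: tuple[float, ...] = (40.0, 50.0, 55.0, 60.0)
    skull_thickness: float = 5.0
    target_edge_length: float = 6.0
    axis_ratios: tuple[float, float, float] = (1.0, 0.92, 0.85)
    appendage: str = "none"  # none | neck | spine
    appendage_length: float | None = None  # mm; neck defaults 120, spine 500
    appendage_radius: float = 24.0
    n_parcels: int = 16
    seed: int = 0
    jitter_frac: float = 0.001
    base_band_frac: float = 0.75
    base_z_quantile: float = 0.35
    back_y_quantile: float = 0.25
    side_x_quantile: float = 0.80

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.shell_radii)
        if len(radii) == 3:
            radii = radii + (radii[-1] + self.skull_thickness,)
        if len(radii) not in (1, 4):
            raise ValueError("shell_radii must have 1, 3 or 4 entries")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("shell_radii must be strictly increasing")
        object.__setattr__(self, "shell_radii", radii)
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be positive")
        if self.n_parcels < 2:
            raise ValueError("n_parcels must be at least 2")
        if self.appendage not in ("none", "neck", "spine"):
            raise ValueError("appendage must be 'none', 'neck' or 'spine'")

    @property
    def region_names(self) -> tuple[str, ...]:
        return ("HOMOG",) if len(self.shell_radii) == 1 else (
            "WM", "GM", "CSF", "SKULL")

    @property
    def resolved_appendage_length(self) -> float:
        if self.appendage_length is not None:
            return float(self.appendage_length)
        return {"neck": 120.0, "spine": 500.0, "none": 0.0}[self.appendage]


def build_layered_phantom(config: PhantomConfig) -> LabeledMesh:
    """Generate a layered head phantom mesh from a :class:`PhantomConfig`.

    Elements are labeled by the shell their cell centroid falls in; node
    sets and GM parcel labels are attached.  Deterministic for a fixed
    config (connectivity is a pure function of the lattice; jitter is keyed
    by lattice index and seed).
    """
    radii = np.asarray(config.shell_radii)
    names = config.region_names
    a = np.asarray(config.axis_ratios, dtype=float)
    h = float(config.target_edge_length)
    rmax = radii[-1]

    half = np.ceil(rmax * a / h).astype(int) + 1
    origin = -half * h
    spacing = np.full(3, h)
    ranges = [np.arange(2 * k) for k in half]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    centroids = origin + (grid + 0.5) * h
    rho = np.sqrt(((centroids / (a * rmax)) ** 2).sum(axis=1)) * rmax
    shell = np.searchsorted(radii, rho, side="left")
    inside = shell < len(radii)
    cells = grid[inside]
    labels = np.asarray(names)[shell[inside]]

    if len(names) == 4:
        labels = _enforce_layering(cells, labels)

    counts = {n: int((labels == n).sum()) for n in names}
    missing = [n for n, c in counts.items() if c == 0]
    if missing or len(cells) == 0:
        widths = np.diff(np.concatenate([[0.0], radii]))
        thinnest = names[int(np.argmin(widths))] if names else "?"
        raise MeshError(
            f"target_edge_length {h:g} mm is infeasible: shell(s) "
            f"{missing or list(names)} received no elements "
            f"(thinnest shell: {thinnest})"
        )

    mesh = _mesh_from_cells(
        cells, labels, origin, spacing,
        jitter_amplitude=config.jitter_frac * rmax, seed=config.seed,
    )
    mesh.meta["config"] = config
    _assign_phantom_node_sets(mesh, config)
    _assign_parcels(mesh, config)
    mesh.validate()

    if config.appendage != "none":
        mesh = attach_cylinder(
            mesh,
            length_mm=config.resolved_appendage_length,
            radius_mm=config.appendage_radius,
            label=config.appendage.upper(),
        )
    return mesh


_FACE_NEIGHBORS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def _enforce_layering(cells: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Repair voxel labels so compartments nest (WM ⊂ GM ⊂ CSF ⊂ SKULL).

    At coarse resolution the thin CSF band can leave a GM (or WM) cell
    face-adjacent to the skull or the outside.  Two sweeps promote such
    cells outward (WM→GM where it touches CSF/SKULL/outside, then
    GM→CSF where it touches SKULL/outside), which keeps the topological
    layering that the phantom exists to preserve.
    """
    labels = labels.copy()
    lookup = {tuple(c): i for i, c in enumerate(cells)}

    def neighbor_labels(idx: int):
        for off in _FACE_NEIGHBORS:
            j = lookup.get(tuple(cells[idx] + off))
            yield None if j is None else labels[j]

    for source, bad, target in (
        ("WM", {"CSF", "SKULL", None}, "GM"),
        ("GM", {"SKULL", None}, "CSF"),
    ):
        for idx in np.flatnonzero(labels == source):
            if any(nb in bad for nb in neighbor_labels(int(idx))):
                labels[idx] = target
    return labels


def _assign_phantom_node_sets(mesh: LabeledMesh, config: PhantomConfig) -> None:
    h = float(config.target_edge_length)
    ext = mesh.surface_nodes()
    mesh.node_sets["exterior"] = ext

    outer_label = "SKULL" if "SKULL" in mesh.regions else mesh.regions[-1]
    shell_nodes = mesh.region_nodes(outer_label)
    z = mesh.nodes[shell_nodes, 2]
    band = config.base_band_frac * h
    mesh.node_sets["base"] = np.sort(shell_nodes[z <= z.min() + band])

    ez = mesh.nodes[ext, 2]
    ey = mesh.nodes[ext, 1]
    ex = np.abs(mesh.nodes[ext, 0])
    low = ez <= np.quantile(ez, config.base_z_quantile)
    back = ey <= np.quantile(ey, config.back_y_quantile)
    sides = ex >= np.quantile(ex, config.side_x_quantile)
    mesh.node_sets["base_back_sides"] = np.sort(ext[low | back | sides])


def _assign_parcels(mesh: LabeledMesh, config: PhantomConfig) -> None:
    """Parcel GM-surface nodes into near-equal solid-angle sectors."""
    if "GM" in mesh.regions and "CSF" in mesh.regions:
        gm_surface = np.intersect1d(
            mesh.region_nodes("GM"), mesh.region_nodes("CSF"))
    elif "GM" in mesh.regions:
        gm_surface = np.intersect1d(mesh.region_nodes("GM"), mesh.surface_nodes())
    else:
        gm_surface = mesh.surface_nodes()
    a = np.asarray(config.axis_ratios, dtype=float)
    u = mesh.nodes[gm_surface] / a
    norm = np.linalg.norm(u, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    u = u / norm
    dirs = fibonacci_directions(config.n_parcels)
    parcel = np.argmax(u @ dirs.T, axis=1)
    mesh.parcel_labels = np.full(mesh.n_nodes, -1, dtype=np.int64)
    mesh.parcel_labels[gm_surface] = parcel


def build_bar_mesh(length_mm: float, side_mm: float, n_divisions: int) -> LabeledMesh:
    """Structured tetrahedralised rectangular bar for analytic benchmarks.

    ``n_divisions`` cells along the length; the square cross-section is
    divided to keep cells near-cubic.  Node sets ``fixed_end`` (x = 0) and
    ``free_end`` (x = L).
    """
    if n_divisions < 2:
        raise ValueError("n_divisions must be at least 2")
    if length_mm <= 0 or side_mm <= 0:
        raise ValueError("length and side must be positive")
    n_ax = int(n_divisions)
    n_side = max(1, round(n_ax * side_mm / length_mm))
    hx = length_mm / n_ax
    hs = side_mm / n_side
    ranges = [np.arange(n_ax), np.arange(n_side), np.arange(n_side)]
    cells = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    labels = np.full(len(cells), "HOMOG", dtype="U6")
    mesh = _mesh_from_cells(
        cells, labels, origin=np.zeros(3), spacing=np.array([hx, hs, hs]))
    tol = 1e-9 * length_mm
    x = mesh.nodes[:, 0]
    mesh.node_sets["fixed_end"] = np.flatnonzero(x <= tol)
    mesh.node_sets["free_end"] = np.flatnonzero(x >= length_mm - tol)
    mesh.node_sets["exterior"] = mesh.surface_nodes()
    mesh.validate()
    return mesh


def attach_cylinder(
    mesh: LabeledMesh,
    length_mm: float,
    radius_mm: float,
    label: str = "NECK",
) -> LabeledMesh:
    """Join a vertical cylinder conformally under the skull base.

    The cylinder is voxelised on the phantom's own lattice: within the
    circular footprint around the z-axis, every column is filled from the
    local bottom of the existing mesh down to a common flat base plane at
    least ``length_mm`` below the current skull bottom.  The far-end nodes
    form the ``cylinder_base`` node set.

    Requires the lattice metadata produced by :func:`build_layered_phantom`;
    meshes read back from disk cannot be extended.
    """
    meta = mesh.meta
    for key in ("cell_ijk", "cell_labels", "origin", "spacing"):
        if key not in meta:
            raise MeshError(
                "attach_cylinder requires lattice metadata from "
                "build_layered_phantom")
    if "SKULL" not in mesh.regions:
        raise MeshError("attach_cylinder requires a SKULL region")
    if label not in ("NECK", "SPINE"):
        raise ValueError("cylinder label must be 'NECK' or 'SPINE'")

    cells = meta["cell_ijk"]
    labels = meta["cell_labels"]
    origin, spacing = meta["origin"], meta["spacing"]
    h = float(spacing[2])
    centroids = origin + (cells + 0.5) * spacing
    in_footprint = np.hypot(centroids[:, 0], centroids[:, 1]) <= radius_mm
    if not np.any(in_footprint & (labels == "SKULL")):
        raise MeshError(
            f"no SKULL elements within the {radius_mm:g} mm attachment "
            "footprint; increase the cylinder radius")

    fp = cells[in_footprint]
    cols: dict[tuple[int, int], int] = {}
    for i, j, k in fp:
        key = (int(i), int(j))
        cols[key] = min(cols.get(key, k), int(k))
    k_lowest = min(cols.values())
    # pad by the jitter amplitude so the guaranteed extent is >= length_mm
    jit = float(meta.get("jitter_amplitude", 0.0))
    n_len = int(np.ceil((length_mm + 2.0 * jit) / h))
    k_base = k_lowest - n_len

    new_cells = [
        (i, j, k)
        for (i, j), k_low in sorted(cols.items())
        for k in range(k_base, k_low)
    ]
    new_cells = np.array(new_cells, dtype=np.int64).reshape(-1, 3)
    all_cells = np.vstack([cells, new_cells])
    all_labels = np.concatenate(
        [labels, np.full(len(new_cells), label, dtype="U6")])

    config: PhantomConfig = meta.get("config") or PhantomConfig()
    out = _mesh_from_cells(
        all_cells, all_labels, origin, spacing,
        jitter_amplitude=meta.get("jitter_amplitude", 0.0),
        seed=meta.get("seed", 0),
    )
    out.meta["config"] = config
    _assign_phantom_node_sets(out, config)
    _assign_parcels(out, config)
    cyl_nodes = out.region_nodes(label)
    zc = out.nodes[cyl_nodes, 2]
    band = config.base_band_frac * h
    out.node_sets["cylinder_base"] = np.sort(cyl_nodes[zc <= zc.min() + band])
    out.validate()
    return out


def strip_skull(mesh: LabeledMesh) -> LabeledMesh:
    """Remove SKULL (and appendage) elements; recompute the outer surface.

    Lattice-free: works on any :class:`LabeledMesh`.  Idempotent; a no-op
    with a warning when no skull is present.
    """
    keep = np.isin(mesh.region_labels, BRAIN_REGIONS)
    if keep.all():
        warnings.warn("strip_skull: mesh has no SKULL elements; no-op",
                      stacklevel=2)
        return mesh.copy()

    tets = mesh.tets[keep]
    labels = mesh.region_labels[keep]
    used = np.unique(tets)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))

    out = LabeledMesh(
        nodes=mesh.nodes[used],
        tets=remap[tets],
        region_labels=labels,
        parcel_labels=mesh.parcel_labels[used],
    )
    for name, idx in mesh.node_sets.items():
        if name in ("exterior", "base", "base_back_sides", "cylinder_base"):
            continue  # tied to the removed outer shell; recomputed/obsolete
        mapped = remap[np.asarray(idx)]
        mapped = mapped[mapped >= 0]
        if mapped.size:
            out.node_sets[name] = np.sort(mapped)
    out.node_sets["exterior"] = out.surface_nodes()

    meta = dict(mesh.meta)
    if "cell_labels" in meta:
        cell_keep = np.isin(meta["cell_labels"], BRAIN_REGIONS)
        meta["cell_ijk"] = meta["cell_ijk"][cell_keep]
        meta["cell_labels"] = meta["cell_labels"][cell_keep]
        meta.pop("node_keys", None)
    out.meta = meta
    out.validate()
    return out
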