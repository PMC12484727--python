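"""Labeled tetrahedral meshes.

The mesh container used throughout the package: node coordinates in
millimetres, 4-node tetrahedra (C3D4-style linear elements), a region label
per element (WM, GM, CSF, SKULL, NECK, SPINE or HOMOG), named node sets for
boundary conditions, and an optional parcel id per node for projecting mode
shapes onto cortical-surface sectors.

Vertex-ordering convention: every tetrahedron (n0, n1, n2, n3) has strictly
positive signed volume det([x1-x0, x2-x0, x3-x0]) / 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: region labels recognised by the package, innermost compartment first
REGION_LABELS = ("WM", "GM", "CSF", "SKULL", "NECK", "SPINE", "HOMOG")

#: regions that constitute brain tissue (survive skull stripping)
BRAIN_REGIONS = ("WM", "GM", "CSF", "HOMOG")

_FACE_INDEX = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


class MeshError(ValueError):
    """Raised for invalid mesh topology or labeling."""


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with per-element region labels and named node sets.

    Parameters
    ----------
    nodes
        ``(n_nodes, 3)`` float array of coordinates in mm.
    tets
        ``(n_elements, 4)`` integer array of 0-based node indices.
    region_labels
        ``(n_elements,)`` array of strings from :data:`REGION_LABELS`.
    node_sets
        Mapping from set name (e.g. ``"base"``, ``"exterior"``) to a sorted
        integer array of node indices.
    parcel_labels
        ``(n_nodes,)`` integer array; parcel id for GM-surface nodes,
        ``-1`` elsewhere.
    meta
        Construction metadata (lattice origin/spacing, generating config);
        not part of the geometric identity of the mesh.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_labels: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    parcel_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.region_labels = np.asarray(self.region_labels, dtype="U6")
        if self.parcel_labels is None:
            self.parcel_labels = np.full(len(self.nodes), -1, dtype=np.int64)
        else:
            self.parcel_labels = np.asarray(self.parcel_labels, dtype=np.int64)

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    @property
    def regions(self) -> tuple[str, ...]:
        """Region labels present, in canonical order."""
        present = set(self.region_labels.tolist())
        return tuple(r for r in REGION_LABELS if r in present)

    def signed_volumes(self) -> np.ndarray:
        """Signed volume of every element (positive under the convention)."""
        x = self.nodes[self.tets]
        e = x[:, 1:] - x[:, :1]
        return np.linalg.det(e) / 6.0

    def total_volume(self) -> float:
        return float(self.signed_volumes().sum())

    def region_volume(self, label: str) -> float:
        mask = self.region_labels == label
        if not mask.any():
            raise MeshError(f"no elements with region label {label!r}")
        return float(self.signed_volumes()[mask].sum())

    def region_nodes(self, label: str) -> np.ndarray:
        """Sorted indices of nodes belonging to elements of one region."""
        mask = self.region_labels == label
        return np.unique(self.tets[mask])

    # -- surface extraction ----------------------------------------------

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces that belong to exactly one tetrahedron."""
        faces = self.tets[:, _FACE_INDEX].reshape(-1, 3)
        faces = np.sort(faces, axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        return uniq[counts == 1]

    def surface_nodes(self) -> np.ndarray:
        """Sorted indices of nodes on the outer (boundary) surface."""
        return np.unique(self.boundary_faces())

    # -- integrity --------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure."""
        n = self.n_nodes
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= n):
            raise MeshError("tetrahedra reference nonexistent node indices")
        vols = self.signed_volumes()
        if vols.size and vols.min() <= 0:
            bad = int(np.argmin(vols))
            raise MeshError(
                f"element {bad} has non-positive signed volume {vols[bad]:g}"
            )
        if self.region_labels.shape[0] != self.n_elements:
            raise MeshError("region_labels length does not match element count")
        unknown = set(self.region_labels.tolist()) - set(REGION_LABELS)
        if unknown:
            raise MeshError(f"unknown region labels: {sorted(unknown)}")
        for name, idx in self.node_sets.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise MeshError(f"node set {name!r} references nonexistent nodes")
        if self.parcel_labels.shape[0] != n:
            raise MeshError("parcel_labels length does not match node count")

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            nodes=self.nodes.copy(),
            tets=self.tets.copy(),
            region_labels=self.region_labels.copy(),
            node_sets={k: np.array(v) for k, v in self.node_sets.items()},
            parcel_labels=self.parcel_labels.copy(),
            meta=dict(self.meta),
        )
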