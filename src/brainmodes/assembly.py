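"""Global stiffness/mass assembly for linear tetrahedra.

Constant-strain (linear, C3D4-style) tetrahedra with isotropic linear
elasticity.  Element stiffness is the exact integral K_e = V · BᵀDB (the
integrand is constant); element mass is either the consistent matrix
(ρV/20)(1 + δᵢⱼ) per direction or the row-sum lumped diagonal ρV/4.

Dirichlet conditions are applied by elimination: rows/columns of
constrained DOFs are removed, which keeps M positive definite and the
reduced K symmetric.  DOF numbering is 3 per node, (node, direction) →
3·node + direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .materials import Material, MaterialSet
from .mesh import LabeledMesh, MeshError

__all__ = [
    "AssembledSystem",
    "element_stiffness",
    "element_mass",
    "assemble",
    "apply_dirichlet",
]


class AssemblyError(ValueError):
    pass


@dataclass
class AssembledSystem:
    """Sparse symmetric global matrices with the constrained-DOF map.

    ``dof_map[3*node + direction]`` is the index of that DOF in the reduced
    matrices, or ``-1`` if it is constrained.  ``K`` and ``M`` are over the
    ``n_free`` free DOFs only.
    """

    K: sp.csr_matrix
    M: sp.csr_matrix
    dof_map: np.ndarray
    n_nodes: int

    @property
    def n_free(self) -> int:
        return self.K.shape[0]

    @property
    def fully_constrained(self) -> bool:
        return self.n_free == 0

    @property
    def is_constrained(self) -> bool:
        return self.n_free < 3 * self.n_nodes

    def free_dofs(self) -> np.ndarray:
        """Global DOF indices of the free DOFs, in reduced order."""
        free = np.flatnonzero(self.dof_map >= 0)
        return free[np.argsort(self.dof_map[free])]


def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6×6 isotropic D for engineering strain (xx, yy, zz, xy, yz, zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _gradients_and_volumes(coords: np.ndarray):
    """Shape-function gradients and volumes for stacked tets.

    ``coords``: (n, 4, 3).  Returns ``grads`` (n, 4, 3) with
    grads[e, a] = ∇N_a (constant over the element) and ``vols`` (n,).
    """
    e = coords[:, 1:] - coords[:, :1]  # (n, 3, 3) edge matrix
    det = np.linalg.det(e)
    vols = det / 6.0
    if (vols <= 0).any():
        bad = int(np.argmin(vols))
        raise AssemblyError(
            f"degenerate tetrahedron at index {bad} "
            f"(signed volume {vols[bad]:g})")
    inv = np.linalg.inv(e)  # rows i of inv.T are gradients of N_1..N_3
    g = inv.transpose(0, 2, 1)  # (n, 3, 3): g[e, a-1] = ∇N_a, a = 1..3
    g0 = -g.sum(axis=1, keepdims=True)  # partition of unity: Σ ∇N_a = 0
    grads = np.concatenate([g0, g], axis=1)
    return grads, vols


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement operators, (n, 6, 12), engineering shear."""
    n = grads.shape[0]
    B = np.zeros((n, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def element_stiffness(tet_coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12×12 stiffness of one constant-strain tetrahedron (K_e = V·BᵀDB)."""
    coords = np.asarray(tet_coords, dtype=float).reshape(1, 4, 3)
    grads, vols = _gradients_and_volumes(coords)
    B = _b_matrices(grads)[0]
    D = _elasticity_matrix(E, nu)
    Ke = vols[0] * (B.T @ D @ B)
    return 0.5 * (Ke + Ke.T)


_MASS_TEMPLATE = (np.ones((4, 4)) + np.eye(4)) / 20.0  # consistent, per V·rho


def element_mass(tet_coords: np.ndarray, rho: float,
                 lumped: bool = False) -> np.ndarray:
    """12×12 mass of one tetrahedron (consistent by default)."""
    coords = np.asarray(tet_coords, dtype=float).reshape(1, 4, 3)
    _, vols = _gradients_and_volumes(coords)
    if lumped:
        block = np.eye(4) / 4.0
    else:
        block = _MASS_TEMPLATE
    return rho * vols[0] * np.kron(block, np.eye(3))


def assemble(mesh: LabeledMesh, materials: MaterialSet,
             mass: str = "consistent") -> AssembledSystem:
    """Assemble unconstrained global K and M (3 DOFs per node).

    Elements are grouped by region so each group shares one elasticity
    matrix; the scatter-add uses a COO triplet accumulation.
    """
    if mass not in ("consistent", "lumped"):
        raise ValueError("mass must be 'consistent' or 'lumped'")
    missing = [r for r in mesh.regions if r not in materials]
    if missing:
        raise AssemblyError(
            f"no material defined for region(s) {missing}")

    n_dof = 3 * mesh.n_nodes
    rows_k, cols_k, vals_k = [], [], []
    vals_m = []

    dofs_all = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)

    for region in mesh.regions:
        emask = mesh.region_labels == region
        mat: Material = materials[region]
        coords = mesh.nodes[mesh.tets[emask]]
        try:
            grads, vols = _gradients_and_volumes(coords)
        except AssemblyError as exc:
            raise AssemblyError(f"region {region}: {exc}") from None
        B = _b_matrices(grads)
        D = _elasticity_matrix(mat.E, mat.nu)
        Ke = np.einsum("eai,ab,ebj->eij", B, D, B, optimize=True)
        Ke *= vols[:, None, None]
        if mass == "lumped":
            block = np.eye(4) / 4.0
        else:
            block = _MASS_TEMPLATE
        Me_block = np.kron(block, np.eye(3))
        Me = (mat.rho * vols)[:, None, None] * Me_block[None, :, :]

        dofs = dofs_all[emask]
        rows = np.repeat(dofs, 12, axis=1).reshape(-1)
        cols = np.tile(dofs, (1, 12)).reshape(-1)
        rows_k.append(rows)
        cols_k.append(cols)
        vals_k.append(Ke.reshape(-1))
        vals_m.append(Me.reshape(-1))

    rows = np.concatenate(rows_k)
    cols = np.concatenate(cols_k)
    K = sp.coo_matrix(
        (np.concatenate(vals_k), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    M = sp.coo_matrix(
        (np.concatenate(vals_m), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    K = (K + K.T) * 0.5  # kill floating-point asymmetry
    M = (M + M.T) * 0.5
    return AssembledSystem(
        K=K, M=M, dof_map=np.arange(n_dof, dtype=np.int64),
        n_nodes=mesh.n_nodes)


def apply_dirichlet(
    system: AssembledSystem,
    mesh: LabeledMesh,
    node_set_name,
    fixed_directions=(0, 1, 2),
) -> AssembledSystem:
    """Fix DOFs of named node set(s) by row/column elimination.

    ``node_set_name`` may be one name or a sequence of names (union).
    ``fixed_directions`` selects the translational components (0=x, 1=y,
    2=z); the default fixes all three, matching the convention that a
    "fixed" boundary suppresses all translational displacement.
    """
    names = [node_set_name] if isinstance(node_set_name, str) else list(node_set_name)
    node_lists = []
    for name in names:
        if name not in mesh.node_sets:
            raise KeyError(
                f"node set {name!r} not found; available: "
                f"{sorted(mesh.node_sets)}")
        node_lists.append(np.asarray(mesh.node_sets[name]))
    nodes = np.unique(np.concatenate(node_lists)) if node_lists else np.array([], int)
    if nodes.size == 0:
        raise AssemblyError(
            f"node set(s) {names} are empty: constraining nothing would "
            "leave rigid-body modes unintentionally")

    fixed_global = (3 * nodes[:, None] + np.asarray(fixed_directions)).reshape(-1)
    fixed_reduced = system.dof_map[fixed_global]
    fixed_reduced = np.unique(fixed_reduced[fixed_reduced >= 0])

    keep = np.ones(system.n_free, dtype=bool)
    keep[fixed_reduced] = False
    keep_idx = np.flatnonzero(keep)

    new_map = np.full_like(system.dof_map, -1)
    old_free = np.flatnonzero(system.dof_map >= 0)
    reduced_pos = system.dof_map[old_free]
    new_of_reduced = np.full(system.n_free, -1, dtype=np.int64)
    new_of_reduced[keep_idx] = np.arange(keep_idx.size)
    new_map[old_free] = new_of_reduced[reduced_pos]

    K = system.K[keep_idx][:, keep_idx].tocsr()
    M = system.M[keep_idx][:, keep_idx].tocsr()
    return AssembledSystem(K=K, M=M, dof_map=new_map, n_nodes=system.n_nodes)
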