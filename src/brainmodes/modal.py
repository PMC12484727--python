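"""Generalized eigensolution ([K] − ω²[M]){φ} = 0 for the lowest modes.

Shift-invert Lanczos (ARPACK through :func:`scipy.sparse.linalg.eigsh`)
about σ = 0 for constrained systems and σ = −10 s⁻² for free-free systems,
where the semidefinite K would otherwise make the factorization singular.
Mode shapes are displacement-normalized: the largest-magnitude entry of
each eigenvector is scaled to +1, which also fixes the (otherwise
arbitrary) eigenvector sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.linalg import eigsh

from .assembly import AssembledSystem
from .mesh import LabeledMesh

__all__ = [
    "ModalResult",
    "solve_modes",
    "normalize_modes",
    "expand_to_full",
    "reduce_from_full",
    "frequency_table",
    "export_modes_vtk",
]

_FREE_FREE_SIGMA = -10.0  # s^-2; below the 6 zero eigenvalues of a free body


class FullyConstrainedError(ValueError):
    """All DOFs are fixed; the system has no modes."""


class ConvergenceError(RuntimeError):
    def __init__(self, n_converged: int, n_requested: int):
        super().__init__(
            f"eigensolver converged {n_converged}/{n_requested} modes")
        self.n_converged = n_converged


@dataclass
class ModalResult:
    """Eigenfrequencies (Hz) and mode shapes over free DOFs.

    ``shapes`` is ``(n_free, n_modes)``, column i the mode shape at
    ``frequencies_hz[i]`` (ascending).  ``residuals`` holds the relative
    residual ‖Kφ − ω²Mφ‖ / ‖Kφ‖ per mode.
    """

    frequencies_hz: np.ndarray
    omegas: np.ndarray
    shapes: np.ndarray
    residuals: np.ndarray
    dof_map: np.ndarray
    n_nodes: int
    n_requested: int
    n_converged: int
    normalization: str = "raw"

    @property
    def n_modes(self) -> int:
        return self.shapes.shape[1]


def solve_modes(
    system: AssembledSystem,
    n_modes: int = 25,
    sigma: float | None = None,
    seed: int = 0,
    normalize: bool = True,
    residual_tol: float = 1e-6,
) -> ModalResult:
    """Extract the ``n_modes`` lowest eigenpairs of the assembled system.

    Deterministic for a fixed seed (the Lanczos start vector is seeded;
    eigenvector sign is fixed by displacement normalization).  Retries with
    a perturbed shift if the shifted operator cannot be factorized.
    """
    if system.fully_constrained:
        raise FullyConstrainedError(
            "system is fully constrained (n_free = 0); no modes exist")
    n_free = system.n_free
    if not 0 < n_modes < n_free:
        raise ValueError(
            f"n_modes must be in (0, n_free={n_free}), got {n_modes}")

    if sigma is None:
        sigma = 0.0 if system.is_constrained else _FREE_FREE_SIGMA

    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(n_free)

    shifts = [sigma, sigma - 1.0, sigma - 100.0]
    last_exc: Exception | None = None
    for s in shifts:
        try:
            vals, vecs = eigsh(
                system.K, k=n_modes, M=system.M, sigma=s, which="LM", v0=v0)
            break
        except RuntimeError as exc:  # singular factorization
            last_exc = exc
    else:
        raise RuntimeError(
            f"shift-invert factorization failed for shifts {shifts}"
        ) from last_exc

    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[-1]), 1.0)
    vals = np.where(np.abs(vals) < 1e-12 * scale, 0.0, vals)
    vals = np.clip(vals, 0.0, None)  # numerically tiny negatives → 0

    omegas = np.sqrt(vals)
    freqs = omegas / (2.0 * np.pi)

    kphi = system.K @ vecs
    mphi = system.M @ vecs
    res_num = np.linalg.norm(kphi - mphi * vals[None, :], axis=0)
    # scale by ||Kφ|| plus the spectral scale of the pencil so that
    # zero-frequency (rigid-body) modes, where Kφ ≈ 0, are judged fairly
    res_den = (np.linalg.norm(kphi, axis=0)
               + max(vals[-1], 1.0) * np.linalg.norm(mphi, axis=0))
    residuals = res_num / np.where(res_den > 0, res_den, 1.0)
    n_conv = int((residuals <= residual_tol).sum())
    if n_conv < n_modes:
        raise ConvergenceError(n_conv, n_modes)

    result = ModalResult(
        frequencies_hz=freqs,
        omegas=omegas,
        shapes=vecs,
        residuals=residuals,
        dof_map=system.dof_map,
        n_nodes=system.n_nodes,
        n_requested=n_modes,
        n_converged=n_conv,
    )
    return normalize_modes(result) if normalize else result


def normalize_modes(result: ModalResult) -> ModalResult:
    """Displacement normalization: largest-magnitude entry of each shape → +1.

    Idempotent; fixes the eigenvector sign convention.
    """
    shapes = result.shapes.copy()
    for i in range(shapes.shape[1]):
        col = shapes[:, i]
        peak = col[np.argmax(np.abs(col))]
        if peak == 0.0:
            raise ValueError(f"mode {i} is a zero vector; cannot normalize")
        shapes[:, i] = col / peak
    return replace(result, shapes=shapes, normalization="max-unit")


def expand_to_full(result: ModalResult,
                   system: AssembledSystem | None = None) -> np.ndarray:
    """Re-insert constrained DOFs as zeros → (3·n_nodes, n_modes) fields."""
    dof_map = result.dof_map if system is None else system.dof_map
    if system is not None and not np.array_equal(result.dof_map, system.dof_map):
        raise ValueError("dof_map mismatch between result and system")
    full = np.zeros((dof_map.shape[0], result.n_modes))
    free = dof_map >= 0
    full[free] = result.shapes[dof_map[free]]
    return full


def reduce_from_full(full: np.ndarray, system: AssembledSystem) -> np.ndarray:
    """Inverse of :func:`expand_to_full` on the free DOFs."""
    free = np.flatnonzero(system.dof_map >= 0)
    out = np.zeros((system.n_free, full.shape[1]))
    out[system.dof_map[free]] = full[free]
    return out


def frequency_table(result: ModalResult) -> pd.DataFrame:
    """Tidy per-mode table: mode, f_hz, omega_rad_s, residual."""
    return pd.DataFrame({
        "mode": np.arange(1, result.n_modes + 1),
        "f_hz": result.frequencies_hz,
        "omega_rad_s": result.omegas,
        "residual": result.residuals,
    })


def export_modes_vtk(result: ModalResult, mesh: LabeledMesh, outdir) -> list:
    """Write one VTK file per mode with the displacement field as vectors.

    File names follow ``mode_###_<freq>Hz.vtk``.  Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    full = expand_to_full(result).reshape(mesh.n_nodes, 3, -1)
    paths = []
    for i in range(result.n_modes):
        f = result.frequencies_hz[i]
        path = outdir / f"mode_{i + 1:03d}_{f:.3f}Hz.vtk"
        disp = full[:, :, i]
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write(f"mode {i + 1}, f = {f:.6g} Hz\n")
            fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {mesh.n_nodes} double\n")
            for x, y, z in mesh.nodes:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
            m = mesh.n_elements
            fh.write(f"CELLS {m} {5 * m}\n")
            for tet in mesh.tets:
                fh.write("4 " + " ".join(str(int(v)) for v in tet) + "\n")
            fh.write(f"CELL_TYPES {m}\n")
            fh.write("\n".join(["10"] * m) + "\n")
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            fh.write("VECTORS displacement double\n")
            for ux, uy, uz in disp:
                fh.write(f"{ux:.9g} {uy:.9g} {uz:.9g}\n")
        paths.append(path)
    return paths
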