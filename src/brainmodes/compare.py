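"""Quantitative mode-set comparison: MAC, optimal pairing, NRFD.

The Modal Assurance Criterion between mode vectors φ_A and φ_B is the
squared normalized dot product

    MAC = (φ_Aᵀ φ_B)² / ((φ_Aᵀ φ_A)(φ_Bᵀ φ_B)),

1 for perfect consistency, 0 for none; invariant to per-mode scaling and
sign.  Mode pairing solves the one-to-one assignment maximizing total MAC
(Hungarian algorithm), dropping pairs below a threshold.  The Normalized
Relative Frequency Difference between paired frequencies is

    NRFD = |f_r − f_v| / f_r,

with the first argument the reference model.  Both sets must live on the
same DOF basis; comparing modes from different meshes is unsupported
(restrict both to shared DOFs first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["mac", "mac_matrix", "pair_modes", "nrfd", "compare",
           "ModeComparison", "plot_comparison"]


def _as_shape_matrix(x) -> np.ndarray:
    """Accept a ModalResult or a (n_dofs, n_modes) array."""
    shapes = getattr(x, "shapes", x)
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim == 1:
        shapes = shapes[:, None]
    return shapes


def mac(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """MAC of two mode vectors; in [0, 1]."""
    a = np.asarray(phi_a, dtype=float).reshape(-1)
    b = np.asarray(phi_b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError(
            f"mode vectors have different lengths ({a.size} vs {b.size}); "
            "modes from different meshes cannot be compared")
    aa, bb = a @ a, b @ b
    if aa == 0.0 or bb == 0.0:
        raise ValueError("cannot compute MAC of a zero vector")
    return float((a @ b) ** 2 / (aa * bb))


def mac_matrix(A, B) -> np.ndarray:
    """(n_A × n_B) matrix of MAC values between two mode sets."""
    sa = _as_shape_matrix(A)
    sb = _as_shape_matrix(B)
    if sa.shape[0] != sb.shape[0]:
        raise ValueError(
            f"mode sets live on different DOF spaces "
            f"({sa.shape[0]} vs {sb.shape[0]} DOFs)")
    na = (sa * sa).sum(axis=0)
    nb = (sb * sb).sum(axis=0)
    if (na == 0).any() or (nb == 0).any():
        raise ValueError("cannot compute MAC of a zero vector")
    cross = sa.T @ sb
    return cross**2 / np.outer(na, nb)


def pair_modes(mac_mat: np.ndarray, threshold: float = 0.5):
    """One-to-one pairing maximizing total MAC.

    Returns ``(pairing, unpaired_a, unpaired_b)`` where ``pairing`` is a
    list of ``(i, k, mac_ik)`` sorted by ``i``; assignments with MAC below
    ``threshold`` are dropped to the unpaired lists.
    """
    m = np.asarray(mac_mat, dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("MAC matrix contains non-finite entries")
    rows, cols = linear_sum_assignment(-m)
    pairing = [
        (int(i), int(k), float(m[i, k]))
        for i, k in zip(rows, cols)
        if m[i, k] >= threshold
    ]
    pairing.sort(key=lambda p: p[0])
    paired_a = {p[0] for p in pairing}
    paired_b = {p[1] for p in pairing}
    unpaired_a = [i for i in range(m.shape[0]) if i not in paired_a]
    unpaired_b = [k for k in range(m.shape[1]) if k not in paired_b]
    return pairing, unpaired_a, unpaired_b


def nrfd(f_r: float, f_v: float, percent: bool = False) -> float:
    """Normalized relative frequency difference |f_r − f_v| / f_r.

    ``f_r`` is the reference frequency; ``percent=True`` returns the value
    multiplied by 100.
    """
    if f_r <= 0:
        raise ValueError(f"reference frequency must be positive, got {f_r}")
    val = abs(f_r - f_v) / f_r
    return 100.0 * val if percent else val


@dataclass
class ModeComparison:
    """MAC matrix, optimal pairing and per-pair NRFD of two modal results."""

    mac: np.ndarray
    pairing: list
    nrfd: np.ndarray
    unpaired_a: list
    unpaired_b: list
    freqs_a: np.ndarray | None = None
    freqs_b: np.ndarray | None = None
    threshold: float = 0.5
    labels: tuple = field(default=("A", "B"))

    @property
    def n_paired(self) -> int:
        return len(self.pairing)

    def to_frame(self) -> pd.DataFrame:
        """Heatmap-ready per-pair table (pair, f_ref, f_val, MAC, NRFD)."""
        rows = []
        for (i, k, m), d in zip(self.pairing, self.nrfd):
            rows.append({
                "mode_a": i + 1,
                "mode_b": k + 1,
                "f_ref_hz": None if self.freqs_a is None else self.freqs_a[i],
                "f_val_hz": None if self.freqs_b is None else self.freqs_b[k],
                "mac": m,
                "nrfd": d,
                "nrfd_percent": 100.0 * d,
            })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "labels": list(self.labels),
            "threshold": self.threshold,
            "n_paired": self.n_paired,
            "n_unpaired_a": len(self.unpaired_a),
            "n_unpaired_b": len(self.unpaired_b),
            "mac_min": float(min((p[2] for p in self.pairing), default=np.nan)),
            "mac_mean": float(np.mean([p[2] for p in self.pairing]))
            if self.pairing else float("nan"),
            "nrfd_max": float(self.nrfd.max()) if self.nrfd.size else float("nan"),
        }


def compare(A, B, threshold: float = 0.5, labels=("A", "B")) -> ModeComparison:
    """Compose MAC matrix, pairing and per-pair NRFD for two modal results.

    ``A`` is the reference model for the NRFD direction.  ``A``/``B`` may
    be :class:`~brainmodes.modal.ModalResult` objects or bare shape
    matrices (NRFD columns are then NaN-free only if frequencies exist).
    """
    m = mac_matrix(A, B)
    pairing, unpaired_a, unpaired_b = pair_modes(m, threshold=threshold)
    fa = getattr(A, "frequencies_hz", None)
    fb = getattr(B, "frequencies_hz", None)
    if fa is not None and fb is not None:
        vals = np.array([nrfd(fa[i], fb[k]) for i, k, _ in pairing])
    else:
        vals = np.full(len(pairing), np.nan)
    return ModeComparison(
        mac=m, pairing=pairing, nrfd=vals,
        unpaired_a=unpaired_a, unpaired_b=unpaired_b,
        freqs_a=None if fa is None else np.asarray(fa),
        freqs_b=None if fb is None else np.asarray(fb),
        threshold=threshold, labels=tuple(labels),
    )


def plot_comparison(comp: ModeComparison, path) -> None:
    """MAC heatmap + per-pair NRFD bar chart, saved as one PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(
        1, 2, figsize=(11, 4.2),
        gridspec_kw={"width_ratios": [1.15, 1]})
    im = ax0.imshow(comp.mac, vmin=0, vmax=1, cmap="viridis", origin="lower")
    ax0.set_xlabel(f"mode ({comp.labels[1]})")
    ax0.set_ylabel(f"mode ({comp.labels[0]})")
    ax0.set_title("MAC")
    fig.colorbar(im, ax=ax0, fraction=0.046)
    if comp.pairing:
        idx = [p[0] + 1 for p in comp.pairing]
        ax1.bar(idx, 100.0 * comp.nrfd, color="#b5533c")
        ax1.set_xlabel(f"paired mode ({comp.labels[0]})")
        ax1.set_ylabel("NRFD (%)")
    ax1.set_title("NRFD per paired mode")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
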