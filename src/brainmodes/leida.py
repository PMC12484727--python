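"""Leading Eigenvector Dynamics Analysis on synthetic BOLD-like signals.

Pipeline: narrowband signals → instantaneous phase (analytic signal) → per
timepoint phase-alignment matrix A_ij(t) = cos(θ_i(t) − θ_j(t)) → its
unit-norm leading eigenvector → k-means clustering of the eigenvector
series into K recurring modes (cluster centroids).

The synthetic generator plants recurring phase-locking states: state 1 is
a global in-phase state (all regions co-vary); every other state k has a
designated region subset oscillating in anti-phase (offset π) to the rest.
Recovered centroids can then be scored against the planted patterns.  The
generator emulates only this statistical structure of resting-state
recordings, not hemodynamics or anatomy.

A small bridge projects finite-element mode shapes onto GM-surface parcels
so eigenmodes and empirical modes can be compared as vectors over the same
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import hilbert
from sklearn.cluster import KMeans

from .mesh import LabeledMesh

__all__ = [
    "SignalSet",
    "EmpiricalModeSet",
    "simulate_bold",
    "instantaneous_phase",
    "leading_eigenvector_series",
    "cluster_modes",
    "project_mode_to_parcels",
    "match_eigenmodes_to_empirical",
]


@dataclass
class SignalSet:
    """Region × time signal matrix with optional planted ground truth."""

    signals: np.ndarray  # (n_regions, n_timepoints)
    sampling_interval: float = 1.0  # seconds
    planted_states: np.ndarray | None = None  # (n_timepoints,) state ids
    planted_patterns: np.ndarray | None = None  # (K_states, n_regions), ±1
    planted_phases: np.ndarray | None = None  # (n_regions, n_timepoints)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] < 2:
            raise ValueError("signals must be (n_regions >= 2, n_timepoints)")
        if not np.isfinite(self.signals).all():
            raise ValueError("signals contain non-finite values")

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]


@dataclass
class EmpiricalModeSet:
    """K unit-norm cluster centroids with their timepoint occupancies."""

    centroids: np.ndarray  # (K, n_regions), each row unit norm
    occupancy: np.ndarray  # (K,), sums to 1
    K: int
    assignments: np.ndarray | None = None  # (n_timepoints,) cluster ids


def simulate_bold(
    n_regions: int = 16,
    n_timepoints: int = 2000,
    K_states: int = 8,
    noise_sd: float = 0.2,
    seed: int = 0,
    carrier_freq: float = 0.05,  # cycles per sample
    mean_dwell: int = 25,  # samples per state visit
    global_occupancy: float = 0.5,
) -> SignalSet:
    """Generate narrowband signals with planted phase-locking states.

    The timeline is segmented into dwell periods; each period is the global
    in-phase state (probability ``global_occupancy``) or one of the
    ``K_states − 1`` anti-phase states chosen uniformly.  In state k the
    subset S_k runs π out of phase with the remaining regions.  Gaussian
    observation noise of standard deviation ``noise_sd`` is added to unit
    amplitude carriers.  Deterministic per seed.

    The default dwell time (25 samples ≳ one carrier cycle) makes every
    state recur many times over a typical series, and planted patterns are
    drawn with pairwise |cosine| ≤ 0.75 so the states are genuinely
    distinct — both defining properties of the recurring phase-locking
    regimes the generator emulates.
    """
    if K_states < 2:
        raise ValueError("K_states must be at least 2")
    if n_regions < 4:
        raise ValueError("n_regions must be at least 4")
    if n_timepoints < 2 * mean_dwell:
        raise ValueError("n_timepoints too short for the dwell time")
    if not 0.0 <= global_occupancy <= 1.0:
        raise ValueError("global_occupancy must be in [0, 1]")

    rng = np.random.default_rng(seed)

    # distinct ±1 region patterns; state 0 is the global (all in phase) mode
    patterns = np.ones((K_states, n_regions))
    max_cos = 0.75  # pairwise pattern separation (|cosine| bound)
    for k in range(1, K_states):
        for _ in range(1000):
            size = int(rng.integers(2, max(3, n_regions // 2 + 1)))
            members = rng.choice(n_regions, size=size, replace=False)
            cand = np.ones(n_regions)
            cand[members] = -1.0
            cos = np.abs(patterns[:k] @ cand) / n_regions
            if cos.max() <= max_cos:
                patterns[k] = cand
                break
        else:
            raise RuntimeError(
                "could not draw sufficiently distinct state patterns; "
                "reduce K_states or increase n_regions")

    states = np.empty(n_timepoints, dtype=np.int64)
    t = 0
    while t < n_timepoints:
        if rng.random() < global_occupancy:
            s = 0
        else:
            s = int(rng.integers(1, K_states))
        dwell = max(10, int(rng.poisson(mean_dwell)))
        states[t:t + dwell] = s
        t += dwell

    tgrid = np.arange(n_timepoints)
    base_phase = 2.0 * np.pi * carrier_freq * tgrid  # common carrier
    offsets = np.where(patterns[states] < 0, np.pi, 0.0).T  # (n_regions, T)
    phases = base_phase[None, :] + offsets
    signals = np.cos(phases) + noise_sd * rng.standard_normal(
        (n_regions, n_timepoints))

    return SignalSet(
        signals=signals,
        planted_states=states,
        planted_patterns=patterns,
        planted_phases=np.mod(phases + np.pi, 2 * np.pi) - np.pi,
    )


def instantaneous_phase(signals: np.ndarray) -> np.ndarray:
    """Per-region instantaneous phase via the analytic signal, in (−π, π].

    Each region's signal is demeaned first; a constant signal has no phase
    and raises, naming the offending region.
    """
    x = np.asarray(getattr(signals, "signals", signals), dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    flat = np.ptp(x, axis=1) == 0
    if flat.any():
        raise ValueError(
            f"region(s) {np.flatnonzero(flat).tolist()} have constant "
            "signal; instantaneous phase is undefined")
    return np.angle(hilbert(x, axis=1))


def leading_eigenvector_series(phases: np.ndarray) -> np.ndarray:
    """Unit-norm leading eigenvector of cos(θ_i − θ_j) at every timepoint.

    Exploits A(t) = c cᵀ + s sᵀ with c = cos θ(t), s = sin θ(t) (rank ≤ 2),
    but solves the full symmetric eigenproblem per timepoint for clarity.
    Sign convention: flipped so the majority of components are negative
    (ties broken by the component sum, then the first component), mapping
    the global in-phase state to an all-same-sign vector.
    """
    th = np.asarray(phases, dtype=float)
    n, T = th.shape
    c, s = np.cos(th), np.sin(th)
    # (T, n, n) batch of alignment matrices
    A = (np.einsum("it,jt->tij", c, c) + np.einsum("it,jt->tij", s, s))
    w, v = np.linalg.eigh(A)
    lead = v[:, :, -1]  # (T, n), already unit norm
    neg = (lead < 0).sum(axis=1)
    flip = neg < n / 2
    tie = neg == n - neg
    if tie.any():
        sums = lead.sum(axis=1)
        flip = flip | (tie & (sums > 0))
        zero_sum = tie & (sums == 0)
        if zero_sum.any():
            flip = flip | (zero_sum & (lead[:, 0] > 0))
    lead[flip] *= -1.0
    return lead


def cluster_modes(
    eigenvector_series: np.ndarray,
    K: int = 8,
    seed: int = 0,
    n_restarts: int = 20,
) -> EmpiricalModeSet:
    """K-means clustering of the eigenvector series into K recurring modes.

    Centroids are unit-normalized; occupancy is the fraction of timepoints
    assigned to each cluster.  Deterministic per seed.
    """
    X = np.asarray(eigenvector_series, dtype=float)
    T = X.shape[0]
    if T < 5 * K:
        raise ValueError(
            f"series of length {T} too short to extract {K} clusters")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    counts = np.bincount(labels, minlength=K)
    if (counts == 0).any():
        raise RuntimeError("k-means produced an empty cluster")
    centroids = km.cluster_centers_
    norms = np.linalg.norm(centroids, axis=1, keepdims=True)
    centroids = centroids / norms
    return EmpiricalModeSet(
        centroids=centroids,
        occupancy=counts / T,
        K=K,
        assignments=labels,
    )


def project_mode_to_parcels(mode_field: np.ndarray,
                            mesh: LabeledMesh) -> np.ndarray:
    """Mean signed radial displacement per GM-surface parcel, z-scored.

    ``mode_field`` is a full displacement field, ``(3·n_nodes,)`` or
    ``(n_nodes, 3)``.  A spatially uniform radial field maps to the zero
    vector (constant before z-scoring).
    """
    u = np.asarray(mode_field, dtype=float)
    if u.ndim == 1:
        u = u.reshape(-1, 3)
    if u.shape != (mesh.n_nodes, 3):
        raise ValueError(
            f"mode field shape {u.shape} does not match mesh with "
            f"{mesh.n_nodes} nodes")
    labeled = np.flatnonzero(mesh.parcel_labels >= 0)
    if labeled.size == 0:
        raise ValueError("mesh has no parcel labels")
    n_parcels = int(mesh.parcel_labels.max()) + 1

    pos = mesh.nodes[labeled]
    r = np.linalg.norm(pos, axis=1, keepdims=True)
    r[r == 0] = 1.0
    radial = (u[labeled] * (pos / r)).sum(axis=1)

    parcels = mesh.parcel_labels[labeled]
    counts = np.bincount(parcels, minlength=n_parcels)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"empty parcel(s): {empty}")
    means = np.bincount(parcels, weights=radial, minlength=n_parcels) / counts

    sd = means.std()
    if sd < 1e-12 * (np.abs(means).max() + 1e-300):
        return np.zeros(n_parcels)
    return (means - means.mean()) / sd


def match_eigenmodes_to_empirical(parcel_vectors: np.ndarray,
                                  modes: EmpiricalModeSet):
    """Sign-invariant cosine similarity + best one-to-one match.

    ``parcel_vectors`` is (n_modes, n_parcels).  Returns
    ``(similarity, matches)`` where ``similarity[i, k] = |cos| `` between
    eigenmode i and centroid k, and ``matches`` is a list of
    ``(i, k, similarity)`` from the optimal assignment.
    """
    P = np.atleast_2d(np.asarray(parcel_vectors, dtype=float))
    C = modes.centroids
    if P.shape[1] != C.shape[1]:
        raise ValueError(
            f"parcel dimension {P.shape[1]} does not match centroid "
            f"dimension {C.shape[1]}")
    pn = np.linalg.norm(P, axis=1, keepdims=True)
    pn[pn == 0] = 1.0
    cn = np.linalg.norm(C, axis=1, keepdims=True)
    sim = np.abs((P / pn) @ (C / cn).T)
    rows, cols = linear_sum_assignment(-sim)
    matches = [(int(i), int(k), float(sim[i, k])) for i, k in zip(rows, cols)]
    return sim, matches
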