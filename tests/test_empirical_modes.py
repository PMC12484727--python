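"""Synthetic BOLD generation, phase extraction, LEiDA clustering, projection."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from brainmodes import (
    cluster_modes,
    instantaneous_phase,
    leading_eigenvector_series,
    match_eigenmodes_to_empirical,
    project_mode_to_parcels,
    simulate_bold,
)


class TestSimulateBold:
    def test_deterministic_per_seed(self):
        a = simulate_bold(seed=7)
        b = simulate_bold(seed=7)
        assert np.array_equal(a.signals, b.signals)
        assert np.array_equal(a.planted_states, b.planted_states)

    def test_noise_free_global_state_is_coherent(self):
        ss = simulate_bold(n_regions=8, n_timepoints=600, K_states=2,
                           noise_sd=0.0, seed=0, global_occupancy=1.0)
        ph = instantaneous_phase(ss.signals)
        interior = slice(30, -30)
        spread = np.abs(ph[:, interior] - ph[0:1, interior])
        assert spread.max() < 0.05

    def test_antiphase_state_offset_is_pi(self):
        ss = simulate_bold(n_regions=8, n_timepoints=600, K_states=2,
                           noise_sd=0.0, seed=1, global_occupancy=0.0)
        k = 1
        in_state = np.flatnonzero(ss.planted_states == k)
        in_state = in_state[(in_state > 50) & (in_state < 550)]
        pattern = ss.planted_patterns[k]
        anti = np.flatnonzero(pattern < 0)
        base = np.flatnonzero(pattern > 0)
        ph = instantaneous_phase(ss.signals)
        diff = np.angle(np.exp(1j * (ph[anti[0], in_state]
                                     - ph[base[0], in_state])))
        assert np.abs(np.abs(diff) - np.pi).mean() < 0.1

    def test_recovered_phase_matches_planted(self):
        ss = simulate_bold(n_regions=6, n_timepoints=800, K_states=2,
                           noise_sd=0.0, seed=2, global_occupancy=1.0)
        ph = instantaneous_phase(ss.signals)
        err = np.angle(np.exp(1j * (ph - ss.planted_phases)))
        assert np.abs(err[:, 40:-40]).max() < 0.05

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            simulate_bold(K_states=1)
        with pytest.raises(ValueError):
            simulate_bold(n_regions=2)


class TestInstantaneousPhase:
    def test_cosine_phase_advances_linearly(self):
        f = 0.04
        t = np.arange(1000)
        x = np.vstack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)])
        ph = instantaneous_phase(x)
        slope = np.diff(np.unwrap(ph[0, 100:-100]))
        assert np.allclose(slope, 2 * np.pi * f, atol=1e-3)

    def test_sin_lags_cos_by_half_pi(self):
        f = 0.04
        t = np.arange(1000)
        x = np.vstack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)])
        ph = instantaneous_phase(x)
        lag = np.angle(np.exp(1j * (ph[0, 100:-100] - ph[1, 100:-100])))
        assert np.allclose(lag, np.pi / 2, atol=1e-2)

    def test_constant_signal_names_region(self):
        x = np.vstack([np.ones(100), np.sin(np.arange(100))])
        with pytest.raises(ValueError, match=r"\[0\]"):
            instantaneous_phase(x)


class TestLeadingEigenvector:
    def test_uniform_phases_give_uniform_eigenvector(self):
        phases = np.full((6, 5), 0.3)
        lead = leading_eigenvector_series(phases.copy())
        expected = -np.ones(6) / np.sqrt(6)  # majority-negative convention
        assert np.allclose(lead, expected[None, :], atol=1e-12)
        A = np.cos(phases[:, 0][:, None] - phases[:, 0][None, :])
        assert np.allclose(A @ lead[0], 6.0 * lead[0])

    def test_two_block_antiphase_matches_dense_oracle(self):
        p, q = 3, 5
        theta = np.concatenate([np.zeros(p), np.full(q, np.pi)])
        lead = leading_eigenvector_series(theta[:, None])
        A = np.cos(theta[:, None] - theta[None, :])
        w, v = np.linalg.eigh(A)
        oracle = v[:, -1]
        if (oracle < 0).sum() < (p + q) / 2:
            oracle = -oracle
        assert np.allclose(np.abs(lead[0]), np.abs(oracle), atol=1e-12)
        # constant within blocks, opposite sign across blocks
        assert np.allclose(lead[0, :p], lead[0, 0])
        assert np.allclose(lead[0, p:], lead[0, p])
        assert lead[0, 0] * lead[0, p] < 0

    def test_majority_negative_convention(self):
        ss = simulate_bold(seed=4)
        lead = leading_eigenvector_series(instantaneous_phase(ss.signals))
        neg = (lead < 0).sum(axis=1)
        assert (neg >= lead.shape[1] / 2).all()

    def test_invariant_to_global_phase_shift(self):
        ss = simulate_bold(n_regions=8, n_timepoints=400, seed=5)
        ph = instantaneous_phase(ss.signals)
        a = leading_eigenvector_series(ph)
        b = leading_eigenvector_series(ph + 1.234)
        assert np.allclose(a, b, atol=1e-9)


class TestClustering:
    def test_k1_centroid_is_normalized_mean(self):
        ss = simulate_bold(seed=3)
        ev = leading_eigenvector_series(instantaneous_phase(ss.signals))
        ms = cluster_modes(ev, K=1, seed=0)
        mean = ev.mean(axis=0)
        mean /= np.linalg.norm(mean)
        assert np.allclose(ms.centroids[0], mean, atol=1e-12)
        assert ms.occupancy.tolist() == [1.0]

    def test_noise_free_four_state_recovery(self):
        ss = simulate_bold(n_regions=12, n_timepoints=1500, K_states=4,
                           noise_sd=0.0, seed=6, global_occupancy=0.25)
        ev = leading_eigenvector_series(instantaneous_phase(ss.signals))
        ms = cluster_modes(ev, K=4, seed=0)
        P = ss.planted_patterns / np.linalg.norm(
            ss.planted_patterns, axis=1, keepdims=True)
        sim = np.abs(P @ ms.centroids.T)
        rows, cols = linear_sum_assignment(-sim)
        assert sim[rows, cols].min() > 0.99

    def test_occupancies_sum_to_one_and_centroids_unit_norm(self):
        ss = simulate_bold(seed=8)
        ev = leading_eigenvector_series(instantaneous_phase(ss.signals))
        ms = cluster_modes(ev, K=8, seed=0)
        assert ms.occupancy.sum() == pytest.approx(1.0)
        assert np.allclose(np.linalg.norm(ms.centroids, axis=1), 1.0)

    def test_global_state_occupancy_recovered(self):
        # generator spends ~50% of the time in the global state; the
        # recovered occupancy should agree within 5 percentage points on
        # average across seeds
        occ = []
        for seed in range(6):
            ss = simulate_bold(seed=seed)
            ev = leading_eigenvector_series(instantaneous_phase(ss.signals))
            ms = cluster_modes(ev, K=8, seed=seed)
            sim = np.abs(ms.centroids @ (np.ones(16) / 4.0))
            occ.append(ms.occupancy[np.argmax(sim)])
        assert abs(np.mean(occ) - 0.5) < 0.05

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            cluster_modes(np.zeros((10, 4)), K=8)


class TestProjection:
    def test_uniform_radial_field_maps_to_zero(self, coarse_phantom):
        pos = coarse_phantom.nodes
        r = np.linalg.norm(pos, axis=1, keepdims=True)
        r[r == 0] = 1.0
        field = pos / r  # unit radial displacement everywhere
        z = project_mode_to_parcels(field, coarse_phantom)
        assert np.allclose(z, 0.0)

    def test_matches_naive_per_node_loop(self, coarse_phantom, rng):
        field = rng.standard_normal((coarse_phantom.n_nodes, 3))
        z = project_mode_to_parcels(field, coarse_phantom)
        sums = {}
        counts = {}
        for n in range(coarse_phantom.n_nodes):
            p = coarse_phantom.parcel_labels[n]
            if p < 0:
                continue
            pos = coarse_phantom.nodes[n]
            rad = field[n] @ (pos / np.linalg.norm(pos))
            sums[p] = sums.get(p, 0.0) + rad
            counts[p] = counts.get(p, 0) + 1
        means = np.array([sums[p] / counts[p] for p in sorted(sums)])
        expected = (means - means.mean()) / means.std()
        assert np.allclose(z, expected, atol=1e-10)

    def test_mesh_without_parcels_rejected(self, small_bar):
        with pytest.raises(ValueError, match="parcel"):
            project_mode_to_parcels(
                np.zeros((small_bar.n_nodes, 3)), small_bar)


class TestMatching:
    def test_self_similarity_is_one(self):
        ss = simulate_bold(seed=9)
        ev = leading_eigenvector_series(instantaneous_phase(ss.signals))
        ms = cluster_modes(ev, K=4, seed=0)
        sim, matches = match_eigenmodes_to_empirical(ms.centroids, ms)
        assert np.allclose(np.diag(sim), 1.0)
        assert all(i == k for i, k, _ in matches)

    def test_orthogonal_vectors_have_zero_similarity(self):
        from brainmodes.leida import EmpiricalModeSet
        modes = EmpiricalModeSet(
            centroids=np.eye(4)[:2], occupancy=np.array([0.5, 0.5]), K=2)
        sim, _ = match_eigenmodes_to_empirical(np.eye(4)[2:3], modes)
        assert np.allclose(sim, 0.0)

    def test_block_pattern_fixture_best_match(self):
        from brainmodes.leida import EmpiricalModeSet
        pattern = np.array([1.0, 1, 1, -1, -1, -1])
        other = np.array([1.0, -1, 1, -1, 1, -1])
        modes = EmpiricalModeSet(
            centroids=np.vstack([pattern, other]) / np.sqrt(6),
            occupancy=np.array([0.6, 0.4]), K=2)
        sim, matches = match_eigenmodes_to_empirical(
            (-3.0 * pattern)[None, :], modes)
        assert matches[0][1] == 0 and matches[0][2] == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        from brainmodes.leida import EmpiricalModeSet
        modes = EmpiricalModeSet(
            centroids=np.eye(3), occupancy=np.full(3, 1 / 3), K=3)
        with pytest.raises(ValueError, match="dimension"):
            match_eigenmodes_to_empirical(np.ones((1, 4)), modes)
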