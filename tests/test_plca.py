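"""PLCA and shift-invariant 2D PLCA: EM contracts, recovery, pruning."""

import numpy as np
import pytest

from choruscope import (
    AudioSignal, InputError, ParameterError,
    component_reconstruction, model_entropies, normalize_input, plca_fit,
    prune_components, sample_analysis_windows, shannon_entropy, siplca2d_fit,
    synthesize_factor_matrix,
)
from choruscope.plca import SIPLCA2DModel


class TestNormalizeInput:
    def test_uniform_matrix(self):
        v = normalize_input(np.ones((2, 2)))
        assert np.allclose(v, 0.25)

    def test_scale_invariance(self, rng):
        x = rng.random((6, 9))
        assert np.allclose(normalize_input(x), normalize_input(10 * x))

    def test_sums_to_one(self, rng):
        assert normalize_input(rng.random((13, 7))).sum() == pytest.approx(
            1.0, abs=1e-12)

    def test_rejects_zero_and_nan(self):
        with pytest.raises(InputError):
            normalize_input(np.zeros((3, 3)))
        bad = np.ones((3, 3)); bad[0, 0] = np.nan
        with pytest.raises(InputError):
            normalize_input(bad)


class TestPLCAFit:
    def test_rank_one_exact(self, rng):
        w = rng.random(12); w /= w.sum()
        h = rng.random(20); h /= h.sum()
        m = plca_fit(np.outer(w, h), K=1, n_iters=5, seed=3)
        assert np.abs(m.W[:, 0] - w).max() < 1e-8
        assert np.abs(m.H[0] - h).max() < 1e-8
        assert m.objective_history[-1] < 1e-12

    def test_disjoint_two_component_weights(self, rng):
        w1 = np.zeros(12); w1[:6] = rng.random(6); w1 /= w1.sum()
        w2 = np.zeros(12); w2[6:] = rng.random(6); w2 /= w2.sum()
        h1 = np.zeros(20); h1[:10] = rng.random(10); h1 /= h1.sum()
        h2 = np.zeros(20); h2[10:] = rng.random(10); h2 /= h2.sum()
        v = 0.6 * np.outer(w1, h1) + 0.4 * np.outer(w2, h2)
        m = plca_fit(v, K=2, n_iters=2000, tol=1e-14, seed=5)
        assert np.allclose(np.sort(m.z)[::-1], [0.6, 0.4], atol=1e-6)

    def test_invariants_hold_every_iteration(self, rng):
        v = normalize_input(rng.random((10, 14)))
        plca_fit(v, K=3, n_iters=40, seed=1, check_invariants=True)

    def test_unnormalized_input_rejected(self, rng):
        with pytest.raises(InputError, match="sum to 1"):
            plca_fit(rng.random((5, 5)) + 1.0, K=2, seed=0)

    def test_overcomplete_k_warns(self, rng):
        v = normalize_input(rng.random((4, 6)))
        with pytest.warns(UserWarning, match="overcomplete"):
            plca_fit(v, K=5, n_iters=3, seed=0)


class TestSIPLCA2DFit:
    def test_single_kernel_impulse_recovery(self, rng):
        kernel = rng.random((6, 4)) ** 2
        kernel /= kernel.sum()
        act = np.zeros((10, 20)); act[4, 7] = 1.0
        v, _ = synthesize_factor_matrix(kernel[None], act[None], [1.0])
        m = siplca2d_fit(v, K_max=4, kernel_shape=(6, 4), alpha=0.98,
                         n_iters=200, seed=0)
        assert m.k_effective == 1
        # cosine up to the shift ambiguity between kernel and activation
        best = max(
            np.abs(np.vdot(np.roll(m.kernels[0], (df, dt), (0, 1)).ravel(),
                           kernel.ravel()))
            / (np.linalg.norm(m.kernels[0]) * np.linalg.norm(kernel))
            for df in range(-3, 4) for dt in range(-2, 3))
        assert best >= 0.99

    def test_alpha_one_is_monotone_em(self, rng):
        v = normalize_input(rng.random((16, 24)))
        m = siplca2d_fit(v, K_max=4, kernel_shape=(5, 4), alpha=1.0,
                         n_iters=60, tol=0.0, seed=2, check_invariants=True)
        diffs = np.diff(m.objective_history)
        assert np.all(diffs <= 1e-10)

    def test_normalization_invariants(self, rng):
        v = normalize_input(rng.random((20, 40)))
        m = siplca2d_fit(v, K_max=8, kernel_shape=(6, 5), n_iters=30, seed=4)
        assert np.allclose(m.kernels.sum(axis=(1, 2)), 1.0, atol=1e-6)
        assert np.allclose(m.activations.sum(axis=(1, 2)), 1.0, atol=1e-6)
        assert m.z.sum() == pytest.approx(1.0, abs=1e-6)
        assert m.reconstruct().sum() == pytest.approx(1.0, abs=1e-5)

    def test_kernel_larger_than_input_rejected(self, rng):
        v = normalize_input(rng.random((6, 6)))
        with pytest.raises(ParameterError):
            siplca2d_fit(v, K_max=2, kernel_shape=(8, 3), seed=0)

    def test_alpha_out_of_range_rejected(self, rng):
        v = normalize_input(rng.random((8, 8)))
        with pytest.raises(ParameterError):
            siplca2d_fit(v, K_max=2, kernel_shape=(3, 3), alpha=0.0, seed=0)

    def test_determinism(self, rng):
        v = normalize_input(rng.random((16, 24)))
        m1 = siplca2d_fit(v, K_max=4, kernel_shape=(5, 4), n_iters=30, seed=9)
        m2 = siplca2d_fit(v, K_max=4, kernel_shape=(5, 4), n_iters=30, seed=9)
        assert np.array_equal(m1.z, m2.z)
        assert np.array_equal(m1.kernels, m2.kernels)

    def test_time_shift_equivariance(self):
        # shifting the input in time moves the fitted activation peak by
        # the same number of frames; kernels agree up to the
        # kernel/activation shift ambiguity and EM's local-optimum wobble
        kernel = np.zeros((6, 4))
        kernel[1, :] = [0.2, 0.4, 0.3, 0.1]
        kernel[4, :] = [0.05, 0.3, 0.15, 0.05]
        kernel /= kernel.sum()
        fits = []
        for shift in (0, 3):
            act = np.zeros((7, 30)); act[3, 8 + shift] = 1.0
            v, _ = synthesize_factor_matrix(kernel[None], act[None], [1.0])
            fits.append(siplca2d_fit(v, K_max=2, kernel_shape=(6, 4),
                                     n_iters=400, tol=1e-12, seed=3))
        m1, m2 = fits
        p1 = np.unravel_index(np.argmax(m1.activations[0]),
                              m1.activations[0].shape)
        p2 = np.unravel_index(np.argmax(m2.activations[0]),
                              m2.activations[0].shape)
        assert p2[1] - p1[1] == 3
        c = max(
            np.abs(np.vdot(np.roll(m1.kernels[0], (df, dt), (0, 1)).ravel(),
                           m2.kernels[0].ravel()))
            / (np.linalg.norm(m1.kernels[0]) * np.linalg.norm(m2.kernels[0]))
            for df in range(-5, 6) for dt in range(-3, 4))
        assert c >= 0.8
        # reconstructions are equivariant up to those same approximations
        r1, r2 = m1.reconstruct(), m2.reconstruct()
        a, b = r2[:, 3:].ravel(), r1[:, :-3].ravel()
        cos = np.vdot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos >= 0.95


class TestPruning:
    def _model(self, z):
        z = np.asarray(z, float)
        K = z.size
        kernels = np.full((K, 2, 2), 0.25)
        acts = np.full((K, 3, 3), 1 / 9)
        return SIPLCA2DModel(kernels, acts, z, K, int((z > 1e-3).sum()),
                             0.98, 1e-3, 0, 0, np.zeros(1), (4, 4))

    def test_prune_drops_negligible(self):
        m = prune_components(self._model([0.5, 0.5 - 1e-9, 1e-9]), 1e-3)
        assert m.k_effective == 2
        assert np.allclose(m.z, 0.5, atol=1e-8)

    def test_floor_zero_is_identity(self):
        m0 = self._model([0.7, 0.3])
        m = prune_components(m0, 0.0)
        assert np.array_equal(m.z, m0.z)

    def test_all_below_floor_rejected(self):
        with pytest.raises(InputError):
            prune_components(self._model([1e-6, 1e-7]), 1e-3)

    def test_pruning_tiny_component_barely_moves_reconstruction(self, rng):
        v = normalize_input(rng.random((12, 16)))
        m = siplca2d_fit(v, K_max=6, kernel_shape=(4, 4), n_iters=60, seed=0)
        if np.any((m.z > 0) & (m.z < 1e-6)):
            from choruscope.plca import _kl
            pruned = prune_components(m, 1e-6)
            assert abs(_kl(v, pruned.reconstruct())
                       - _kl(v, m.reconstruct())) < 1e-4


class TestComponentReconstruction:
    def test_components_sum_to_full_reconstruction(self, rng):
        v = normalize_input(rng.random((14, 20)))
        m = siplca2d_fit(v, K_max=4, kernel_shape=(5, 4), n_iters=40, seed=6)
        total = sum(component_reconstruction(m, k) for k in range(m.K))
        assert np.allclose(total, m.reconstruct(), atol=1e-9)

    def test_out_of_range_component(self, rng):
        v = normalize_input(rng.random((10, 10)))
        m = siplca2d_fit(v, K_max=2, kernel_shape=(3, 3), n_iters=10, seed=0)
        with pytest.raises(ParameterError):
            component_reconstruction(m, 99)

    def test_disjoint_components_have_disjoint_support(self):
        k1 = np.zeros((4, 3)); k1[0, 1] = 1.0
        k2 = np.zeros((4, 3)); k2[3, 1] = 1.0
        a1 = np.zeros((9, 18)); a1[0, 2] = 1.0
        a2 = np.zeros((9, 18)); a2[8, 14] = 1.0
        v, _ = synthesize_factor_matrix(np.stack([k1, k2]),
                                        np.stack([a1, a2]), [0.5, 0.5])
        m = siplca2d_fit(v, K_max=4, kernel_shape=(4, 3), n_iters=200, seed=1)
        assert m.k_effective == 2
        r0 = component_reconstruction(m, 0)
        r1 = component_reconstruction(m, 1)
        overlap = np.minimum(r0, r1).sum()
        assert overlap < 1e-6


class TestEntropies:
    def test_spike_and_uniform(self):
        kernels = np.zeros((2, 3, 3)); kernels[:, 1, 1] = 1.0
        acts = np.full((2, 4, 4), 1 / 16)
        m = SIPLCA2DModel(kernels, acts, np.array([0.5, 0.5]), 2, 2,
                          0.98, 1e-3, 0, 0, np.zeros(1), (6, 6))
        rep = model_entropies(m)
        assert np.allclose(rep.kernel_entropies, 0.0)
        assert np.allclose(rep.activation_entropies, 1.0)
        assert rep.weight_entropy == pytest.approx(1.0)

    def test_matches_shared_entropy_oracle(self, rng):
        v = normalize_input(rng.random((12, 16)))
        m = siplca2d_fit(v, K_max=3, kernel_shape=(4, 4), n_iters=20, seed=2)
        rep = model_entropies(m)
        for k in range(m.K):
            assert rep.kernel_entropies[k] == pytest.approx(
                shannon_entropy(m.kernels[k].ravel(), normalized=True))


class TestAnalysisWindows:
    def test_concatenated_frame_count(self, rng):
        rate = 22050.0
        sig = AudioSignal(0.1 * rng.standard_normal(int(8 * rate)), rate)
        spec = sample_analysis_windows(sig, n_windows=4, window_seconds=1.0,
                                       fmin=220.0, hop=1024)
        single = sample_analysis_windows(sig, n_windows=1, window_seconds=1.0,
                                         fmin=220.0, hop=1024)
        assert spec.shape[1] == 4 * single.shape[1]
        assert np.all(np.diff(spec.times) > 0)

    def test_too_short_signal_rejected(self, rng):
        sig = AudioSignal(rng.standard_normal(22050), 22050.0)
        with pytest.raises(InputError):
            sample_analysis_windows(sig, n_windows=16, window_seconds=4.0)
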