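"""Probabilistic latent component analysis of spectrograms.

Two models over a normalised non-negative time-frequency matrix V
(sum(V) = 1):

* :func:`plca_fit` — classic PLCA, the probabilistic counterpart of
  NMF: V ~ sum_k w_k z_k h_k^T where every w_k (spectral template),
  h_k (temporal excitation) and the weight vector z are probability
  distributions.

* :func:`siplca2d_fit` — shift-invariant 2D PLCA: each component is a
  small time-frequency *kernel* placed anywhere in frequency shift and
  time by a 2D *activation* map,
  V ~ sum_k z_k (kernel_k * activation_k) (2D convolution). A sparsity
  hyper-parameter ``alpha`` < 1 both regularises the activations and
  sets the relevance scale at which uninformative components are
  pruned, giving automatic relevance determination: initialise with
  K_max components and read off the surviving count ``k_effective``.

Both fitters run expectation-maximisation with multiplicative updates;
with no prior (``alpha = 1``) the KL divergence KL(V || model) is
non-increasing at every iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .audio_spectra import AudioSignal, Spectrogram, constant_q_spectrogram
from .exceptions import InputError, ParameterError
from .indices import shannon_entropy

__all__ = [
    "PLCAModel", "SIPLCA2DModel", "EntropyReport",
    "normalize_input", "plca_fit", "siplca2d_fit",
    "prune_components", "component_reconstruction", "model_entropies",
    "sample_analysis_windows",
]

_NORM_TOL = 1e-6


def _values_of(v) -> np.ndarray:
    if isinstance(v, Spectrogram):
        return v.values
    return np.asarray(v, dtype=np.float64)


def normalize_input(spec) -> np.ndarray:
    """Normalise a non-negative matrix (or Spectrogram) to sum to 1."""
    v = _values_of(spec)
    if v.ndim != 2:
        raise InputError("expected a 2-D matrix")
    if np.any(~np.isfinite(v)):
        raise InputError("input contains NaN or infinite values")
    if np.any(v < 0):
        raise InputError("input must be non-negative")
    total = v.sum()
    if total <= 0:
        raise InputError("cannot normalise an all-zero matrix")
    return v / total


def _check_normalized(v: np.ndarray) -> None:
    if np.any(~np.isfinite(v)):
        raise InputError("input contains NaN or infinite values")
    if np.any(v < 0):
        raise InputError("input must be non-negative")
    if abs(v.sum() - 1.0) > _NORM_TOL:
        raise InputError(
            "input must sum to 1; run normalize_input() first "
            f"(got sum = {v.sum():.6g})")


def _kl(v: np.ndarray, lam: np.ndarray) -> float:
    """KL(V || Lambda) for matrices both summing to 1 (0 log 0 := 0)."""
    mask = v > 0
    return float(np.sum(v[mask] * (np.log(v[mask])
                                   - np.log(np.maximum(lam[mask], 1e-300)))))


# ---------------------------------------------------------------------------
# PLCA (Eq. V ~ W Z H)
# ---------------------------------------------------------------------------

@dataclass
class PLCAModel:
    """Fitted PLCA factors.

    ``W`` holds K column distributions over frequency, ``H`` K row
    distributions over time and ``z`` the K mixing weights; each sums
    to 1.
    """

    W: np.ndarray                 # (F, K)
    z: np.ndarray                 # (K,)
    H: np.ndarray                 # (K, T)
    n_iter: int
    seed: int
    objective_history: np.ndarray

    @property
    def K(self) -> int:
        return self.z.size

    def reconstruct(self) -> np.ndarray:
        return (self.W * self.z) @ self.H


def plca_fit(v, K: int, n_iters: int = 200, tol: float = 1e-5,
             seed: int = 0, check_invariants: bool = False) -> PLCAModel:
    """Fit PLCA by EM.

    E-step: posterior over components per time-frequency cell;
    M-step: posterior-weighted marginalisation re-estimating w_k, h_k
    and z_k. Stops when the relative KL change drops below ``tol`` or
    after ``n_iters`` iterations. Deterministic given ``seed``.
    """
    v = _values_of(v)
    _check_normalized(v)
    if K < 1:
        raise ParameterError("K must be >= 1")
    if K > min(v.shape):
        import warnings
        warnings.warn(f"K={K} exceeds min(V dims)={min(v.shape)}: "
                      "overcomplete factorisation", stacklevel=2)
    f_dim, t_dim = v.shape
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.5, 1.5, size=(f_dim, K))
    w /= w.sum(axis=0)
    h = rng.uniform(0.5, 1.5, size=(K, t_dim))
    h /= h.sum(axis=1, keepdims=True)
    z = np.full(K, 1.0 / K)

    history = []
    for it in range(n_iters):
        lam = (w * z) @ h
        history.append(_kl(v, lam))
        r = np.where(lam > 0, v / np.maximum(lam, 1e-300), 0.0)
        # posterior-weighted counts, computed without materialising the
        # (F, T, K) posterior: C_k(f,.) = z_k w_k(f) * (R h_k)(f), etc.
        wn = w * z * (r @ h.T)            # (F, K) unnormalised new W
        hn = h * (z[:, None] * (w.T @ r))  # (K, T) unnormalised new H
        z = wn.sum(axis=0)
        z /= z.sum()
        wsum = wn.sum(axis=0)
        w = np.where(wsum > 0, wn / np.maximum(wsum, 1e-300), w)
        hsum = hn.sum(axis=1, keepdims=True)
        h = np.where(hsum > 0, hn / np.maximum(hsum, 1e-300), h)
        if check_invariants:
            assert np.allclose(w.sum(axis=0), 1.0, atol=_NORM_TOL)
            assert np.allclose(h.sum(axis=1), 1.0, atol=_NORM_TOL)
            assert abs(z.sum() - 1.0) <= _NORM_TOL
        if it > 0 and history[-2] - history[-1] <= tol * abs(history[-2]):
            break
    history.append(_kl(v, (w * z) @ h))
    order = np.argsort(-z)
    return PLCAModel(w[:, order], z[order], h[order], len(history) - 1,
                     seed, np.array(history))


# ---------------------------------------------------------------------------
# SI-PLCA2D
# ---------------------------------------------------------------------------

@dataclass
class SIPLCA2DModel:
    """Fitted shift-invariant 2D PLCA factors.

    ``kernels[k]`` is a (kf, kt) time-frequency patch summing to 1;
    ``activations[k]`` is a (F-kf+1, T-kt+1) map of (frequency shift,
    time) placements summing to 1; ``z`` are the mixing weights.
    Components are ordered by descending weight. Components whose
    weight collapsed to zero under the sparse prior keep their last
    (still normalised) kernels/activations.
    """

    kernels: np.ndarray               # (K, kf, kt)
    activations: np.ndarray           # (K, F-kf+1, T-kt+1)
    z: np.ndarray                     # (K,)
    K_max: int
    k_effective: int
    alpha: float
    z_floor: float
    seed: int
    n_iter: int
    objective_history: np.ndarray
    shape: tuple[int, int]

    @property
    def K(self) -> int:
        return self.z.size

    def reconstruct(self) -> np.ndarray:
        out = np.zeros(self.shape)
        for k in range(self.K):
            if self.z[k] > 0:
                out += self.z[k] * fftconvolve(self.kernels[k],
                                               self.activations[k], mode="full")
        return np.clip(out, 0.0, None)


def _default_kernel_shape(v_shape: tuple[int, int],
                          times: np.ndarray | None) -> tuple[int, int]:
    f_dim, t_dim = v_shape
    kf = max(2, f_dim // 3)
    if times is not None and times.size > 1:
        dt = float(np.median(np.diff(times)))
        kt = max(2, int(round(0.5 / dt)))
    else:
        kt = max(2, t_dim // 8)
    return kf, min(kt, max(2, t_dim - 1))


def siplca2d_fit(v, K_max: int = 16, kernel_shape: tuple[int, int] | None = None,
                 alpha: float = 0.98, n_iters: int = 200, tol: float = 1e-5,
                 seed: int = 0, z_floor: float = 1e-3,
                 refine_iters: int = 100,
                 check_invariants: bool = False) -> SIPLCA2DModel:
    """Fit shift-invariant 2D PLCA by EM with sparsity-driven component
    pruning (automatic relevance determination).

    The latent variables are (component k, frequency shift phi, time
    offset tau); the model is
    ``V(f,t) ~ sum_k z_k sum_{phi,tau} kernel_k(f-phi, tau)
    activation_k(phi, t-tau)``, i.e. a sum of 2D convolutions. The E/M
    steps reduce to 2D cross-correlations with the current factors.

    The sparsity hyper-parameter ``alpha`` in (0, 1] acts twice:

    * each M-step the activation maps are raised to the power
      ``1 + (1 - alpha)`` and renormalised (with a tiny floor so
      sharpened cells stay recoverable) — an entropic prior that keeps
      the fit away from the degenerate near-delta-kernel /
      dense-activation solution (which can reproduce any input with a
      single component);
    * after the main EM phase, components are pruned by relevance-
      tested backward elimination: a candidate (the weaker half of the
      most redundant pair by activation cosine, else the lowest-weight
      component) is tentatively deleted and the model refined for up
      to ``refine_iters`` EM iterations; the deletion stands if the KL
      fit has not degraded by more than ``1 - alpha`` nats relative to
      the full-K_max baseline, or if this deletion alone cost less
      than a tenth of that — i.e. if the component did not contribute
      significantly to the reconstruction. Elimination stops at the
      first component whose removal costs more.

    With ``alpha = 1`` both mechanisms are off and the fit is exact EM:
    the KL objective is non-increasing at every iteration.
    ``k_effective`` counts surviving weights above ``z_floor``.
    """
    times = v.times if isinstance(v, Spectrogram) else None
    v = _values_of(v)
    _check_normalized(v)
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must lie in (0, 1]")
    if K_max < 1:
        raise ParameterError("K_max must be >= 1")
    f_dim, t_dim = v.shape
    if kernel_shape is None:
        kernel_shape = _default_kernel_shape(v.shape, times)
    kf, kt = kernel_shape
    if kf >= f_dim or kt >= t_dim:
        raise ParameterError(
            f"kernel {kernel_shape} must be strictly smaller than V {v.shape}")
    af, at = f_dim - kf + 1, t_dim - kt + 1

    rng = np.random.default_rng(seed)
    kernels = rng.uniform(0.5, 1.5, size=(K_max, kf, kt))
    kernels /= kernels.sum(axis=(1, 2), keepdims=True)
    acts = rng.uniform(0.5, 1.5, size=(K_max, af, at))
    acts /= acts.sum(axis=(1, 2), keepdims=True)
    z = np.full(K_max, 1.0 / K_max)
    alive = np.ones(K_max, dtype=bool)
    act_exponent = 1.0 + (1.0 - alpha)
    history: list[float] = []

    def reconstruction() -> np.ndarray:
        lam = np.zeros_like(v)
        for k in np.nonzero(alive)[0]:
            lam += z[k] * fftconvolve(kernels[k], acts[k], mode="full")
        return lam

    def em_pass(max_iters: int, use_tol: bool) -> float:
        """Run EM over the alive components; returns the final KL."""
        nonlocal z
        for it in range(max_iters):
            lam = reconstruction()
            history.append(_kl(v, lam))
            r = np.where(lam > 0, v / np.maximum(lam, 1e-300), 0.0)
            omega = np.zeros(K_max)
            for k in np.nonzero(alive)[0]:
                # valid cross-correlations give the expected counts;
                # fftconvolve roundoff can leave tiny negatives -> clip
                cw = fftconvolve(r, acts[k, ::-1, ::-1], mode="valid")
                ch = fftconvolve(r, kernels[k, ::-1, ::-1], mode="valid")
                wn = np.clip(kernels[k] * cw, 0.0, None)
                hn = np.clip(acts[k] * ch, 0.0, None)
                mass = wn.sum()
                omega[k] = z[k] * mass
                if mass > 0:
                    kernels[k] = wn / mass
                hmass = hn.sum()
                if hmass > 0:
                    acts[k] = hn / hmass
                    if act_exponent > 1.0:
                        # floor keeps sharpened cells recoverable: a hard
                        # zero can never regrow under multiplicative updates
                        acts[k] = np.maximum(acts[k] ** act_exponent, 1e-16)
                        acts[k] /= acts[k].sum()
            z = omega / max(omega.sum(), 1e-300)
            if check_invariants:
                assert np.allclose(kernels.sum(axis=(1, 2))[alive], 1.0,
                                   atol=_NORM_TOL)
                assert np.allclose(acts.sum(axis=(1, 2))[alive], 1.0,
                                   atol=_NORM_TOL)
                assert abs(z.sum() - 1.0) <= _NORM_TOL
            if (use_tol and it > 0
                    and abs(history[-2] - history[-1]) <= tol * abs(history[-2])):
                break
        kl = _kl(v, reconstruction())
        history.append(kl)
        return kl

    kl_now = em_pass(n_iters, use_tol=True)

    if alpha < 1.0:
        kill_cost = 1.0 - alpha  # nats of fit a relevant component must carry
        kl_baseline = kl_now     # full K_max model after the main EM phase

        def cosines(mats, live):
            flat = mats[live].reshape(live.size, -1)
            flat = flat / np.maximum(np.linalg.norm(flat, axis=1),
                                     1e-300)[:, None]
            c = flat @ flat.T
            np.fill_diagonal(c, -1.0)
            return c

        def refine_and_test():
            """Rejuvenate + refine; True if the edit passes relevance."""
            nonlocal kl_now
            live = np.nonzero(alive)[0]
            # lift hard zeros so survivors can reabsorb structure
            kernels[live] = np.maximum(kernels[live], 1e-12)
            kernels[live] /= kernels[live].sum(axis=(1, 2), keepdims=True)
            acts[live] = np.maximum(acts[live], 1e-12)
            acts[live] /= acts[live].sum(axis=(1, 2), keepdims=True)
            kl_before = kl_now
            done = 0
            while done < refine_iters:
                chunk = min(10, refine_iters - done)
                kl_after = em_pass(chunk, use_tol=False)
                done += chunk
                if kl_after - kl_baseline <= 0.25 * kill_cost:
                    break
            # an edit stands if the *cumulative* degradation stays within
            # the prior scale (successive marginal edits cannot silently
            # erode the fit) or if this edit alone was negligible
            if (kl_after - kl_baseline > kill_cost
                    and kl_after - kl_before > 0.1 * kill_cost):
                return False
            kl_now = kl_after
            return True

        while alive.sum() > 1:
            snapshot = (kernels.copy(), acts.copy(), z.copy(), alive.copy(),
                        kl_now)
            live = np.nonzero(alive)[0]
            # prefer deleting the weaker half of the most redundant pair
            # (highest activation-map cosine): such a component's mass is
            # reabsorbed almost freely because its placements are already
            # covered; fall back to the lowest-weight component
            sim = cosines(acts, live)
            i, j = np.unravel_index(int(np.argmax(sim)), sim.shape)
            if sim[i, j] >= 0.5:
                weakest = int(live[i] if z[live[i]] <= z[live[j]] else live[j])
            else:
                weakest = int(live[np.argmin(z[live])])
            alive[weakest] = False
            z[weakest] = 0.0
            if z.sum() <= 0:
                kernels, acts, z, alive, kl_now = snapshot
                break
            z = z / z.sum()
            if not refine_and_test():
                kernels, acts, z, alive, kl_now = snapshot
                break
        kl_now = em_pass(refine_iters, use_tol=False)

    order = np.argsort(-z)
    z, kernels, acts = z[order], kernels[order], acts[order]
    return SIPLCA2DModel(kernels, acts, z, K_max,
                         int(np.sum(z > z_floor)), alpha, z_floor, seed,
                         len(history), np.array(history), v.shape)


def prune_components(model: SIPLCA2DModel, z_floor: float) -> SIPLCA2DModel:
    """Drop components with z below ``z_floor`` and renormalise z."""
    keep = model.z >= z_floor if z_floor > 0 else np.ones(model.K, bool)
    if not np.any(keep):
        raise InputError("all components fall below the floor: degenerate model")
    z = model.z[keep]
    return SIPLCA2DModel(model.kernels[keep], model.activations[keep],
                         z / z.sum(), model.K_max, int(keep.sum()),
                         model.alpha, z_floor, model.seed, model.n_iter,
                         model.objective_history, model.shape)


def component_reconstruction(model: SIPLCA2DModel, k: int) -> np.ndarray:
    """z_k * (kernel_k convolved with activation_k), shaped like V."""
    if not 0 <= k < model.K:
        raise ParameterError(f"component index {k} out of range [0, {model.K})")
    return model.z[k] * fftconvolve(model.kernels[k], model.activations[k],
                                    mode="full")


@dataclass
class EntropyReport:
    """Normalised Shannon entropies of a fitted model's distributions."""

    kernel_entropies: np.ndarray
    activation_entropies: np.ndarray
    weight_entropy: float


def model_entropies(model: SIPLCA2DModel) -> EntropyReport:
    """Normalised entropy of each kernel, each activation map and z."""
    ke = np.array([shannon_entropy(kk.reshape(-1), normalized=True)
                   for kk in model.kernels])
    ae = np.array([shannon_entropy(aa.reshape(-1), normalized=True)
                   for aa in model.activations])
    we = shannon_entropy(np.maximum(model.z, 0), normalized=True)
    return EntropyReport(ke, ae, we)


# ---------------------------------------------------------------------------
# analysis-window sampling
# ---------------------------------------------------------------------------

def sample_analysis_windows(sig: AudioSignal, n_windows: int = 16,
                            window_seconds: float = 4.0,
                            fmin: float = 110.0, bins_per_octave: int = 24,
                            hop: int = 1024) -> Spectrogram:
    """Evenly spaced excerpts, constant-Q transformed and concatenated.

    Extracts ``n_windows`` windows of ``window_seconds`` each at evenly
    spaced offsets across the signal, transforms each and concatenates
    the frames in temporal order — the protocol used to summarise a
    long recording with a tractable spectrogram.
    """
    if n_windows < 1:
        raise ParameterError("n_windows must be >= 1")
    w = int(round(window_seconds * sig.rate))
    n = sig.samples.size
    if n < n_windows * w:
        raise InputError(
            f"signal of {n / sig.rate:.1f} s too short for {n_windows} "
            f"windows of {window_seconds} s")
    if n_windows == 1:
        starts = [0]
    else:
        starts = [int(math.floor(i * (n - w) / (n_windows - 1)))
                  for i in range(n_windows)]
    pieces = []
    freqs = None
    for s0 in starts:
        sub = AudioSignal(sig.samples[s0:s0 + w], sig.rate)
        spec = constant_q_spectrogram(sub, fmin=fmin,
                                      bins_per_octave=bins_per_octave, hop=hop)
        freqs = spec.freqs
        pieces.append((spec.values, spec.times + s0 / sig.rate))
    values = np.concatenate([p[0] for p in pieces], axis=1)
    times = np.concatenate([p[1] for p in pieces])
    return Spectrogram(values, freqs, times, scale="log")
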