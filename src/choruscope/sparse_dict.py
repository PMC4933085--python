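"""Sparse approximation of spectrogram patches.

Two routes to an overcomplete dictionary of 2D time-frequency atoms —
an analytic Gabor field and mini-batch gradient dictionary learning —
plus Orthogonal Matching Pursuit (OMP) for the sparse codes and
overlap-add reassembly of the approximated spectrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_spectra import Spectrogram
from .exceptions import InputError, ParameterError

__all__ = [
    "PatchSet", "Dictionary", "SparseCode", "SparseCodeEntry",
    "extract_patches", "gabor_atom", "gabor_dictionary",
    "learn_dictionary_minibatch", "omp", "approximate_spectrogram",
]


@dataclass
class PatchSet:
    """Equally shaped 2D patches tiled from a source spectrogram."""

    patches: np.ndarray               # (n_patches, pf, pt)
    origins: np.ndarray               # (n_patches, 2) -> (freq, time) index
    patch_shape: tuple[int, int]
    source_shape: tuple[int, int]

    def __len__(self) -> int:
        return self.patches.shape[0]

    def to_matrix(self) -> np.ndarray:
        """Flatten to (n_patches, pf*pt) for linear-algebra consumers."""
        return self.patches.reshape(len(self), -1)


@dataclass
class Dictionary:
    """A set of unit-L2-norm 2D atoms.

    ``kind`` records the provenance ("gabor" or "learned"). A dictionary
    is *overcomplete* when it holds at least as many atoms as the patch
    has cells; this is a property, not a hard requirement.
    """

    atoms: np.ndarray                 # (n_atoms, pf, pt)
    patch_shape: tuple[int, int]
    kind: str = "learned"

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 3 or self.atoms.shape[1:] != tuple(self.patch_shape):
            raise ParameterError("atoms must have shape (n_atoms, *patch_shape)")
        norms = np.linalg.norm(self.atoms.reshape(len(self), -1), axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ParameterError("every atom must have unit L2 norm")

    def __len__(self) -> int:
        return self.atoms.shape[0]

    @property
    def is_overcomplete(self) -> bool:
        return len(self) >= int(np.prod(self.patch_shape))

    def to_matrix(self) -> np.ndarray:
        """Atoms as columns of a (pf*pt, n_atoms) matrix."""
        return self.atoms.reshape(len(self), -1).T


@dataclass
class SparseCodeEntry:
    """OMP result for one patch."""

    atom_indices: np.ndarray
    coefficients: np.ndarray
    residual_norm: float


@dataclass
class SparseCode:
    """Per-patch sparse codes plus the geometry needed to reassemble."""

    entries: list
    sparsity: int
    patch_shape: tuple[int, int]
    origins: np.ndarray
    source_shape: tuple[int, int]
    residual_norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.residual_norms = np.array([e.residual_norm for e in self.entries])


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def _values_of(spec) -> np.ndarray:
    if isinstance(spec, Spectrogram):
        return spec.values
    return np.asarray(spec, dtype=np.float64)


def extract_patches(spec, patch_shape: tuple[int, int],
                    stride: tuple[int, int] | int) -> PatchSet:
    """Row-major tiling of ``spec`` into patches of ``patch_shape`` with
    the given stride; count = ((F-pf)//sf + 1) * ((T-pt)//st + 1)."""
    v = _values_of(spec)
    pf, pt = patch_shape
    if isinstance(stride, int):
        stride = (stride, stride)
    sf, st = stride
    if pf > v.shape[0] or pt > v.shape[1]:
        raise ParameterError(
            f"patch {patch_shape} larger than spectrogram {v.shape}")
    if sf < 1 or st < 1:
        raise ParameterError("stride components must be >= 1")
    f_starts = np.arange(0, v.shape[0] - pf + 1, sf)
    t_starts = np.arange(0, v.shape[1] - pt + 1, st)
    patches = np.empty((f_starts.size * t_starts.size, pf, pt))
    origins = np.empty((patches.shape[0], 2), dtype=int)
    k = 0
    for i in f_starts:
        for j in t_starts:
            patches[k] = v[i:i + pf, j:j + pt]
            origins[k] = (i, j)
            k += 1
    return PatchSet(patches, origins, (pf, pt), v.shape)


# ---------------------------------------------------------------------------
# dictionaries
# ---------------------------------------------------------------------------

def gabor_atom(patch_shape: tuple[int, int], sigma: float, theta: float,
               freq: float, phase: float = 0.0, gamma: float = 0.8,
               normalize: bool = True) -> np.ndarray:
    """A single 2D Gabor atom: a Gaussian-windowed sinusoid.

    ``freq`` is in cycles per cell along the rotated axis; ``freq = 0``
    with ``phase = 0`` degenerates to a pure 2D Gaussian.
    """
    pf, pt = patch_shape
    y, x = np.mgrid[0:pf, 0:pt].astype(np.float64)
    y -= (pf - 1) / 2.0
    x -= (pt - 1) / 2.0
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    g = np.exp(-(xr ** 2 + (gamma * yr) ** 2) / (2.0 * sigma ** 2))
    atom = g * np.cos(2.0 * np.pi * freq * xr + phase)
    if normalize:
        n = np.linalg.norm(atom)
        if n > 0:
            atom = atom / n
    return atom


def gabor_dictionary(patch_shape: tuple[int, int] = (16, 16),
                     n_orientations: int = 8, n_scales: int = 4,
                     n_phases: int = 2, n_freqs: int = 4) -> Dictionary:
    """Deterministic Gabor field dictionary over a grid of
    orientation x scale x modulation frequency x phase.

    With the defaults the grid yields 8*4*4*2 = 256 atoms — overcomplete
    for the default 16x16 patch.
    """
    if min(n_orientations, n_scales, n_phases, n_freqs) < 1:
        raise ParameterError("all grid counts must be >= 1")
    pf, pt = patch_shape
    sigmas = np.geomspace(max(min(pf, pt) / 10.0, 1.0),
                          max(min(pf, pt) / 3.0, 1.5), n_scales)
    thetas = np.arange(n_orientations) * np.pi / n_orientations
    phases = np.arange(n_phases) * (np.pi / 2.0 / max(n_phases - 1, 1))
    atoms = []
    for s in sigmas:
        freqs = np.linspace(0.5 / (2.0 * s), 1.0 / (2.0 * s), n_freqs)
        for th in thetas:
            for f in freqs:
                for ph in phases:
                    atoms.append(gabor_atom(patch_shape, s, th, f, ph))
    return Dictionary(np.array(atoms), patch_shape, kind="gabor")


def learn_dictionary_minibatch(patches: PatchSet, n_atoms: int = 64,
                               batch_size: int = 32, n_iters: int = 200,
                               step: float = 0.1, sparsity: int = 4,
                               seed: int = 0) -> Dictionary:
    """Mini-batch gradient dictionary learning.

    Alternates OMP sparse coding of a random batch with a gradient step
    on the reconstruction objective sum ||x - D a||^2, renormalising
    atoms to unit norm after every step (step size decays as 1/t).
    Deterministic for a fixed seed.
    """
    if n_atoms < 1:
        raise ParameterError("n_atoms must be >= 1")
    if len(patches) == 0:
        raise InputError("empty patch set")
    x_all = patches.to_matrix()
    if not np.any(x_all):
        raise InputError("degenerate all-zero patch set")
    rng = np.random.default_rng(seed)

    # initialise from randomly chosen patches (plus jitter for duplicates)
    idx = rng.choice(len(patches), size=n_atoms, replace=n_atoms > len(patches))
    d = x_all[idx].T + 1e-6 * rng.standard_normal((x_all.shape[1], n_atoms))
    d /= np.maximum(np.linalg.norm(d, axis=0), 1e-12)

    s = min(sparsity, n_atoms)
    for t in range(n_iters):
        batch = x_all[rng.choice(len(patches), size=min(batch_size, len(patches)),
                                 replace=False)]
        codes = np.zeros((batch.shape[0], n_atoms))
        for i, x in enumerate(batch):
            entry = _omp_vector(x, d, s, 0.0)
            codes[i, entry.atom_indices] = entry.coefficients
        resid = batch - codes @ d.T
        eta = step / (1.0 + t / 10.0)
        d += eta * (resid.T @ codes) / batch.shape[0]
        norms = np.linalg.norm(d, axis=0)
        dead = norms < 1e-10
        if np.any(dead):  # re-seed collapsed atoms from data
            repl = x_all[rng.choice(len(patches), size=int(dead.sum()))].T
            d[:, dead] = repl + 1e-6
            norms = np.linalg.norm(d, axis=0)
        d /= norms
    return Dictionary(d.T.reshape(n_atoms, *patches.patch_shape),
                      patches.patch_shape, kind="learned")


# ---------------------------------------------------------------------------
# OMP
# ---------------------------------------------------------------------------

def _omp_vector(x: np.ndarray, d: np.ndarray, s: int, tol: float,
                history: list | None = None) -> SparseCodeEntry:
    """Greedy OMP on a flattened patch; ``d`` holds atoms as columns."""
    r = x.astype(np.float64).copy()
    support: list[int] = []
    coefs = np.zeros(0)
    x_scale = max(np.linalg.norm(x), 1.0)
    while len(support) < s and np.linalg.norm(r) > tol:
        corr = d.T @ r
        j = int(np.argmax(np.abs(corr)))  # argmax ties -> lowest index
        if np.abs(corr[j]) <= 1e-12 * x_scale:
            break  # nothing correlates: stop with the residual untouched
        if j in support:
            break
        support.append(j)
        sub = d[:, support]
        coefs, *_ = np.linalg.lstsq(sub, x, rcond=None)
        r = x - sub @ coefs
        if history is not None:
            history.append((list(support), r.copy()))
    return SparseCodeEntry(np.array(support, dtype=int),
                           np.asarray(coefs, dtype=np.float64),
                           float(np.linalg.norm(r)))


def omp(patch: np.ndarray, dictionary: Dictionary, sparsity: int,
        tol: float = 0.0, return_history: bool = False):
    """Orthogonal Matching Pursuit for one patch.

    Repeatedly selects the atom with maximal |correlation| to the
    residual, refits all selected coefficients by least squares, and
    stops after ``sparsity`` atoms or when the residual norm drops to
    ``tol``. The residual is orthogonal to the span of the selected
    atoms at every step. With ``return_history=True`` also returns the
    per-step (support, residual) list.
    """
    if sparsity < 1:
        raise ParameterError("sparsity must be >= 1")
    if sparsity > len(dictionary):
        raise ParameterError("sparsity exceeds the number of atoms")
    x = np.asarray(patch, dtype=np.float64).reshape(-1)
    if x.size != int(np.prod(dictionary.patch_shape)):
        raise ParameterError("patch shape does not match the dictionary")
    hist: list | None = [] if return_history else None
    entry = _omp_vector(x, dictionary.to_matrix(), sparsity, tol, hist)
    return (entry, hist) if return_history else entry


def approximate_spectrogram(spec, dictionary: Dictionary, sparsity: int = 8,
                            stride: tuple[int, int] | int = 8,
                            tol: float = 0.0):
    """Patch-wise OMP approximation of a spectrogram.

    Patches are coded independently and reassembled by overlap-add with
    uniform averaging of overlapping contributions; negative cells are
    clipped to 0. Returns ``(SparseCode, reconstruction)`` where the
    reconstruction mirrors the input container type.
    """
    patches = extract_patches(spec, dictionary.patch_shape, stride)
    d = dictionary.to_matrix()
    entries = []
    recon = np.zeros(patches.source_shape)
    counts = np.zeros(patches.source_shape)
    pf, pt = dictionary.patch_shape
    for patch, (i, j) in zip(patches.patches, patches.origins):
        entry = _omp_vector(patch.reshape(-1), d, min(sparsity, d.shape[1]), tol)
        entries.append(entry)
        approx = (d[:, entry.atom_indices] @ entry.coefficients
                  if entry.atom_indices.size else np.zeros(pf * pt))
        recon[i:i + pf, j:j + pt] += approx.reshape(pf, pt)
        counts[i:i + pf, j:j + pt] += 1.0
    np.divide(recon, counts, out=recon, where=counts > 0)
    recon = np.clip(recon, 0.0, None)
    code = SparseCode(entries, sparsity, dictionary.patch_shape,
                      patches.origins, patches.source_shape)
    if isinstance(spec, Spectrogram):
        return code, Spectrogram(recon, spec.freqs, spec.times, spec.scale)
    return code, recon
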