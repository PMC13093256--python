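"""Shift-invariant k-means waveform dictionary learning.

Each training window of length L is approximated by a single waveform of
length P < L, shifted by tau and scaled by a non-negative alpha.  The
assignment step picks, per window, the (waveform, shift) pair with the
highest cosine similarity between the P-length sub-window ``W_tau(x)``
and the waveform; the update step replaces each waveform by the plain
average of the sub-windows assigned to it.  Iteration stops when the mean
squared centroid change per point falls below a tolerance tied to the
pooled variance of the training samples, or after ``max_iter`` rounds.

Cross-correlations over all shifts are computed either by direct dot
products (small P) or via the FFT (P >= 64); both paths agree to 1e-8
relative and are selected automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .signal import WindowBatch, extract_window

__all__ = [
    "WaveformDictionary",
    "Assignment",
    "assign_windows",
    "update_centroids",
    "fit_shift_invariant_kmeans",
    "reconstruction_objective",
    "ShiftInvariantKMeans",
]

_FFT_MIN_P = 64


@dataclass
class WaveformDictionary:
    """A learned dictionary of K waveforms of length P.

    Centroids are stored unnormalized (plain averages of aligned
    sub-windows); cosine-similarity matching makes downstream use
    scale-free.
    """

    centroids: np.ndarray
    class_label: str = ""
    fold: int | None = None
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.centroids.shape[0] < 1:
            raise ValueError("dictionary needs at least one waveform")
        norms = np.linalg.norm(self.centroids, axis=1)
        if np.any(norms == 0):
            raise ValueError("dictionary contains an all-zero waveform")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]

    @property
    def P(self) -> int:
        return self.centroids.shape[1]


@dataclass
class Assignment:
    """Best (waveform, shift) match for one window."""

    k: int
    tau: int
    similarity: float
    alpha: float


def _sliding_corr_direct(windows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Inner products <W_tau(x_i), c_k> for all i, k, tau. Shape (M, K, T)."""
    M, L = windows.shape
    K, P = centroids.shape
    T = L - P + 1
    sub = np.lib.stride_tricks.sliding_window_view(windows, P, axis=1)  # (M, T, P)
    return np.einsum("mtp,kp->mkt", sub, centroids)


def _sliding_corr_fft(windows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """FFT path for the same quantity; correlation = convolution with reversed kernel."""
    M, L = windows.shape
    K, P = centroids.shape
    T = L - P + 1
    n = sp_fft.next_fast_len(L + P - 1)
    Xf = sp_fft.rfft(windows, n, axis=1)  # (M, F)
    Cf = sp_fft.rfft(centroids[:, ::-1], n, axis=1)  # (K, F)
    out = np.empty((M, K, T))
    # chunk over windows to bound the (chunk, K, n) intermediate
    chunk = max(1, int(4e7 // (K * n)))
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        prod = Xf[lo:hi, None, :] * Cf[None, :, :]
        full = sp_fft.irfft(prod, n, axis=2)
        out[lo:hi] = full[:, :, P - 1 : P - 1 + T]
    return out


def _sliding_corr(windows: np.ndarray, centroids: np.ndarray, method: str = "auto") -> np.ndarray:
    if method == "auto":
        method = "fft" if centroids.shape[1] >= _FFT_MIN_P else "direct"
    if method == "fft":
        return _sliding_corr_fft(windows, centroids)
    if method == "direct":
        return _sliding_corr_direct(windows, centroids)
    raise ValueError(f"unknown method {method!r}")


def _window_sub_norms(windows: np.ndarray, P: int) -> np.ndarray:
    """||W_tau(x_i)||_2 for all tau; shape (M, T)."""
    sq = windows**2
    csum = np.concatenate([np.zeros((windows.shape[0], 1)), np.cumsum(sq, axis=1)], axis=1)
    T = windows.shape[1] - P + 1
    ssq = csum[:, P : P + T] - csum[:, :T]
    return np.sqrt(np.maximum(ssq, 0.0))


def _similarity_cube(windows: np.ndarray, centroids: np.ndarray, method: str = "auto") -> np.ndarray:
    """Cosine similarity sim(W_tau(x_i), c_k) for all (i, k, tau); zero-norm pairs -> 0."""
    corr = _sliding_corr(windows, centroids, method)
    c_norm = np.linalg.norm(centroids, axis=1)  # (K,)
    w_norm = _window_sub_norms(windows, centroids.shape[1])  # (M, T)
    denom = c_norm[None, :, None] * w_norm[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, corr / np.where(denom > 0, denom, 1.0), 0.0)
    return sim


def assign_indices(
    windows: np.ndarray, centroids: np.ndarray, method: str = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized argmax assignment: best (k, tau) per window, tie-break lowest k then tau."""
    sim = _similarity_cube(np.atleast_2d(windows), np.atleast_2d(centroids), method)
    M, K, T = sim.shape
    best = np.argmax(sim.reshape(M, K * T), axis=1)
    ks, taus = np.unravel_index(best, (K, T))
    return ks, taus


def assign_windows(
    batch: WindowBatch, dictionary: WaveformDictionary, method: str = "auto"
) -> list[Assignment]:
    """Assign each window to its best (waveform, shift) by cosine similarity.

    Ties are broken by lowest waveform index k, then lowest shift tau.
    ``alpha`` is the non-negative least-squares scale
    ``max(0, <W_tau(x), c_k> / ||c_k||^2)`` at the chosen pair; windows
    whose best similarity is negative keep their argmax assignment but get
    ``alpha = 0``.
    """
    windows = batch.windows
    centroids = dictionary.centroids
    if dictionary.P > batch.window_length:
        raise ValueError(
            f"waveform length P={dictionary.P} exceeds window length L={batch.window_length}"
        )
    sim = _similarity_cube(windows, centroids, method)
    M, K, T = sim.shape
    flat = sim.reshape(M, K * T)
    best = np.argmax(flat, axis=1)  # first max -> lowest k then lowest tau
    ks, taus = np.unravel_index(best, (K, T))
    c_sq = np.einsum("kp,kp->k", centroids, centroids)
    out = []
    for i in range(M):
        k, tau = int(ks[i]), int(taus[i])
        sub = windows[i, tau : tau + dictionary.P]
        alpha = max(0.0, float(sub @ centroids[k]) / c_sq[k])
        out.append(Assignment(k, tau, float(sim[i, k, tau]), alpha))
    return out


def update_centroids(
    batch: WindowBatch,
    assignments: list[Assignment],
    K: int,
    P: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Average the aligned sub-windows of each cluster into new centroids.

    Empty clusters are re-seeded from the first P samples of a uniformly
    drawn training window (seeded via ``rng``).
    """
    if len(assignments) != batch.M:
        raise ValueError("assignments must cover all windows")
    if P is None:
        P = batch.window_length
    sums = np.zeros((K, P))
    counts = np.zeros(K, dtype=int)
    for i, a in enumerate(assignments):
        sums[a.k] += batch.windows[i, a.tau : a.tau + P]
        counts[a.k] += 1
    centroids = np.empty((K, P))
    if rng is None:
        rng = np.random.default_rng(0)
    for k in range(K):
        if counts[k]:
            centroids[k] = sums[k] / counts[k]
        else:
            j = int(rng.integers(batch.M))
            centroids[k] = batch.windows[j, :P]
    return centroids


def fit_shift_invariant_kmeans(
    batch: WindowBatch,
    K: int,
    P: int,
    max_iter: int = 300,
    tol_factor: float = 1e-4,
    seed: int = 0,
    class_label: str = "",
    fold: int | None = None,
    method: str = "auto",
) -> WaveformDictionary:
    """Learn a K-waveform dictionary of length P from a window batch.

    Initialization takes the first P samples of K uniformly selected
    windows (without replacement).  Iterates assignment / collection /
    update until the mean squared centroid change per point,
    ``(1/(PK)) * sum_k ||c_k_prev - c_k||^2``, is <= ``tol_factor`` times
    the pooled variance of the training-window samples, or ``max_iter``.
    """
    if K > batch.M:
        raise ValueError(f"K={K} exceeds the number of windows M={batch.M}")
    if P >= batch.window_length:
        raise ValueError(f"P={P} must be smaller than the window length L={batch.window_length}")
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(batch.M, size=K, replace=False)
    centroids = batch.windows[init_idx, :P].copy()
    tol = tol_factor * float(np.var(batch.windows))
    n_iter = 0
    change = np.inf
    for n_iter in range(1, max_iter + 1):
        assignments = assign_windows(
            WindowBatch(batch.windows), WaveformDictionary(centroids), method
        )
        new = update_centroids(batch, assignments, K, P, rng)
        change = float(np.sum((centroids - new) ** 2)) / (P * K)
        centroids = new
        if change <= tol:
            break
    return WaveformDictionary(
        centroids,
        class_label=class_label,
        fold=fold,
        train_meta={"iterations": n_iter, "final_change": change, "seed": seed, "tol": tol},
    )


def reconstruction_objective(batch: WindowBatch, dictionary: WaveformDictionary) -> float:
    """Mean over windows of min over (alpha>=0, k, tau) of ||x - alpha*S_tau(c_k)||^2.

    Uses the closed form: per window the minimal loss is
    ``||x||^2 - max_{k,tau} max(0, <W_tau(x), c_k>)^2 / ||c_k||^2``.
    """
    corr = _sliding_corr(batch.windows, dictionary.centroids)
    c_sq = np.einsum("kp,kp->k", dictionary.centroids, dictionary.centroids)
    gain = np.maximum(corr, 0.0) ** 2 / c_sq[None, :, None]
    best_gain = gain.reshape(batch.M, -1).max(axis=1)
    x_sq = np.einsum("ml,ml->m", batch.windows, batch.windows)
    return float(np.mean(x_sq - best_gain))


class ShiftInvariantKMeans:
    """Scikit-learn-style estimator wrapping :func:`fit_shift_invariant_kmeans`.

    Parameters mirror the functional API; after :meth:`fit` the learned
    dictionary is available as ``dictionary_`` and the centroid matrix as
    ``centroids_``.
    """

    def __init__(self, K: int, P: int, max_iter: int = 300, tol_factor: float = 1e-4, seed: int = 0):
        self.K = K
        self.P = P
        self.max_iter = max_iter
        self.tol_factor = tol_factor
        self.seed = seed

    def fit(self, batch: WindowBatch | np.ndarray) -> "ShiftInvariantKMeans":
        if not isinstance(batch, WindowBatch):
            batch = WindowBatch(batch)
        self.dictionary_ = fit_shift_invariant_kmeans(
            batch, self.K, self.P, self.max_iter, self.tol_factor, self.seed
        )
        self.centroids_ = self.dictionary_.centroids
        return self

    def predict(self, batch: WindowBatch | np.ndarray) -> list[Assignment]:
        if not isinstance(batch, WindowBatch):
            batch = WindowBatch(batch)
        return assign_windows(batch, self.dictionary_)

    def score(self, batch: WindowBatch | np.ndarray) -> float:
        if not isinstance(batch, WindowBatch):
            batch = WindowBatch(batch)
        return -reconstruction_objective(batch, self.dictionary_)
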