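"""Count-based featurization of EEG segments.

Bag-of-waves (BOW) counts how often each dictionary waveform is the best
match for the non-overlapping L-length windows of a segment; counts from
the J class-conditional dictionaries are concatenated into a single
D-dimensional vector.  A TFIDF transform re-weights the counts so that
waveforms appearing in few training segments count more, then the vector
is scaled to unit Euclidean norm — which also makes the features
invariant to whether counts or rates are used.

Two baselines share the surface: bag-of-spectra (BOS), which clusters
l2-normalized window magnitude spectra with ordinary k-means, and the
soft-counted waveform (SCW) features, which slide mean-removed,
l1-normalized waveforms over every sample offset of the segment and sum
the winning inner products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from sklearn.cluster import KMeans

from .dictionary import WaveformDictionary, _sliding_corr, assign_indices
from .signal import WindowBatch, segment_to_windows

__all__ = [
    "BagOfWaves",
    "TfidfWeights",
    "FeatureVector",
    "SpectralDictionary",
    "encode_bow",
    "fit_tfidf",
    "apply_tfidf",
    "pool_bags",
    "window_spectra",
    "fit_bos",
    "encode_bos",
    "encode_scw",
]


@dataclass
class BagOfWaves:
    """Concatenated waveform counts for one segment (or a pooled set).

    ``block_index`` maps dictionary position j to its half-open coordinate
    range in the concatenated vector.
    """

    counts: np.ndarray
    block_index: list[tuple[int, int]]
    subject_id: str = ""
    start: int = 0
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def D(self) -> int:
        return len(self.counts)

    def block(self, j: int) -> np.ndarray:
        lo, hi = self.block_index[j]
        return self.counts[lo:hi]


@dataclass
class TfidfWeights:
    """Inverse-document-frequency weights estimated on training segments."""

    w: np.ndarray
    N_train: int
    N_k: np.ndarray


@dataclass
class FeatureVector:
    """A transformed feature vector; ``norm_kind`` records the convention."""

    values: np.ndarray
    norm_kind: str = "tfidf-l2"


@dataclass
class SpectralDictionary:
    """K-means centroids of l2-normalized window magnitude spectra."""

    centroids: np.ndarray
    fft_length: int

    @property
    def K(self) -> int:
        return self.centroids.shape[0]


def encode_bow(
    segment: np.ndarray,
    dicts: list[WaveformDictionary],
    subject_id: str = "",
    start: int = 0,
    rate: float | None = None,
    L: int | None = None,
    stride: int | None = None,
) -> BagOfWaves:
    """Count best-matching waveforms per dictionary over a segment.

    The segment is cut into windows of length ``L`` (default ``2 * P``),
    each window is assigned independently under every dictionary, and the
    per-dictionary count vectors are concatenated.  Windows are
    non-overlapping by default, so every dictionary block sums to the
    number of windows M; passing ``stride`` (e.g. ``L - P + 1``, which
    guarantees every shift of a waveform is examined) switches to
    overlapping windows.
    """
    Ps = {d.P for d in dicts}
    if len(Ps) != 1:
        raise ValueError(f"dictionaries must share P, got lengths {sorted(Ps)}")
    P = Ps.pop()
    if L is None:
        L = 2 * P
    if stride is None or stride == L:
        batch = segment_to_windows(segment, L)
    else:
        segment = np.asarray(segment, dtype=float).ravel()
        if len(segment) < L:
            raise ValueError("segment shorter than window length")
        starts = np.arange(0, len(segment) - L + 1, stride)
        batch = WindowBatch(
            np.lib.stride_tricks.sliding_window_view(segment, L)[starts]
        )
    counts, block_index, off = [], [], 0
    for d in dicts:
        ks, _ = assign_indices(batch.windows, d.centroids)
        counts.append(np.bincount(ks, minlength=d.K))
        block_index.append((off, off + d.K))
        off += d.K
    duration = len(segment) / rate if rate else float(len(segment))
    return BagOfWaves(
        np.concatenate(counts), block_index, subject_id=subject_id, start=start, duration_s=duration
    )


def fit_tfidf(train_bags: list[BagOfWaves]) -> TfidfWeights:
    """Estimate smooth IDF weights ``w_k = ln((1+N)/(1+N_k)) + 1``.

    ``N_k`` is the number of training segments in which feature k is
    nonzero; waveforms present in every segment get weight exactly 1.
    """
    if not train_bags:
        raise ValueError("need at least one training bag")
    Z = np.array([b.counts for b in train_bags], dtype=float)
    N_train = Z.shape[0]
    N_k = (Z > 0).sum(axis=0)
    w = np.log((1.0 + N_train) / (1.0 + N_k)) + 1.0
    return TfidfWeights(w=w, N_train=N_train, N_k=N_k)


def apply_tfidf(bag: BagOfWaves | np.ndarray, weights: TfidfWeights) -> FeatureVector:
    """Elementwise re-weighting followed by l2 normalization.

    An all-zero bag maps to the all-zero vector (with a warning) rather
    than raising.
    """
    z = bag.counts if isinstance(bag, BagOfWaves) else np.asarray(bag, dtype=float)
    if len(z) != len(weights.w):
        raise ValueError("bag length does not match weight length")
    v = weights.w * z
    norm = np.linalg.norm(v)
    if norm == 0:
        warnings.warn("all-zero bag: returning the zero feature vector", stacklevel=2)
        return FeatureVector(np.zeros_like(v))
    return FeatureVector(v / norm)


def pool_bags(bags: list[BagOfWaves]) -> BagOfWaves:
    """Sum count vectors across segments (per-individual pooling)."""
    if not bags:
        raise ValueError("nothing to pool")
    first = bags[0]
    for b in bags[1:]:
        if b.D != first.D or b.block_index != first.block_index:
            raise ValueError("bags have heterogeneous block structures")
    total = np.sum([b.counts for b in bags], axis=0)
    return BagOfWaves(
        total,
        first.block_index,
        subject_id=first.subject_id,
        start=min(b.start for b in bags),
        duration_s=sum(b.duration_s for b in bags),
    )


def window_spectra(windows: np.ndarray, fft_length: int | None = None) -> np.ndarray:
    """Per-window processed spectra: unit-l2 one-sided FFT magnitude vectors.

    Equivalent to taking the squared magnitude spectrum, normalizing it to
    sum to one, and taking the elementwise square root.
    """
    windows = np.atleast_2d(windows)
    n = fft_length or windows.shape[1]
    mag = np.abs(sp_fft.rfft(windows, n=n, axis=1))
    norm = np.linalg.norm(mag, axis=1, keepdims=True)
    return np.where(norm > 0, mag / np.where(norm > 0, norm, 1.0), 0.0)


def fit_bos(windows: WindowBatch | np.ndarray, K: int, seed: int = 0) -> SpectralDictionary:
    """Cluster processed window spectra with standard (Euclidean) k-means."""
    w = windows.windows if isinstance(windows, WindowBatch) else np.atleast_2d(windows)
    spectra = window_spectra(w)
    km = KMeans(n_clusters=K, random_state=seed, n_init=10).fit(spectra)
    return SpectralDictionary(km.cluster_centers_, fft_length=w.shape[1])


def encode_bos(
    segment: np.ndarray,
    spec_dicts: SpectralDictionary | list[SpectralDictionary],
    L: int | None = None,
    subject_id: str = "",
    start: int = 0,
    rate: float | None = None,
) -> BagOfWaves:
    """Nearest-spectral-centroid counts over the segment's windows."""
    if isinstance(spec_dicts, SpectralDictionary):
        spec_dicts = [spec_dicts]
    if L is None:
        L = spec_dicts[0].fft_length
    batch = segment_to_windows(segment, L)
    spectra = window_spectra(batch.windows, fft_length=spec_dicts[0].fft_length)
    counts, block_index, off = [], [], 0
    for d in spec_dicts:
        d2 = ((spectra[:, None, :] - d.centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        counts.append(np.bincount(labels, minlength=d.K))
        block_index.append((off, off + d.K))
        off += d.K
    duration = len(segment) / rate if rate else float(len(segment))
    return BagOfWaves(
        np.concatenate(counts), block_index, subject_id=subject_id, start=start, duration_s=duration
    )


def scw_transform(centroids: np.ndarray) -> np.ndarray:
    """Mean-removal and l1 normalization of each waveform.

    Raises
    ------
    ValueError
        If any waveform is constant (zero deviation), naming its index.
    """
    c = np.atleast_2d(np.asarray(centroids, dtype=float))
    dev = c - c.mean(axis=1, keepdims=True)
    l1 = np.abs(dev).sum(axis=1)
    bad = np.flatnonzero(l1 == 0)
    if bad.size:
        raise ValueError(f"constant waveform(s) at index {bad.tolist()}: SCW transform undefined")
    return dev / l1[:, None]


def encode_scw(segment: np.ndarray, dicts: list[WaveformDictionary]) -> np.ndarray:
    """Hydra-style soft counts with learned waveforms (no windowing).

    Per dictionary: at every sample offset tau of the segment the
    transformed waveform with the largest inner product wins, and its
    soft count accumulates that inner product.  Blocks are concatenated
    across dictionaries; the output is dense and real-valued.
    """
    segment = np.asarray(segment, dtype=float).ravel()
    out = []
    for d in dicts:
        if len(segment) < d.P:
            raise ValueError("segment shorter than waveform length")
        c_t = scw_transform(d.centroids)
        corr = _sliding_corr(segment[None, :], c_t)[0]  # (K, T)
        winners = np.argmax(corr, axis=0)  # ties -> lowest k
        winning = corr[winners, np.arange(corr.shape[1])]
        z = np.zeros(d.K)
        np.add.at(z, winners, winning)
        out.append(z)
    return np.concatenate(out)
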