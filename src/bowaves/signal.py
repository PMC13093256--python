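"""Time-series containers, window/shift operators and sampling.

The bag-of-waves pipeline works on single-channel EEG treated as a plain
1-D sample array at a known rate.  All indexing follows a 0-based,
half-open convention ``[start, start + length)``; the "first half" /
"second half" of a recording split at sample index ``floor(length / 2)``.

The two linear operators at the heart of the method are the window
operator ``W_tau`` (:func:`extract_window`), which cuts a ``P``-length
sub-window starting at sample ``tau``, and its adjoint ``S_tau``
(:func:`shift_pad`), which zero-pads a short waveform out to length ``L``
with its support starting at ``tau``.  They satisfy the adjoint identity
``<x, S_tau(y)> == <W_tau(x), y>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "WindowBatch",
    "SeizureEvent",
    "extract_window",
    "shift_pad",
    "segment_to_windows",
    "build_exclusion_mask",
    "sample_training_windows",
    "sample_segments",
]

#: padding (seconds) prepended to each seizure event when building exclusions
PRE_PAD_S = 300.0
#: padding (seconds) appended to each seizure event when building exclusions
POST_PAD_S = 3600.0


@dataclass
class SeizureEvent:
    """An electrographic seizure interval, in seconds from recording start."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"event end ({self.end}) must exceed start ({self.start})")


@dataclass
class Recording:
    """Single-channel recording with sampling rate and exclusion intervals.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples (µV), 1-D.
    rate : float
        Sampling frequency in Hz, > 0.
    subject_id : str
        Identifier of the individual the recording belongs to.
    exclusions : list of (int, int)
        Sorted, disjoint half-open sample-index intervals to avoid when
        sampling windows or segments (e.g. peri-ictal spans).
    """

    samples: np.ndarray
    rate: float
    subject_id: str = ""
    exclusions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.samples)
        prev_end = 0
        for lo, hi in self.exclusions:
            if not (0 <= lo < hi <= n):
                raise ValueError(f"exclusion [{lo}, {hi}) outside [0, {n})")
            if lo < prev_end:
                raise ValueError("exclusion intervals must be sorted and disjoint")
            prev_end = hi

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.samples) / self.rate

    @property
    def halfpoint(self) -> int:
        """Sample index separating the first and second halves."""
        return len(self.samples) // 2


@dataclass
class WindowBatch:
    """A batch of M equal-length windows with per-row provenance.

    ``source`` holds one ``(subject_id, start_index)`` pair per row.
    """

    windows: np.ndarray
    source: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.windows = np.atleast_2d(np.asarray(self.windows, dtype=float))
        if self.windows.shape[0] < 1:
            raise ValueError("a WindowBatch needs at least one window")
        if self.source is not None and len(self.source) != self.windows.shape[0]:
            raise ValueError("source must have one entry per window")

    @property
    def M(self) -> int:
        return self.windows.shape[0]

    @property
    def window_length(self) -> int:
        return self.windows.shape[1]


def extract_window(x: np.ndarray, tau: int, P: int) -> np.ndarray:
    """Window operator ``W_tau``: return ``x[tau : tau + P]``.

    Raises
    ------
    IndexError
        If ``tau`` is outside ``[0, len(x) - P]``.
    """
    x = np.asarray(x)
    if not 0 <= tau <= len(x) - P:
        raise IndexError(f"tau={tau} out of range [0, {len(x) - P}] for P={P}")
    return x[tau : tau + P]


def shift_pad(y: np.ndarray, tau: int, L: int) -> np.ndarray:
    """Adjoint shift operator ``S_tau``: place ``y`` at offset ``tau`` in zeros of length ``L``."""
    y = np.asarray(y, dtype=float)
    P = len(y)
    if P > L:
        raise ValueError(f"waveform length {P} exceeds output length {L}")
    if not 0 <= tau <= L - P:
        raise IndexError(f"tau={tau} out of range [0, {L - P}]")
    out = np.zeros(L, dtype=float)
    out[tau : tau + P] = y
    return out


def segment_to_windows(segment: np.ndarray, L: int, subject_id: str = "", start: int = 0) -> WindowBatch:
    """Split a segment into non-overlapping L-length windows.

    The trailing remainder (``len(segment) mod L`` samples) is discarded,
    i.e. the segment length is truncated to a multiple of the window
    length, yielding ``M = floor(len(segment)/L)`` windows.
    """
    segment = np.asarray(segment, dtype=float).ravel()
    M = len(segment) // L
    if M < 1:
        raise ValueError(f"segment of {len(segment)} samples is shorter than window length {L}")
    windows = segment[: M * L].reshape(M, L)
    source = [(subject_id, start + i * L) for i in range(M)]
    return WindowBatch(windows, source)


def build_exclusion_mask(
    events: list[SeizureEvent],
    record_duration: float,
    pre_pad: float = PRE_PAD_S,
    post_pad: float = POST_PAD_S,
) -> list[tuple[float, float]]:
    """Expand seizure events into peri-ictal exclusion intervals and merge.

    Each event contributes ``[start - pre_pad, end + post_pad]`` (default:
    5 min before, 60 min after), clipped to ``[0, record_duration]``;
    overlapping or touching expanded intervals are merged.  Returns sorted,
    disjoint ``(start_s, end_s)`` tuples.
    """
    if not events:
        return []
    expanded = sorted(
        (max(0.0, e.start - pre_pad), min(record_duration, e.end + post_pad)) for e in events
    )
    merged = [list(expanded[0])]
    for lo, hi in expanded[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _admissible_starts(rec: Recording, length: int, half: str) -> tuple[int, int]:
    """Start-index range [lo, hi] for a draw of `length` samples in the given half."""
    if half == "first":
        lo, hi = 0, rec.halfpoint - length
    elif half == "second":
        lo, hi = rec.halfpoint, len(rec) - length
    else:
        raise ValueError(f"half must be 'first' or 'second', got {half!r}")
    return lo, hi


def _intersects_exclusion(rec: Recording, start: int, length: int) -> bool:
    end = start + length
    for lo, hi in rec.exclusions:
        if start < hi and lo < end:
            return True
    return False


def _draw_starts(
    rec: Recording, n: int, length: int, half: str, rng: np.random.Generator, max_attempts: int = 10_000
) -> list[int]:
    """Uniform start draws avoiding exclusions; reject-and-redraw per draw."""
    lo, hi = _admissible_starts(rec, length, half)
    if hi < lo:
        raise ValueError(
            f"subject {rec.subject_id!r}: {half} half too short for draws of {length} samples"
        )
    starts = []
    for _ in range(n):
        for attempt in range(max_attempts):
            s = int(rng.integers(lo, hi + 1))
            if not _intersects_exclusion(rec, s, length):
                starts.append(s)
                break
        else:
            raise RuntimeError(
                f"subject {rec.subject_id!r}: no admissible start found in "
                f"{max_attempts} attempts (exclusions too dense)"
            )
    return starts


def sample_training_windows(
    recordings: list[Recording],
    total: int,
    L: int,
    half: str = "first",
    seed: int | np.random.Generator = 0,
) -> WindowBatch:
    """Draw ~``total`` windows of length ``L``, balanced across subjects.

    The quota is split as evenly as possible: with ``r = total mod
    n_subjects``, the first ``r`` subjects contribute ``floor(total/n)+1``
    windows and the rest ``floor(total/n)``, so the grand total is exactly
    ``total`` and every subject contributes at least ``floor(total/n)``.
    Starts are drawn uniformly from the designated half of each recording,
    never intersecting an exclusion interval.  Deterministic given ``seed``.
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_sub = len(recordings)
    base, extra = divmod(total, n_sub)
    windows, source = [], []
    for i, rec in enumerate(recordings):
        take = base + (1 if i < extra else 0)
        starts = _draw_starts(rec, take, L, half, rng)
        for s in starts:
            windows.append(rec.samples[s : s + L])
            source.append((rec.subject_id, s))
    return WindowBatch(np.array(windows), source)


def sample_segments(
    recordings: list[Recording],
    n_segments: int,
    seg_len: float,
    half: str = "second",
    seed: int | np.random.Generator = 0,
) -> list[tuple[Recording, int, np.ndarray]]:
    """Draw ``n_segments`` segments of ``seg_len`` seconds, equal per subject.

    Segments are drawn uniformly (possibly overlapping each other) from the
    designated half of each recording, avoiding exclusions.  Returns
    ``(recording, start_index, samples)`` triples.

    Raises
    ------
    ValueError
        If ``n_segments`` is not divisible by the subject count.
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    n_sub = len(recordings)
    if n_segments % n_sub:
        raise ValueError(f"{n_segments} segments not divisible across {n_sub} subjects")
    per = n_segments // n_sub
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for rec in recordings:
        length = int(round(seg_len * rec.rate))
        for s in _draw_starts(rec, per, length, half, rng):
            out.append((rec, s, rec.samples[s : s + length]))
    return out
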