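"""Synthetic EEG cohorts with planted waveforms.

The generator realizes exactly the generative model the bag-of-waves
analysis assumes: sparse, non-overlapping occurrences of short canonical
waveforms — Hann-windowed sinusoid "rhythms" and Gabor/biphasic
"transients" — placed at Poisson event times, scaled by log-normal
amplitude draws, in additive Gaussian (optionally 1/f-shaped) noise.
Class structure comes from class-specific occurrence-rate vectors over a
shared waveform bank, mirroring the idea that genotypes differ in how
often characteristic waveforms occur rather than in what they look like.

Ground-truth event lists are returned so that recovery of planted
waveforms and assignments can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dictionary import _sliding_corr
from .signal import Recording

__all__ = [
    "WaveformBank",
    "CohortSpec",
    "make_waveform_bank",
    "simulate_recording",
    "simulate_cohort",
]


@dataclass
class PlantedEvent:
    """Ground truth for one planted waveform occurrence."""

    waveform: int
    start: int
    amplitude: float


@dataclass
class WaveformBank:
    """Unit-norm canonical waveform shapes with family tags."""

    waveforms: np.ndarray  # (n, P)
    families: list[str]  # "rhythm" or "transient"
    peak_freqs: list[float | None]
    rate_hz: float

    @property
    def n(self) -> int:
        return self.waveforms.shape[0]

    @property
    def P(self) -> int:
        return self.waveforms.shape[1]


@dataclass
class CohortSpec:
    """Generation parameters for a multi-subject synthetic cohort.

    ``class_rates`` maps each (strain, tsc) genotype to a per-waveform
    occurrence-rate vector in events/minute.  ``subjects_per_class`` may
    be a single count or a per-genotype mapping (to mirror unbalanced
    panels).  Defaults are desk-scale: 12 subjects in 2 genotypes, 2 h
    per subject at 256 Hz.
    """

    class_rates: dict[tuple[str, str], np.ndarray]
    subjects_per_class: int | dict[tuple[str, str], int] = 6
    duration_s: float = 7200.0
    rate_hz: float = 256.0
    P: int = 256
    amp_mu: float = 0.0
    amp_sigma: float = 0.25
    noise_sd: float = 1.0
    one_over_f: float = 0.0
    seed: int = 0
    sexes: tuple[str, ...] = ("F", "M")
    extra: dict = field(default_factory=dict)


def _max_shift_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Max |cosine| between a and b over all relative shifts (zero-padded)."""
    P = len(a)
    pad = np.zeros(3 * P - 2)
    pad[P - 1 : 2 * P - 1] = a
    corr = _sliding_corr(pad[None, :], b[None, :])[0, 0]
    # norms of the overlapping parts of `a` for each lag
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(np.max(np.abs(corr)) / denom) if denom else 0.0


def make_waveform_bank(
    n_transient: int,
    n_rhythm: int,
    P: int = 256,
    rate: float = 256.0,
    freq_range: tuple[float, float] = (4.0, 10.0),
    seed: int = 0,
    max_pairwise_cos: float = 0.8,
    max_draws: int = 1000,
) -> WaveformBank:
    """Draw a separable bank of unit-norm transients and rhythms.

    Rhythms are Hann-windowed sinusoids at frequencies drawn from
    ``freq_range``; transients are Gabor atoms (short Gaussian-windowed
    oscillations) or biphasic spikes, compactly supported in the middle
    of the P-sample frame.  The bank is redrawn until every pair has
    shift-maximal |cosine| <= ``max_pairwise_cos``.
    """
    lo, hi = freq_range
    if not (1.0 < lo < hi < rate / 2):
        raise ValueError(f"freq_range {freq_range} must lie within (1, rate/2)")
    rng = np.random.default_rng(seed)
    t = np.arange(P) / rate

    def _draw_rhythm():
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        w = np.hanning(P) * np.sin(2 * np.pi * f * t + phase)
        return w / np.linalg.norm(w), f

    def _draw_transient():
        if rng.random() < 0.5:  # Gabor atom
            f = rng.uniform(lo, hi)
            center = rng.uniform(0.35, 0.65) * P / rate
            width = rng.uniform(0.02, 0.06)
            w = np.exp(-0.5 * ((t - center) / width) ** 2) * np.sin(2 * np.pi * f * (t - center))
            return w / np.linalg.norm(w), f
        # biphasic spike: derivative-of-Gaussian
        center = rng.uniform(0.35, 0.65) * P / rate
        width = rng.uniform(0.004, 0.02)
        w = -(t - center) / width * np.exp(-0.5 * ((t - center) / width) ** 2)
        return w / np.linalg.norm(w), None

    for _ in range(max_draws):
        waves, families, peaks = [], [], []
        for _ in range(n_rhythm):
            w, f = _draw_rhythm()
            waves.append(w)
            families.append("rhythm")
            peaks.append(f)
        for _ in range(n_transient):
            w, f = _draw_transient()
            waves.append(w)
            families.append("transient")
            peaks.append(f)
        W = np.array(waves)
        ok = all(
            _max_shift_cosine(W[i], W[j]) <= max_pairwise_cos
            for i in range(len(W))
            for j in range(i + 1, len(W))
        )
        if ok:
            return WaveformBank(W, families, peaks, rate)
    raise RuntimeError(f"no separable bank found in {max_draws} draws; relax the frequency range")


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    from scipy import fft as sp_fft

    f = sp_fft.rfftfreq(n)
    shaping = np.where(f > 0, f ** (-exponent / 2.0), 0.0)
    shaped = sp_fft.irfft(sp_fft.rfft(white) * shaping, n)
    return shaped / shaped.std()


def simulate_recording(
    bank: WaveformBank,
    rates_per_min: np.ndarray,
    duration_s: float,
    rate_hz: float = 256.0,
    amp_mu: float = 0.0,
    amp_sigma: float = 0.25,
    noise_sd: float = 1.0,
    one_over_f: float = 0.0,
    subject_id: str = "",
    seed: int | np.random.Generator = 0,
    max_place_attempts: int = 50,
) -> tuple[Recording, list[PlantedEvent]]:
    """Poisson-planted waveform occurrences in additive noise.

    Event counts per waveform are Poisson(rate * duration); events are
    placed uniformly without overlapping another event's support, scaled
    by ``exp(N(amp_mu, amp_sigma))``, and summed with Gaussian noise of
    standard deviation ``noise_sd`` (optionally 1/f-shaped).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    P = bank.P
    rates = np.asarray(rates_per_min, dtype=float)
    if len(rates) != bank.n:
        raise ValueError("one rate per bank waveform required")
    x = np.zeros(n)
    occupied = np.zeros(n, dtype=bool)
    events: list[PlantedEvent] = []
    counts = rng.poisson(rates * duration_s / 60.0)
    if counts.sum() * P > 0.8 * n:
        raise ValueError(
            "event density too high to place without overlap; lower the rates or durations"
        )
    order = np.repeat(np.arange(bank.n), counts)
    rng.shuffle(order)
    for k in order:
        for _ in range(max_place_attempts):
            start = int(rng.integers(0, n - P + 1))
            if not occupied[start : start + P].any():
                break
        else:
            continue  # skip unplaceable event rather than fail mid-way
        amp = float(np.exp(rng.normal(amp_mu, amp_sigma)))
        x[start : start + P] += amp * bank.waveforms[k]
        occupied[start : start + P] = True
        events.append(PlantedEvent(int(k), start, amp))
    if noise_sd > 0:
        x = x + noise_sd * _one_over_f_noise(n, one_over_f, rng)
    events.sort(key=lambda e: e.start)
    return Recording(x, rate_hz, subject_id=subject_id), events


def simulate_cohort(spec: CohortSpec):
    """Generate a cohort of recordings with genotype-specific rate vectors.

    Subjects get alternating sexes; folds are assigned by shuffling each
    genotype's subjects and alternating, which keeps both folds populated
    in every genotype (mirroring the near-balance of the published fold
    table).  Returns ``(recordings, cohort_table, bank, events)`` where
    ``recordings`` maps subject id to :class:`Recording` and ``events``
    maps subject id to its ground-truth planted events.
    """
    from .classify import CohortTable

    rng = np.random.default_rng(spec.seed)
    n_waves = len(next(iter(spec.class_rates.values())))
    bank = spec.extra.get("bank") or make_waveform_bank(
        n_transient=max(1, n_waves // 2),
        n_rhythm=n_waves - max(1, n_waves // 2),
        P=spec.P,
        rate=spec.rate_hz,
        seed=spec.seed,
    )
    if bank.n != n_waves:
        raise ValueError("rate vectors must have one entry per bank waveform")
    rows, recordings, events = [], {}, {}
    i = 0
    for (strain, tsc), rates in spec.class_rates.items():
        n_sub = (
            spec.subjects_per_class[(strain, tsc)]
            if isinstance(spec.subjects_per_class, dict)
            else spec.subjects_per_class
        )
        fold_order = rng.permutation(n_sub) % 2
        for j in range(n_sub):
            sid = f"s{i:02d}"
            rec, evs = simulate_recording(
                bank,
                rates,
                spec.duration_s,
                spec.rate_hz,
                spec.amp_mu,
                spec.amp_sigma,
                spec.noise_sd,
                spec.one_over_f,
                subject_id=sid,
                seed=rng,
            )
            recordings[sid] = rec
            events[sid] = evs
            rows.append(
                {
                    "subject_id": sid,
                    "strain": strain,
                    "tsc": tsc,
                    "sex": spec.sexes[j % len(spec.sexes)],
                    "fold": int(fold_order[j]),
                }
            )
            i += 1
    table = pd.DataFrame(rows)
    return recordings, CohortTable(table), bank, events
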