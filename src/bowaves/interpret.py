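"""Waveform interpretation: linear-model Shapley values, ACSSV, spectra,
and occurrence rates.

For a linear score with independent features the Shapley value of
feature k for class y is just ``beta_k * (x_k - E[X_k])``, with the
expectation estimated from the model's training features.  The average
class-signed Shapley value (ACSSV) summarizes the per-subject Shapley
values across a fold's leave-one-out models: Shapley values of subjects
in the class enter with sign +1 and the rest with -1, so the ACSSV is
the covariance between a feature's Shapley value and the signed class
indicator.  Waveforms with high ACSSV and a positive average coefficient
occur more (or more discriminatively) in the class and form the
interpretable report, alongside each waveform's Welch spectrum and its
occurrence rates inside/outside the class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .classify import ClassifierModel, LOOResult, pooled_feature
from .features import BagOfWaves

__all__ = [
    "SpectrumEstimate",
    "shapley_linear",
    "acssv",
    "waveform_spectrum",
    "occurrence_rates",
    "top_waveform_report",
]


@dataclass
class SpectrumEstimate:
    """Welch power-spectral-density estimate of a single waveform."""

    freqs: np.ndarray
    psd: np.ndarray
    peak_freq: float | None


def shapley_linear(
    model: ClassifierModel, feature_vec: np.ndarray, feature_means: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Per-class Shapley values ``phi_k = beta_k * (x_k - mean_k)``.

    The additivity identity ``score(x) = phi_0 + sum_k phi_k`` with
    ``phi_0 = beta_0 + <beta, mean>`` holds exactly for each class's
    linear score.
    """
    x = np.asarray(feature_vec, dtype=float)
    means = model.feature_means if feature_means is None else np.asarray(feature_means, dtype=float)
    if means is None or len(means) != len(x):
        raise ValueError("feature means missing or wrong length")
    out = {}
    for y in model.classes:
        _, beta = model.class_coefficients(y)
        out[y] = beta * (x - means)
    return out


def acssv(
    result: LOOResult,
    bags_by_subject: dict,
    klass: str,
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Average class-signed Shapley values across a fold's LOO models.

    Each tested subject s is scored by its own model (trained with s held
    out).  Its Shapley vector for class ``klass`` uses the mean of the
    *pooled, transformed* per-subject features of that model's training
    subjects (all of ``subjects`` except s), and enters the average with
    sign +1 when the subject belongs to the class and -1 otherwise.
    Conditioning on a strain is implicit: run on a
    ``tsc_given_strain:<s>`` task's result with ``subjects`` restricted
    to that strain.

    Returns a DataFrame with per-feature columns ``acssv`` and
    ``mean_coefficient``.
    """
    if not result.models:
        raise ValueError("LOOResult carries no models; rerun with keep_models=True")
    if subjects is None:
        subjects = list(bags_by_subject)
    sigma = None
    mean_coef = None
    n = 0
    for _, row in result.records.iterrows():
        s = row["subject_id"]
        model = result.models[s]
        train = [t for t in subjects if t != s]
        means = np.mean([pooled_feature(model, bags_by_subject[t]) for t in train], axis=0)
        x = pooled_feature(model, bags_by_subject[s])
        phi = shapley_linear(model, x, feature_means=means)[klass]
        sign = 1.0 if row["true"] == klass else -1.0
        _, beta = model.class_coefficients(klass)
        sigma = sign * phi if sigma is None else sigma + sign * phi
        mean_coef = beta.copy() if mean_coef is None else mean_coef + beta
        n += 1
    return pd.DataFrame(
        {
            "feature": np.arange(len(sigma)),
            "acssv": sigma / n,
            "mean_coefficient": mean_coef / n,
        }
    )


def waveform_spectrum(
    waveform: np.ndarray,
    rate: float = 256.0,
    nfft: int = 1024,
    highpass_hz: float = 1.0,
) -> SpectrumEstimate:
    """Welch PSD of a short waveform from two long, heavily overlapping tapers.

    For a P-sample waveform the segment length is ``round(0.95 * P)`` and
    the overlap ``round(0.90 * P)`` (for P = 256: length 243, stride 13,
    i.e. exactly two segments at offsets 0 and 13), Hann-tapered and
    zero-padded to ``nfft``.  The peak frequency is the argmax over bins
    at or above the acquisition high-pass cutoff; a constant waveform has
    a flat zero spectrum and ``peak_freq=None``.
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    P = len(waveform)
    nperseg = int(round(0.95 * P))
    noverlap = int(round(0.90 * P))
    freqs, psd = sp_signal.welch(
        waveform, fs=rate, window="hann", nperseg=nperseg, noverlap=noverlap, nfft=nfft
    )
    if np.allclose(psd, 0.0):
        return SpectrumEstimate(freqs, psd, None)
    valid = freqs >= highpass_hz
    peak = float(freqs[valid][np.argmax(psd[valid])])
    return SpectrumEstimate(freqs, psd, peak)


def occurrence_rates(
    bags: list[BagOfWaves], labels: list[str], klass: str
) -> pd.DataFrame:
    """Per-waveform counts/minute inside the class, outside it, and overall.

    Segment durations are taken from each bag's metadata (seconds).
    """
    durations = np.array([b.duration_s for b in bags], dtype=float)
    if np.any(durations <= 0):
        raise ValueError("all bags need positive durations for rate computation")
    Z = np.array([b.counts for b in bags], dtype=float)
    in_mask = np.array([lab == klass for lab in labels])
    minutes = durations / 60.0

    def _rate(mask):
        if not mask.any():
            return np.zeros(Z.shape[1])
        return Z[mask].sum(axis=0) / minutes[mask].sum()

    return pd.DataFrame(
        {
            "rate_in": _rate(in_mask),
            "rate_out": _rate(~in_mask),
            "rate_all": Z.sum(axis=0) / minutes.sum(),
        }
    )


def top_waveform_report(
    acssv_table: pd.DataFrame,
    n_top: int = 5,
    dicts=None,
    rates: pd.DataFrame | None = None,
    rate_hz: float = 256.0,
) -> pd.DataFrame:
    """Rank positive-coefficient features by descending ACSSV.

    Attaches the waveform's dictionary of origin, peak frequency (when
    dictionaries are supplied), rates, and the sign of the ACSSV (whether
    the feature's Shapley values correlate positively or negatively with
    the class).  All-negative coefficient tables yield an empty report.
    """
    table = acssv_table[acssv_table["mean_coefficient"] > 0].copy()
    table = table.sort_values("acssv", ascending=False).head(n_top)
    table["correlation_sign"] = np.where(table["acssv"] >= 0, "positive", "negative")
    if rates is not None:
        table = table.join(rates, on="feature")
    if dicts is not None:
        offsets, labels = [], []
        off = 0
        for d in dicts:
            offsets.append((off, off + d.K, d))
            off += d.K
        dict_label, wave_idx, peak = [], [], []
        for f in table["feature"]:
            for lo, hi, d in offsets:
                if lo <= f < hi:
                    dict_label.append(d.class_label)
                    wave_idx.append(int(f - lo))
                    peak.append(waveform_spectrum(d.centroids[f - lo], rate=rate_hz).peak_freq)
                    break
        table["dictionary"] = dict_label
        table["waveform"] = wave_idx
        table["peak_hz"] = peak
    return table.reset_index(drop=True)
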