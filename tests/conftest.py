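"""Shared fixtures: small random batches and a desk-scale synthetic cohort.

The cohort fixtures are session-scoped because simulation and encoding
dominate the suite's runtime; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from bowaves.synthetic import CohortSpec, make_waveform_bank, simulate_cohort

# Frozen desk-scale study conditions: 12 subjects, 2 genotypes, 2 h at 64 Hz,
# 1 s waveforms in 2 s windows, event SNR 5 (unit-norm events of per-sample
# RMS 1/8 over noise sd 0.025 after typical log-normal scaling).
DESK = dict(
    rate_hz=64.0,
    P=64,
    L=128,
    K=8,
    duration_s=7200.0,
    noise_sd=0.025,
    seg_len_s=300.0,
    segments_per_dict=144,
    windows_per_dict=1500,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_bank():
    return make_waveform_bank(
        n_transient=2, n_rhythm=2, P=DESK["P"], rate=DESK["rate_hz"],
        freq_range=(4.0, 10.0), seed=3, max_pairwise_cos=0.6,
    )


def _make_cohort(bank, rates_het, rates_wt, seed):
    spec = CohortSpec(
        class_rates={("A", "Het"): np.asarray(rates_het), ("A", "WT"): np.asarray(rates_wt)},
        subjects_per_class=6,
        duration_s=DESK["duration_s"],
        rate_hz=DESK["rate_hz"],
        P=DESK["P"],
        noise_sd=DESK["noise_sd"],
        seed=seed,
        extra={"bank": bank},
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def separated_cohort(desk_bank):
    """Two genotypes with opposite signature waveforms (rhythm up in one,
    transient up in the other, 2.0 vs 0.2 events/min)."""
    return _make_cohort(desk_bank, [2.0, 2.0, 2.0, 0.2], [0.2, 2.0, 2.0, 2.0], seed=7)


@pytest.fixture(scope="session")
def null_cohort(desk_bank):
    """Two genotypes with identical rate vectors: no class signal."""
    return _make_cohort(desk_bank, [2.0, 2.0, 2.0, 2.0], [2.0, 2.0, 2.0, 2.0], seed=8)
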