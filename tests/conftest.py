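import numpy as np
import pytest

from spinecpg import neural, semg, synthetic as syn


@pytest.fixture(scope="session")
def recovery_run():
    """One long low-noise bilateral recording shared by the pipeline
    recovery tests: known switching probability, strong transients."""
    params = syn.CPGSimParams(seed=202, switch_prob=0.8, event_rate=0.4,
                              duration=600.0, noise_sd=0.5)
    traces, truth = syn.simulate_bilateral_traces(params)
    summary = neural.summarize_activity(traces)
    return params, traces, truth, summary


@pytest.fixture(scope="session")
def semg_injection():
    """Preprocessed sEMG with a known injected ECG component.

    Returns (contaminated, injected_component, fs); the injected component
    is isolated by regenerating the same seed with the EMG noise turned off
    (preprocessing is linear, so components add).
    """
    fs = 2000.0
    rec = syn.simulate_semg(seed=7, duration_s=5.0)
    pp = semg.preprocess(rec)
    ecg_only = syn.simulate_semg(seed=7, duration_s=5.0,
                                 emg_sd=1e-12, ref_emg_sd=1e-12)
    inj = semg.preprocess(ecg_only)
    return pp, inj, fs


def brute_force_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exhaustive enumeration of all 2x2 tables with the
    observed margins; two-sided p sums hypergeometric probabilities of
    tables no more probable than the observed one."""
    from math import comb

    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


def brute_force_hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Independent oracle: P(X >= k) for X ~ Hypergeom(N, K, n) by direct
    combinatorial summation."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom
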