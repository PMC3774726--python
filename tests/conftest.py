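import numpy as np
import pytest

from qrsdet.synth import SyntheticSpec, generate


@pytest.fixture(scope="session")
def clean_synth():
    """30 s noise-free synthetic ECG at 60 bpm, fs=360 Hz (30 beats)."""
    return generate(SyntheticSpec(fs=360, duration_s=30, heart_rate_bpm=60, seed=11))


@pytest.fixture(scope="session")
def noisy_synth():
    """Synthetic record with mild mains + muscle noise for invariance tests."""
    return generate(
        SyntheticSpec(
            fs=360, duration_s=30, heart_rate_bpm=75,
            mains_60hz_amp=0.1, muscle_noise_sd=0.05, seed=12,
        )
    )


# ---- independent brute-force oracles -------------------------------------

def moving_average_oracle(x, window):
    """O(N*W) explicit-sum centered moving average with shrinking edges."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - window // 2)
        hi = min(n, i - window // 2 + window)
        total = 0.0
        for j in range(lo, hi):
            total += x[j]
        out[i] = total / (hi - lo)
    return out


def blocks_oracle(ma_qrs, ma_beat, offset):
    """Per-sample boolean scan returning (onset, end) runs."""
    runs = []
    start = None
    for i, (a, b) in enumerate(zip(ma_qrs, ma_beat)):
        if a > b + offset:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(ma_qrs)))
    return runs


def argmax_abs_oracle(signal, onset, end):
    """Explicit per-block scan for the earliest maximum of |signal|."""
    best_i, best_v = onset, abs(signal[onset])
    for i in range(onset + 1, end):
        if abs(signal[i]) > best_v:
            best_i, best_v = i, abs(signal[i])
    return best_i
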