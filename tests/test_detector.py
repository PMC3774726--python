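"""Core detector: conversions, moving averages, blocks, peaks, invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import argmax_abs_oracle, blocks_oracle, moving_average_oracle
from qrsdet.detector import (
    BlockOfInterest,
    DetectorParams,
    MovingAverages,
    compute_moving_averages,
    compute_offset,
    detect,
    duration_to_samples,
    generate_blocks,
    locate_r_peaks,
    moving_average,
    threshold_blocks,
)
from qrsdet.evaluation import evaluate
from qrsdet.records import ECGRecord
from qrsdet.synth import SyntheticSpec, generate


# ---- duration_to_samples --------------------------------------------------

@pytest.mark.parametrize(
    "ms,fs,expected",
    [
        (97, 360, 35),     # optimized QRS-scale window
        (611, 360, 220),   # optimized beat-scale window
        (1000, 360, 360),  # average heartbeat duration
        (120, 360, 43),    # QRS upper normal limit (100 + 20 ms)
        (80, 360, 29),     # QRS lower normal limit (100 - 20 ms)
        (110, 360, 40),    # P width
    ],
)
def test_duration_conversion_knowledge_base(ms, fs, expected):
    assert duration_to_samples(ms, fs, "nearest") == expected


def test_duration_conversion_odd_mode_and_floor():
    assert duration_to_samples(611, 360, "odd") == 221  # even bumped up
    assert duration_to_samples(97, 360, "odd") == 35    # already odd
    assert duration_to_samples(1, 360) == 1             # floor of 1
    with pytest.raises(ValueError):
        duration_to_samples(-5, 360)
    with pytest.raises(ValueError):
        duration_to_samples(97, 0)
    with pytest.raises(ValueError):
        duration_to_samples(97, 360, "up")


# ---- moving_average -------------------------------------------------------

def test_moving_average_constant_and_impulse():
    assert np.allclose(moving_average(np.full(50, 3.25), 7), 3.25)
    assert np.allclose(moving_average(np.full(50, 3.25), 8), 3.25)
    x = np.zeros(101)
    x[50] = 1.0
    out = moving_average(x, 5)
    np.testing.assert_allclose(out[48:53], 0.2)
    assert np.all(out[:48] == 0) and np.all(out[53:] == 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(10, 200),
    window=st.integers(1, 60),
)
def test_moving_average_matches_explicit_sum_oracle(seed, n, window):
    if window > n:
        window = n
    x = np.random.default_rng(seed).normal(size=n)
    np.testing.assert_allclose(
        moving_average(x, window), moving_average_oracle(x, window), atol=1e-10
    )


def test_moving_average_window_validation():
    with pytest.raises(ValueError):
        moving_average(np.zeros(5), 6)
    with pytest.raises(ValueError):
        moving_average(np.zeros(5), 0)


# ---- offset ---------------------------------------------------------------

def test_compute_offset():
    assert compute_offset(7.7, 0.0) == 0.0
    assert compute_offset(2.5, 0.08) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        compute_offset(1.0, 1.5)


# ---- block generation and thresholding ------------------------------------

def test_generate_blocks_simple_cases():
    n = 300
    ma_beat = np.full(n, 0.3)
    ma_qrs = np.zeros(n)
    ma = MovingAverages(ma_qrs, ma_beat, 5, 50)
    assert generate_blocks(ma, 0.0) == []

    ma_qrs2 = np.zeros(n)
    ma_qrs2[100:140] = 1.0
    ma2 = MovingAverages(ma_qrs2, ma_beat, 5, 50)
    blocks = generate_blocks(ma2, 0.0)
    assert len(blocks) == 1
    assert (blocks[0].onset, blocks[0].end, blocks[0].width) == (100, 140, 40)
    assert not blocks[0].accepted


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_generate_blocks_matches_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(5, 300)
    ma_qrs = rng.normal(size=n)
    ma_beat = rng.normal(size=n) * 0.5
    offset = float(rng.uniform(0, 0.5))
    blocks = generate_blocks(MovingAverages(ma_qrs, ma_beat, 3, 10), offset)
    assert [(b.onset, b.end) for b in blocks] == blocks_oracle(ma_qrs, ma_beat, offset)


def test_threshold_blocks_boundary_is_inclusive():
    w1 = 35
    blocks = [
        BlockOfInterest(0, w1 - 1),     # width w1-1 -> rejected
        BlockOfInterest(100, 100 + w1), # width w1 -> accepted (>= rule)
        BlockOfInterest(300, 310),
        BlockOfInterest(400, 600),
    ]
    out = threshold_blocks(blocks, w1)
    assert [b.accepted for b in out] == [False, True, False, True]
    # rejected blocks retained for diagnostics
    assert len(out) == len(blocks)


def test_threshold_widths_example():
    widths = [10, 35, 200]
    blocks = [BlockOfInterest(i * 1000, i * 1000 + w) for i, w in enumerate(widths)]
    out = threshold_blocks(blocks, 35)
    assert [b.accepted for b in out] == [False, True, True]


# ---- R-peak localization --------------------------------------------------

def test_locate_r_peaks_unique_max_and_absolute_value():
    sig = np.zeros(30)
    sig[13] = 2.0
    blocks = [BlockOfInterest(10, 20, accepted=True)]
    assert list(locate_r_peaks(blocks, sig)) == [13]

    sig2 = np.zeros(30)
    sig2[12] = -5.0
    sig2[15] = 4.0
    assert list(locate_r_peaks(blocks, sig2)) == [12]  # |-5| > |4|


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_locate_r_peaks_matches_argmax_oracle(seed):
    rng = np.random.default_rng(seed)
    sig = rng.normal(size=500)
    blocks = []
    pos = 0
    while pos < 450:
        w = int(rng.integers(1, 40))
        blocks.append(BlockOfInterest(pos, pos + w, accepted=True))
        pos += w + int(rng.integers(1, 30))
    expected = [argmax_abs_oracle(sig, b.onset, b.end) for b in blocks]
    assert list(locate_r_peaks(blocks, sig)) == expected


def test_locate_r_peaks_rejects_out_of_range_block():
    with pytest.raises(ValueError):
        locate_r_peaks([BlockOfInterest(5, 100, accepted=True)], np.zeros(50))


# ---- end-to-end detect ----------------------------------------------------

def test_detect_clean_synthetic_exact_count_and_timing(clean_synth):
    res = detect(clean_synth.record)
    assert len(res.r_peaks) == 30
    err_ms = np.abs(res.r_peaks - clean_synth.true_r_peaks) / 360.0 * 1000.0
    assert np.max(err_ms) <= 10.0


def test_detect_scale_invariance(noisy_synth):
    base = detect(noisy_synth.record).r_peaks
    for c in (10.0, 0.01):
        np.testing.assert_array_equal(base, detect(noisy_synth.record.scaled(c)).r_peaks)


def test_detect_dc_invariance(noisy_synth):
    base = detect(noisy_synth.record).r_peaks
    shifted = ECGRecord(noisy_synth.record.samples + 3.7, noisy_synth.record.fs)
    np.testing.assert_array_equal(base, detect(shifted).r_peaks)


def test_detect_cross_rate_consistency():
    r_times = {}
    for fs in (250.0, 500.0):
        s = generate(SyntheticSpec(fs=fs, duration_s=30, heart_rate_bpm=70, seed=21))
        r_times[fs] = detect(s.record).r_peaks / fs
    assert len(r_times[250.0]) == len(r_times[500.0])
    assert np.max(np.abs(r_times[250.0] - r_times[500.0])) <= 0.005


def test_detect_structural_invariants(noisy_synth):
    res = detect(noisy_synth.record)
    w1 = duration_to_samples(res.params.w1_ms, res.fs)
    accepted = res.accepted_blocks
    assert len(accepted) == len(res.r_peaks)
    assert np.all(np.diff(res.r_peaks) > 0)
    for peak, block in zip(res.r_peaks, accepted):
        assert block.width >= w1
        assert block.onset <= peak < block.end


def test_detect_beta_monotone_block_coverage(noisy_synth):
    """Raising the offset fraction can only shrink the above-threshold set."""
    from qrsdet.preprocess import preprocess

    params = DetectorParams()
    pre = preprocess(noisy_synth.record, params)
    ma = compute_moving_averages(
        pre.squared,
        duration_to_samples(params.w1_ms, pre.fs),
        duration_to_samples(params.w2_ms, pre.fs),
    )
    coverage = []
    for beta in (0.0, 0.02, 0.05, 0.08, 0.10):
        blocks = generate_blocks(ma, compute_offset(pre.mean_squared, beta))
        coverage.append(sum(b.width for b in blocks))
    assert all(b <= a for a, b in zip(coverage, coverage[1:]))


def test_detect_rejects_too_short_record():
    rec = ECGRecord(np.random.default_rng(0).normal(size=100), 360.0)
    with pytest.raises(ValueError, match="at least"):
        detect(rec)


def test_detector_params_validation():
    with pytest.raises(ValueError):
        DetectorParams(f1=20, f2=8)
    with pytest.raises(ValueError):
        DetectorParams(w1_ms=700, w2_ms=600)
    with pytest.raises(ValueError):
        DetectorParams(beta=1.5)
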