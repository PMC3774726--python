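"""The two-moving-average QRS detector.

The squared, band-pass-filtered ECG is smoothed twice: a short moving
average at the scale of one QRS complex (window W1) and a long one at the
scale of one heartbeat (window W2).  Wherever the QRS-scale average rises
above the beat-scale average plus a dynamic offset alpha = beta * mean of
the squared signal, the samples form a candidate "block of interest".
Blocks at least W1 samples wide are accepted as QRS complexes; the R peak
of each is the maximum absolute value of the filtered signal inside the
block.  Every quantity in the comparison scales with the square of the
input amplitude, so detection is invariant to positive rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np

from .preprocess import DEFAULT_FILTER_ORDER, PreprocessedSignal, preprocess
from .records import ECGRecord

__all__ = [
    "DetectorParams",
    "MovingAverages",
    "BlockOfInterest",
    "DetectionResult",
    "duration_to_samples",
    "moving_average",
    "compute_offset",
    "generate_blocks",
    "threshold_blocks",
    "locate_r_peaks",
    "detect",
]


@dataclass(frozen=True)
class DetectorParams:
    """The five detector inputs, in physical units.

    Defaults are the optimum found by brute-force search on the MIT-BIH
    Arrhythmia Database: passband 8-20 Hz, W1 = 97 ms (35 samples at
    360 Hz), W2 = 611 ms (220 samples), offset fraction beta = 8%.
    Physical units make the same parameter set applicable to records
    sampled anywhere from 128 Hz to 1 kHz.
    """

    f1: float = 8.0
    f2: float = 20.0
    w1_ms: float = 97.0
    w2_ms: float = 611.0
    beta: float = 0.08
    order: int = DEFAULT_FILTER_ORDER

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError(f"need 0 < f1 < f2, got f1={self.f1}, f2={self.f2}")
        if not 0 < self.w1_ms < self.w2_ms:
            raise ValueError(
                f"need 0 < w1_ms < w2_ms, got w1_ms={self.w1_ms}, w2_ms={self.w2_ms}"
            )
        if not 0 <= self.beta <= 1:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")


@dataclass(frozen=True)
class MovingAverages:
    """The QRS-scale and beat-scale moving averages of the squared signal."""

    ma_qrs: np.ndarray
    ma_beat: np.ndarray
    w1_samples: int
    w2_samples: int


@dataclass
class BlockOfInterest:
    """Candidate QRS region ``[onset, end)`` in sample indices."""

    onset: int
    end: int
    accepted: bool = False

    @property
    def width(self) -> int:
        return self.end - self.onset


@dataclass(frozen=True)
class DetectionResult:
    """Output of one detector run.

    ``r_peaks`` holds one strictly increasing sample index per accepted
    block; rejected blocks are retained in ``blocks`` for diagnostics.
    ``threshold_offset`` is the realized offset alpha = beta * mean of the
    squared filtered signal.
    """

    r_peaks: np.ndarray
    blocks: List[BlockOfInterest]
    params: DetectorParams
    fs: float
    threshold_offset: float

    @property
    def accepted_blocks(self) -> List[BlockOfInterest]:
        return [b for b in self.blocks if b.accepted]


def duration_to_samples(duration_ms: float, fs: float, mode: str = "nearest") -> int:
    """Convert a physical duration to a window length in samples.

    mode="nearest" rounds half away from zero to the nearest integer
    (97 ms at 360 Hz -> 35 samples; 611 ms -> 220; 1000 ms -> 360) with a
    floor of 1.  mode="odd" additionally bumps even results up by one, for
    strictly centered moving-average windows.
    """
    if duration_ms <= 0:
        raise ValueError(f"duration must be positive, got {duration_ms} ms")
    if fs <= 0:
        raise ValueError(f"sampling frequency must be positive, got {fs} Hz")
    if mode not in ("nearest", "odd"):
        raise ValueError(f"mode must be 'nearest' or 'odd', got {mode!r}")
    n = max(1, int(math.floor(duration_ms * fs / 1000.0 + 0.5)))
    if mode == "odd" and n % 2 == 0:
        n += 1
    return n


def moving_average(signal: Sequence[float], window: int) -> np.ndarray:
    """Centered uniform moving average, output length equal to input length.

    Odd windows are symmetric about each sample.  Even windows use the
    left-heavy span ``[n - window/2, n + window/2 - 1]``.  Near the edges
    the window shrinks to the available samples and divides by the actual
    count, so a constant signal maps to itself everywhere.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > n:
        raise ValueError(f"window ({window}) exceeds signal length ({n})")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.clip(idx - window // 2, 0, n)
    hi = np.clip(idx - window // 2 + window, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_moving_averages(
    squared: np.ndarray, w1_samples: int, w2_samples: int
) -> MovingAverages:
    """Both event-related moving averages of the squared signal."""
    if not 1 <= w1_samples < w2_samples:
        raise ValueError(
            f"need 1 <= w1_samples < w2_samples, got {w1_samples}, {w2_samples}"
        )
    return MovingAverages(
        ma_qrs=moving_average(squared, w1_samples),
        ma_beat=moving_average(squared, w2_samples),
        w1_samples=w1_samples,
        w2_samples=w2_samples,
    )


def compute_offset(mean_squared: float, beta: float) -> float:
    """Dynamic-threshold offset alpha = beta * mean of the squared signal."""
    if not 0 <= beta <= 1:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if mean_squared < 0:
        raise ValueError(f"mean of a squared signal cannot be negative: {mean_squared}")
    return beta * mean_squared


def generate_blocks(ma: MovingAverages, offset: float) -> List[BlockOfInterest]:
    """Maximal runs where the QRS average exceeds the beat average + offset.

    Membership uses strict inequality; all blocks are returned unaccepted,
    ordered by onset.
    """
    above = ma.ma_qrs > ma.ma_beat + offset
    if above.size == 0:
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[above[edges + 1]] + 1)
    ends = list(edges[~above[edges + 1]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    return [BlockOfInterest(onset=int(s), end=int(e)) for s, e in zip(starts, ends)]


def threshold_blocks(
    blocks: Iterable[BlockOfInterest], w1_samples: int
) -> List[BlockOfInterest]:
    """Accept blocks at least W1 samples wide (QRS complexes); keep the rest.

    Width equal to W1 is accepted — the rule is "greater than or equal" so
    both average-width and wide arrhythmic QRS complexes pass, while the
    narrower P/T-wave and noise blocks are rejected.
    """
    if w1_samples < 1:
        raise ValueError(f"w1_samples must be >= 1, got {w1_samples}")
    out = []
    for b in blocks:
        out.append(BlockOfInterest(b.onset, b.end, accepted=b.width >= w1_samples))
    return out


def locate_r_peaks(
    blocks: Iterable[BlockOfInterest], filtered: np.ndarray
) -> np.ndarray:
    """One R-peak index per accepted block: argmax of |filtered| inside it.

    The absolute value handles inverted QRS complexes; ties go to the
    earliest index.
    """
    filtered = np.asarray(filtered, dtype=float)
    peaks = []
    for b in blocks:
        if not b.accepted:
            continue
        if not (0 <= b.onset < b.end <= filtered.size):
            raise ValueError(
                f"block [{b.onset}, {b.end}) outside signal of length {filtered.size}"
            )
        seg = np.abs(filtered[b.onset : b.end])
        peaks.append(b.onset + int(np.argmax(seg)))
    return np.asarray(peaks, dtype=int)


def detect(
    record: ECGRecord,
    params: DetectorParams | None = None,
    rounding: str = "nearest",
) -> DetectionResult:
    """Run the full detector on one record.

    Pipeline: band-pass filter -> square -> two moving averages ->
    offset threshold -> block generation -> width acceptance -> per-block
    argmax.  Deterministic for a fixed input.

    Raises
    ------
    ValueError
        If the record is shorter than one beat-scale window W2.
    """
    if params is None:
        params = DetectorParams()
    w1 = duration_to_samples(params.w1_ms, record.fs, rounding)
    w2 = duration_to_samples(params.w2_ms, record.fs, rounding)
    if len(record) < w2:
        raise ValueError(
            f"record {record.record_id!r} has {len(record)} samples but the "
            f"beat-scale window needs {w2} ({params.w2_ms} ms at {record.fs} Hz); "
            f"supply at least {w2 / record.fs:.2f} s of signal"
        )
    pre = preprocess(record, params)
    return detect_preprocessed(pre, params, w1, w2)


def detect_preprocessed(
    pre: PreprocessedSignal,
    params: DetectorParams,
    w1_samples: int,
    w2_samples: int,
) -> DetectionResult:
    """Detection stages downstream of filtering (reusable by the optimizer)."""
    ma = compute_moving_averages(pre.squared, w1_samples, w2_samples)
    alpha = compute_offset(pre.mean_squared, params.beta)
    blocks = threshold_blocks(generate_blocks(ma, alpha), w1_samples)
    r_peaks = locate_r_peaks(blocks, pre.filtered)
    return DetectionResult(
        r_peaks=r_peaks,
        blocks=blocks,
        params=params,
        fs=pre.fs,
        threshold_offset=alpha,
    )
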