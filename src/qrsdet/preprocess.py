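"""Band-pass filtering and squaring of the raw ECG.

The detector thresholds a nonnegative "energy" signal: the raw ECG is
band-pass filtered (removing baseline wander below the passband and muscle
/ mains components above it) and then squared point by point, which boosts
the large, fast QRS deflections relative to the P and T waves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal as sps

from .records import ECGRecord

if TYPE_CHECKING:  # pragma: no cover
    from .detector import DetectorParams

DEFAULT_FILTER_ORDER = 3


def design_bandpass(f1: float, f2: float, fs: float, order: int = DEFAULT_FILTER_ORDER):
    """Design the Butterworth band-pass as second-order sections.

    Exposed separately so tests can evaluate the exact transfer function
    the detector applies.
    """
    if order < 1:
        raise ValueError(f"filter order must be >= 1, got {order}")
    nyquist = fs / 2.0
    if not 0 < f1 < f2:
        raise ValueError(
            f"invalid passband: need 0 < f1 < f2, got f1={f1} Hz, f2={f2} Hz"
        )
    if f2 >= nyquist:
        raise ValueError(
            f"passband stop {f2} Hz must lie below the Nyquist frequency "
            f"{nyquist} Hz (fs={fs} Hz)"
        )
    return sps.butter(order, [f1, f2], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    record: ECGRecord,
    f1: float,
    f2: float,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of an ECG record.

    The filter is applied forward and backward (bidirectionally), so the
    output has no phase lag and the effective magnitude response is the
    squared single-pass response.  One second of reflected signal is
    prepended/appended before filtering and trimmed afterwards to damp
    start-up transients.

    Parameters
    ----------
    record : ECGRecord
    f1, f2 : float
        Passband start / stop in Hz; ``0 < f1 < f2 < fs/2``.
    order : int
        Butterworth order of the single-pass design (default 3).

    Returns
    -------
    numpy.ndarray
        Filtered signal, same length as the input, DC removed.
    """
    sos = design_bandpass(f1, f2, record.fs, order)
    x = record.samples
    # reflect up to 1 s at each end; np.pad needs pad < len
    pad = min(int(round(record.fs)), x.size - 1)
    if pad > 0:
        xp = np.pad(x, pad, mode="reflect")
    else:
        xp = x
    y = sps.sosfiltfilt(sos, xp)
    if pad > 0:
        y = y[pad : pad + x.size]
    return np.ascontiguousarray(y)


def square(filtered: np.ndarray) -> np.ndarray:
    """Point-wise square, producing the nonnegative energy signal."""
    filtered = np.asarray(filtered, dtype=float)
    if not np.all(np.isfinite(filtered)):
        raise ValueError("cannot square a signal containing NaN/Inf")
    return filtered * filtered


@dataclass(frozen=True)
class PreprocessedSignal:
    """Band-passed signal, its square, and the mean of the square.

    ``mean_squared`` is the statistical mean of the squared filtered signal
    over the whole record; the detector's dynamic-threshold offset is a
    fraction of it.
    """

    filtered: np.ndarray
    squared: np.ndarray
    mean_squared: float
    fs: float


def preprocess(record: ECGRecord, params: "DetectorParams") -> PreprocessedSignal:
    """Run the full pre-processing chain: band-pass filter then square."""
    filtered = bandpass_filter(record, params.f1, params.f2, params.order)
    squared = square(filtered)
    return PreprocessedSignal(
        filtered=filtered,
        squared=squared,
        mean_squared=float(np.mean(squared)),
        fs=record.fs,
    )
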