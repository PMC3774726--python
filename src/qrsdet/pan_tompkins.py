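"""Pan-Tompkins comparator detector.

Classic adaptive-threshold QRS detection: the ECG is resampled to 200 Hz
(the rate its filters were designed for), mean-subtracted, band-passed at
5-15 Hz, differentiated, squared, and integrated over a 150 ms moving
window.  Peaks of the integrated signal are classified as signal or noise
by a pair of running thresholds; a search-back pass at a lowered threshold
recovers beats missed during long RR intervals.  Detections are mapped
back to the original record's sample coordinates.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .records import ECGRecord

INTERNAL_FS = 200.0
_BAND = (5.0, 15.0)
_INTEGRATION_MS = 150.0
_REFRACTORY_MS = 200.0
_WARMUP_S = 2.0


def _resample_to_internal(x: np.ndarray, fs: float) -> np.ndarray:
    if fs == INTERNAL_FS:
        return x.astype(float)
    frac = Fraction(INTERNAL_FS / fs).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def _bandpass(x: np.ndarray) -> np.ndarray:
    sos = sps.butter(3, _BAND, btype="bandpass", fs=INTERNAL_FS, output="sos")
    return sps.sosfiltfilt(sos, x)


def _derivative(x: np.ndarray) -> np.ndarray:
    # five-point derivative y[n] = (2x[n] + x[n-1] - x[n-3] - 2x[n-4]) / 8
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0
    return np.convolve(x, kernel, mode="same")


def _integrate(x: np.ndarray) -> np.ndarray:
    w = max(1, int(round(_INTEGRATION_MS * INTERNAL_FS / 1000.0)))
    return np.convolve(x, np.ones(w) / w, mode="same")


def pan_tompkins_detect(record: ECGRecord) -> np.ndarray:
    """Detect R peaks with the Pan-Tompkins algorithm.

    Returns strictly increasing R-peak indices in the ORIGINAL record's
    sample coordinates.  The first two seconds initialise the running
    signal/noise levels.

    Raises
    ------
    ValueError
        If the record is shorter than two seconds.
    """
    if record.duration_s < 2.0:
        raise ValueError(
            f"record {record.record_id!r} is {record.duration_s:.2f} s long; "
            "Pan-Tompkins needs at least 2 s to initialise its thresholds"
        )
    x0 = record.samples - np.mean(record.samples)
    x = _resample_to_internal(x0, record.fs)
    bp = _bandpass(x)
    integ = _integrate(_derivative(bp) ** 2)

    if np.max(integ) <= 0:
        return np.asarray([], dtype=int)

    refractory = int(round(_REFRACTORY_MS * INTERNAL_FS / 1000.0))
    peak_idx, _ = sps.find_peaks(integ, distance=refractory)
    if peak_idx.size == 0:
        return np.asarray([], dtype=int)

    warmup = int(_WARMUP_S * INTERNAL_FS)
    seg = integ[: min(warmup, integ.size)]
    spki = 0.875 * float(np.max(seg))
    npki = 0.5 * float(np.mean(seg))

    qrs_200: list[int] = []
    noise_peaks: list[int] = []
    rr_buffer: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < peak_idx.size:
        p = peak_idx[i]
        v = integ[p]
        if v > threshold1():
            if qrs_200 and (p - qrs_200[-1]) < refractory:
                i += 1
                continue
            spki = 0.125 * v + 0.875 * spki
            if qrs_200:
                rr_buffer.append(p - qrs_200[-1])
                if len(rr_buffer) > 8:
                    rr_buffer.pop(0)
            qrs_200.append(int(p))
        else:
            # search-back: no QRS for 166% of the average RR -> re-examine
            # skipped peaks against the halved threshold
            npki = 0.125 * v + 0.875 * npki
            noise_peaks.append(int(p))
            if qrs_200 and rr_buffer:
                rr_avg = float(np.mean(rr_buffer))
                if (p - qrs_200[-1]) > 1.66 * rr_avg:
                    cands = [
                        q for q in noise_peaks
                        if q > qrs_200[-1] + refractory
                        and integ[q] > 0.5 * threshold1()
                    ]
                    if cands:
                        best = max(cands, key=lambda q: integ[q])
                        spki = 0.25 * integ[best] + 0.75 * spki
                        rr_buffer.append(best - qrs_200[-1])
                        if len(rr_buffer) > 8:
                            rr_buffer.pop(0)
                        qrs_200.append(int(best))
                        qrs_200.sort()
                        noise_peaks = [q for q in noise_peaks if q > best]
        i += 1

    # localise the R apex: max |band-passed| in the 150 ms window preceding
    # each integrated-signal peak (integration delays the peak), then map
    # back to the original rate and refine on an original-rate band-pass.
    win = int(round(_INTEGRATION_MS * INTERNAL_FS / 1000.0))
    sos_orig = sps.butter(3, _BAND, btype="bandpass", fs=record.fs, output="sos")
    bp_orig = sps.sosfiltfilt(sos_orig, x0)
    half = int(round(0.05 * record.fs))  # ±50 ms refinement window

    r_peaks = []
    for p in qrs_200:
        lo = max(0, p - win)
        hi = min(bp.size, p + 2)
        r200 = lo + int(np.argmax(np.abs(bp[lo:hi])))
        r_orig = int(round(r200 * record.fs / INTERNAL_FS))
        a = max(0, r_orig - half)
        b = min(len(record), r_orig + half + 1)
        if a < b:
            r_orig = a + int(np.argmax(np.abs(bp_orig[a:b])))
        if 0 <= r_orig < len(record):
            r_peaks.append(r_orig)

    out = np.unique(np.asarray(r_peaks, dtype=int))
    return out
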