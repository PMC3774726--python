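"""Beat-detection scoring: TP/FP/FN, sensitivity, positive predictivity.

A detection counts as a true positive when it lies within a tolerance
window of an unclaimed reference beat (one-to-one matching).  Sensitivity
SE = TP/(TP+FN) is the fraction of reference beats found; positive
predictivity +P = TP/(TP+FP) is the fraction of detections that are real
beats; the overall accuracy is their arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .detector import DetectorParams, detect
from .records import ECGRecord

DEFAULT_TOLERANCE_MS = 150.0


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    se_percent: Optional[float]
    pp_percent: Optional[float]
    overall_percent: Optional[float]
    tolerance_ms: float = DEFAULT_TOLERANCE_MS

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "se_percent": self.se_percent,
            "pp_percent": self.pp_percent,
            "overall_percent": self.overall_percent,
            "tolerance_ms": self.tolerance_ms,
        }

    def __str__(self) -> str:
        fmt = lambda v: "undefined" if v is None else f"{v:.2f}%"
        return (
            f"TP={self.tp}  FP={self.fp}  FN={self.fn}  "
            f"SE={fmt(self.se_percent)}  +P={fmt(self.pp_percent)}  "
            f"overall={fmt(self.overall_percent)}  "
            f"(tolerance ±{self.tolerance_ms:g} ms)"
        )


def _check_increasing(name: str, seq: np.ndarray) -> None:
    if seq.size > 1 and np.any(np.diff(seq) <= 0):
        raise ValueError(f"{name} indices must be strictly increasing")


def match_beats(
    detected: Sequence[int],
    reference: Sequence[int],
    tolerance_samples: int,
) -> Tuple[int, int, int, List[Tuple[int, int]]]:
    """One-to-one greedy nearest-neighbour matching.

    Candidate (detection, reference) pairs within ``tolerance_samples`` are
    taken in order of increasing absolute time difference (ties to the
    earlier detection); each side is matched at most once.  Unmatched
    detections are FPs, unmatched references FNs.

    Returns ``(tp, fp, fn, matched_pairs)`` where pairs are
    ``(detected_index, reference_index)`` sample positions.
    """
    det = np.asarray(detected, dtype=int)
    ref = np.asarray(reference, dtype=int)
    _check_increasing("detected", det)
    _check_increasing("reference", ref)

    candidates = []
    for i, d in enumerate(det):
        # references within tolerance of this detection
        lo = np.searchsorted(ref, d - tolerance_samples, side="left")
        hi = np.searchsorted(ref, d + tolerance_samples, side="right")
        for j in range(lo, hi):
            candidates.append((abs(int(d) - int(ref[j])), i, j))
    candidates.sort()

    det_used = np.zeros(det.size, dtype=bool)
    ref_used = np.zeros(ref.size, dtype=bool)
    pairs: List[Tuple[int, int]] = []
    for _, i, j in candidates:
        if det_used[i] or ref_used[j]:
            continue
        det_used[i] = True
        ref_used[j] = True
        pairs.append((int(det[i]), int(ref[j])))
    tp = len(pairs)
    fp = det.size - tp
    fn = ref.size - tp
    return tp, fp, fn, sorted(pairs)


def score(tp: int, fp: int, fn: int, tolerance_ms: float = DEFAULT_TOLERANCE_MS) -> EvaluationReport:
    """Turn counts into SE / +P / overall-accuracy percentages.

    Division-by-zero cases (no reference beats, or no detections) yield
    ``None`` rather than 0 so an empty record is not scored as a failure.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    se = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    pp = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    overall = (se + pp) / 2.0 if (se is not None and pp is not None) else None
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn,
        se_percent=se, pp_percent=pp, overall_percent=overall,
        tolerance_ms=tolerance_ms,
    )


def evaluate(
    detected: Sequence[int],
    reference: Sequence[int],
    fs: float,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> EvaluationReport:
    """Match detections against reference beats and score them."""
    tol_samples = int(round(tolerance_ms * fs / 1000.0))
    tp, fp, fn, _ = match_beats(detected, reference, tol_samples)
    return score(tp, fp, fn, tolerance_ms)


def evaluate_record(
    record: ECGRecord,
    reference: Sequence[int],
    params: DetectorParams | None = None,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> EvaluationReport:
    """Detect beats on a record and score them against reference indices."""
    result = detect(record, params)
    return evaluate(result.r_peaks, reference, record.fs, tolerance_ms)
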