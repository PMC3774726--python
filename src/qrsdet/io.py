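"""Reading and writing signals, annotations, reports and configs.

Sample indices are 0-based everywhere.  The plain-text formats are a
one-amplitude-per-line CSV for signals (header optional, multi-channel
allowed) and newline-delimited integer indices for annotations.  WFDB
record/annotation reading is available when the optional ``wfdb`` package
is installed; it is never required.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .detector import DetectorParams
from .records import ECGRecord

logger = logging.getLogger(__name__)

# WFDB single-character beat codes (normal, bundle-branch blocks, ectopics,
# paced, fusions...); anything else is a non-beat annotation and dropped.
BEAT_CODES = set("NLRBAaJSVrFejnE/fQ?")


@dataclass(frozen=True)
class AnnotationList:
    record_id: str
    sample_indices: np.ndarray
    labels: Optional[Sequence[str]] = None


def _require_wfdb():
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - wfdb is optional
        raise ImportError(
            "WFDB support requires the optional 'wfdb' package "
            "(pip install wfdb); CSV/plain-text formats need no extras"
        ) from exc
    return wfdb


def read_signal(
    path: str | Path,
    format: str = "csv",
    fs: Optional[float] = None,
    channel: int = 0,
) -> ECGRecord:
    """Read one channel of a signal file into an ECGRecord.

    CSV: one row per sample, optional single header line, columns are
    channels; ``fs`` must be supplied.  WFDB: ``path`` is the record name
    (without extension); ``fs`` comes from the header.
    """
    path = Path(path)
    if format == "csv":
        if fs is None:
            raise ValueError(
                f"reading {path} as CSV requires a sampling frequency "
                "(pass fs / --fs)"
            )
        with open(path) as fh:
            first = fh.readline()
            try:
                [float(v) for v in first.replace(",", " ").split()]
                skip = 0
            except ValueError:
                skip = 1
        data = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
        if not 0 <= channel < data.shape[1]:
            raise ValueError(
                f"channel {channel} not in {path}; available channels: "
                f"{list(range(data.shape[1]))}"
            )
        return ECGRecord(data[:, channel], fs, record_id=path.stem)
    if format == "wfdb":
        wfdb = _require_wfdb()
        rec = wfdb.rdrecord(str(path))
        sig = np.asarray(rec.p_signal)
        if not 0 <= channel < sig.shape[1]:
            raise ValueError(
                f"channel {channel} not in record {path}; available channels: "
                f"{list(range(sig.shape[1]))} ({rec.sig_name})"
            )
        return ECGRecord(sig[:, channel], float(rec.fs), record_id=path.stem)
    raise ValueError(f"unknown signal format {format!r}; use 'csv' or 'wfdb'")


def write_signal(path: str | Path, record: ECGRecord) -> None:
    np.savetxt(path, record.samples, fmt="%.9g")


def read_annotations(path: str | Path, format: str = "txt") -> AnnotationList:
    """Read beat annotations as 0-based sample indices.

    Text: one integer per line.  WFDB: ``path`` names record+extension;
    non-beat labels (rhythm changes, signal-quality flags) are dropped
    with a logged count.
    """
    path = Path(path)
    if format == "txt":
        raw = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        idx = np.asarray([int(v) for v in raw], dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError(
                f"annotation indices in {path} must be nonnegative and "
                "strictly increasing"
            )
        return AnnotationList(record_id=path.stem, sample_indices=idx)
    if format == "wfdb":
        wfdb = _require_wfdb()
        ann = wfdb.rdann(str(path.parent / path.stem), path.suffix.lstrip("."))
        samples = np.asarray(ann.sample, dtype=int)
        symbols = list(ann.symbol)
        keep = [i for i, s in enumerate(symbols) if s in BEAT_CODES]
        dropped = len(symbols) - len(keep)
        if dropped:
            logger.info("dropped %d non-beat annotations from %s", dropped, path)
        idx = samples[keep]
        return AnnotationList(
            record_id=path.stem,
            sample_indices=idx,
            labels=[symbols[i] for i in keep],
        )
    raise ValueError(f"unknown annotation format {format!r}; use 'txt' or 'wfdb'")


def write_annotations(path: str | Path, indices: Sequence[int]) -> None:
    Path(path).write_text("".join(f"{int(i)}\n" for i in indices))


def write_report_json(path: str | Path, report_dict: dict) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2) + "\n")


def load_params_config(path: str | Path) -> DetectorParams:
    """Detector parameters from a YAML or JSON mapping.

    Recognised keys: f1, f2, w1_ms, w2_ms, beta, order; missing keys fall
    back to the optimized defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of parameter names")
    allowed = {"f1", "f2", "w1_ms", "w2_ms", "beta", "order"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return DetectorParams(**data)


def load_grid_config(path: str | Path):
    """Parameter-grid lists from a YAML or JSON mapping."""
    from .optimizer import ParameterGrid

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"grid config {path} must be a mapping")
    kwargs = {}
    for key in ("f1_values", "f2_values", "w1_values", "w2_values", "beta_values"):
        if key in data:
            kwargs[key] = list(data[key])
    unknown = set(data) - set(kwargs)
    if unknown:
        raise ValueError(f"unknown grid keys in {path}: {sorted(unknown)}")
    return ParameterGrid(**kwargs)
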