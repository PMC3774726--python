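"""Container for a uniformly sampled single-lead ECG."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ECGRecord:
    """A single-lead ECG: raw samples plus their sampling frequency.

    Parameters
    ----------
    samples : array-like of float
        Amplitudes in mV (or arbitrary units); must be non-empty and finite.
    fs : float
        Sampling frequency in Hz; must be positive.
    record_id : str
        Free-text label used in logs and reports.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError(
                f"ECG samples must be one-dimensional, got shape {samples.shape}"
            )
        if samples.size == 0:
            raise ValueError("ECG record is empty")
        if not np.all(np.isfinite(samples)):
            bad = int(np.count_nonzero(~np.isfinite(samples)))
            raise ValueError(
                f"ECG record {self.record_id!r} contains {bad} non-finite "
                "samples (NaN/Inf); clean the input before detection"
            )
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def scaled(self, c: float) -> "ECGRecord":
        """Return a copy with every sample multiplied by ``c``."""
        return ECGRecord(self.samples * c, self.fs, self.record_id)
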