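"""Seeded synthetic single-lead ECG with known R-peak ground truth.

Each beat is a train of smooth unimodal pulses — P wave, QRS complex, T
wave — placed at scheduled beat times, with the standard sinus-rhythm
durations (P width 110 ms, PR interval 160 ms, QRS width 100 ms) as
defaults.  Morphology flags reproduce the classic detection challenges:
inverted or widened QRS, missing P waves, biphasic QRS.  Noise models
cover 60 Hz mains with second and third harmonics, sub-1 Hz baseline
wander, and broadband muscle noise.  Ground-truth R-peak indices are
recorded before noise is added, so truth is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .records import ECGRecord

__all__ = ["SyntheticSpec", "SyntheticRecord", "generate", "PRESETS", "preset_spec"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to render one reproducible synthetic record.

    Widths are interpreted as the ±2-sigma span of a Gaussian pulse.
    ``heart_rate_bpm`` may be a single rate or a (start, stop) ramp.
    """

    fs: float = 360.0
    duration_s: float = 30.0
    heart_rate_bpm: float | Tuple[float, float] = 60.0
    qrs_width_ms: float = 100.0
    p_width_ms: float = 110.0
    pr_ms: float = 160.0
    t_width_ms: float = 160.0
    rt_ms: float = 300.0
    r_amplitude: float = 1.0
    p_amplitude: float = 0.15
    t_amplitude: float = 0.3
    inverted_qrs: bool = False
    widened_qrs: bool = False
    missing_p: bool = False
    biphasic_qrs: bool = False
    mains_60hz_amp: float = 0.0
    mains_harmonic_fracs: Tuple[float, float] = (0.5, 0.25)
    baseline_wander_amp: float = 0.0
    baseline_wander_hz: float = 0.33
    muscle_noise_sd: float = 0.0
    rr_jitter_sd_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")
        rates = self.heart_rate_bpm
        if not isinstance(rates, tuple):
            rates = (rates, rates)
        for hr in rates:
            if not 20 <= hr <= 300:
                raise ValueError(
                    f"heart rate {hr} bpm outside the supported range 20-300 bpm"
                )
        for name in ("qrs_width_ms", "p_width_ms", "pr_ms", "t_width_ms", "rt_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "mains_60hz_amp", "baseline_wander_amp", "muscle_noise_sd",
            "rr_jitter_sd_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 < self.baseline_wander_hz < 1.0):
            raise ValueError(
                f"baseline wander frequency must lie in (0, 1) Hz, "
                f"got {self.baseline_wander_hz}"
            )


@dataclass(frozen=True)
class SyntheticRecord:
    record: ECGRecord
    true_r_peaks: np.ndarray
    spec: SyntheticSpec


def _gaussian_pulse(t: np.ndarray, center_s: float, width_ms: float,
                    amplitude: float) -> np.ndarray:
    sigma = width_ms / 1000.0 / 4.0  # width spans ±2 sigma
    return amplitude * np.exp(-0.5 * ((t - center_s) / sigma) ** 2)


def _beat_times(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Scheduled R-apex times in seconds, fully inside the record."""
    rates = spec.heart_rate_bpm
    if not isinstance(rates, tuple):
        rates = (rates, rates)
    # leading margin for the P wave, trailing margin for the T wave
    lead = (spec.pr_ms + spec.p_width_ms) / 1000.0
    trail = (spec.rt_ms + spec.t_width_ms) / 1000.0
    times = []
    t = max(lead, 0.5 * 60.0 / rates[0])
    while True:
        if t > spec.duration_s - trail:
            break
        times.append(t)
        frac = t / spec.duration_s
        hr = rates[0] + (rates[1] - rates[0]) * frac
        rr = 60.0 / hr
        if spec.rr_jitter_sd_ms > 0:
            sd = spec.rr_jitter_sd_ms / 1000.0
            jitter = float(np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd))
        else:
            jitter = 0.0
        t = t + rr + jitter
    return np.asarray(times)


def generate(spec: SyntheticSpec) -> SyntheticRecord:
    """Render the spec into a record with exact ground-truth R indices."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    beat_times = _beat_times(spec, rng)
    true_r = np.round(beat_times * spec.fs).astype(int)
    true_r = true_r[(true_r >= 0) & (true_r < n)]
    # snap scheduled times to the sample grid so the rendered apex and the
    # stored truth coincide exactly at any sampling rate
    beat_times = true_r / spec.fs

    clean = np.zeros(n)
    qrs_width = spec.qrs_width_ms * (1.8 if spec.widened_qrs else 1.0)
    qrs_sign = -1.0 if spec.inverted_qrs else 1.0
    for tb in beat_times:
        if spec.biphasic_qrs:
            half = qrs_width / 2.0
            off = half / 1000.0 / 2.0
            clean += _gaussian_pulse(t, tb - off, half, qrs_sign * spec.r_amplitude)
            clean += _gaussian_pulse(t, tb + off, half, -qrs_sign * spec.r_amplitude)
        else:
            clean += _gaussian_pulse(t, tb, qrs_width, qrs_sign * spec.r_amplitude)
        if not spec.missing_p:
            clean += _gaussian_pulse(
                t, tb - spec.pr_ms / 1000.0, spec.p_width_ms, spec.p_amplitude
            )
        clean += _gaussian_pulse(
            t, tb + spec.rt_ms / 1000.0, spec.t_width_ms, spec.t_amplitude
        )

    noisy = clean.copy()
    if spec.mains_60hz_amp > 0:
        amps = (spec.mains_60hz_amp,) + tuple(
            spec.mains_60hz_amp * f for f in spec.mains_harmonic_fracs
        )
        for k, amp in enumerate(amps, start=1):
            freq = 60.0 * k
            if freq < spec.fs / 2.0:
                phase = rng.uniform(0, 2 * np.pi)
                noisy += amp * np.sin(2 * np.pi * freq * t + phase)
    if spec.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noisy += spec.baseline_wander_amp * np.sin(
            2 * np.pi * spec.baseline_wander_hz * t + phase
        )
    if spec.muscle_noise_sd > 0:
        noisy += rng.normal(0.0, spec.muscle_noise_sd, size=n)

    record = ECGRecord(noisy, spec.fs, record_id=f"synthetic-seed{spec.seed}")
    return SyntheticRecord(record=record, true_r_peaks=true_r, spec=spec)


# fixture presets named for the classic challenge conditions
PRESETS = {
    "clean": {},
    "mains": {"mains_60hz_amp": 0.2},
    "muscle": {"muscle_noise_sd": 0.15},
    "wander": {"baseline_wander_amp": 0.5},
    "inverted": {"inverted_qrs": True},
    "widened": {"widened_qrs": True},
}


def preset_spec(name: str, **overrides) -> SyntheticSpec:
    """A SyntheticSpec for one of the named challenge presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)
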