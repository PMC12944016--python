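"""Synthetic foot-PPG cohort generator with documented BP-coupled morphology.

The study data this package was designed for are not public, so the
pipeline is exercised on a simulated cohort instead. Each subject gets a
pulse train built from a two-Gaussian beat template — a systolic upstroke
pulse and a delayed diastolic (reflected-wave) pulse — whose morphology is
coupled monotonically to the subject's assigned blood pressure:

* higher SBP narrows the systolic pulse (steeper upstroke, larger |dx/dt|),
* higher DBP raises the reflected-wave amplitude.

Nuisance terms mimic the failure modes of distal PPG: low-frequency
baseline wander (two sinusoids in 0.05–0.3 Hz), additive white noise, and
sporadic 1–3 s multiplicative artifact bursts (×3–×8 amplitude) at Poisson
times. The generator makes no claim to hemodynamic realism beyond these
documented monotone couplings; it exists so that signal-recovery and
leakage properties of the downstream pipeline are testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import Recording

__all__ = ["SyntheticConfig", "generate_subject", "generate_cohort"]

# Beat template constants: base systolic Gaussian width (s), base reflected
# amplitude, and the reflected pulse's delay as a fraction of the beat period.
W0_S = 0.09
A0_REFLECTED = 0.4
REFLECTED_DELAY_FRAC = 0.35
SYSTOLIC_OFFSET_FRAC = 0.15


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings.

    Amplitudes (``wander_amp``, ``noise_sd``) are relative to the unit
    systolic pulse amplitude. ``coupling_sbp`` and ``coupling_dbp`` are
    dimensionless gains; setting both to zero decouples waveform morphology
    from the assigned pressures entirely.
    """

    n_subjects: int = 56
    fs: float = 100.0
    duration_range: tuple[float, float] = (120.0, 360.0)
    hr_mean_bpm: float = 70.0
    hr_sd_bpm: float = 8.0
    beat_jitter_cv: float = 0.04
    coupling_sbp: float = 0.5
    coupling_dbp: float = 0.5
    wander_amp: float = 0.3
    noise_sd: float = 0.05
    artifact_rate: float = 0.5  # bursts per minute
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.duration_range
        if not (30.0 <= lo <= hi <= 3600.0):
            raise ValueError("duration_range must lie within [30, 3600] s")
        for name in ("wander_amp", "noise_sd", "artifact_rate", "beat_jitter_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fs <= 0 or self.hr_mean_bpm <= 0:
            raise ValueError("fs and hr_mean_bpm must be positive")


def _draw_bp(rng: np.random.Generator) -> tuple[float, float]:
    """SBP ~ U[95, 175], DBP ~ U[55, 105], resampled until DBP < SBP - 15.

    The uniform ranges span normotensive through stage-2 hypertensive
    values so that every clinical category is occupied in a modest cohort.
    """
    while True:
        sbp = rng.uniform(95.0, 175.0)
        dbp = rng.uniform(55.0, 105.0)
        if dbp < sbp - 15.0:
            return float(sbp), float(dbp)


def systolic_width(sbp: float, coupling_sbp: float) -> float:
    """Systolic Gaussian width in seconds, narrowed by higher SBP."""
    w = W0_S * (1.0 - coupling_sbp * (sbp - 120.0) / 120.0)
    return float(np.clip(w, 0.25 * W0_S, 2.0 * W0_S))


def reflected_amplitude(dbp: float, coupling_dbp: float) -> float:
    """Reflected-wave amplitude, raised by higher DBP."""
    a = A0_REFLECTED + coupling_dbp * (dbp - 80.0) / 80.0
    return float(np.clip(a, 0.0, 0.9))


def generate_subject(config: SyntheticConfig, subject_index: int) -> Recording:
    """Generate one subject's recording, deterministic in (seed, subject_index)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))

    sbp, dbp = _draw_bp(rng)
    duration = rng.uniform(*config.duration_range)
    hr = float(np.clip(rng.normal(config.hr_mean_bpm, config.hr_sd_bpm), 40.0, 140.0))
    period = 60.0 / hr

    w_s = systolic_width(sbp, config.coupling_sbp)
    a_d = reflected_amplitude(dbp, config.coupling_dbp)

    n = int(round(duration * config.fs))
    t = np.arange(n) / config.fs

    # Jittered beat onsets around the mean period.
    n_beats = int(np.ceil(duration / period)) + 3
    intervals = period * (1.0 + config.beat_jitter_cv * rng.standard_normal(n_beats))
    intervals = np.clip(intervals, 0.3 * period, 3.0 * period)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    onsets = onsets[onsets < duration + period]

    # Two-Gaussian beat template per onset: unit systolic pulse plus a
    # delayed reflected pulse; width of the diastolic pulse is broader.
    pulses = np.zeros(n)
    w_d = 1.8 * w_s
    for onset in onsets:
        c_sys = onset + SYSTOLIC_OFFSET_FRAC * period
        c_dia = c_sys + REFLECTED_DELAY_FRAC * period
        lo = max(0, int((c_sys - 6 * w_d) * config.fs))
        hi = min(n, int((c_dia + 6 * w_d) * config.fs) + 1)
        if hi <= lo:
            continue
        tt = t[lo:hi]
        pulses[lo:hi] += np.exp(-0.5 * ((tt - c_sys) / w_s) ** 2)
        pulses[lo:hi] += a_d * np.exp(-0.5 * ((tt - c_dia) / w_d) ** 2)

    # Sporadic multiplicative artifact bursts (1-3 s, gain 3-8).
    n_bursts = rng.poisson(config.artifact_rate * duration / 60.0)
    gain = np.ones(n)
    for _ in range(n_bursts):
        start = rng.uniform(0.0, duration)
        length = rng.uniform(1.0, 3.0)
        g = rng.uniform(3.0, 8.0)
        i0, i1 = int(start * config.fs), min(n, int((start + length) * config.fs))
        gain[i0:i1] = g
    signal = pulses * gain

    # Baseline wander: two sinusoids with frequencies in [0.05, 0.3] Hz.
    if config.wander_amp > 0:
        for _ in range(2):
            f = rng.uniform(0.05, 0.3)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            signal = signal + 0.5 * config.wander_amp * np.sin(2 * np.pi * f * t + phi)

    if config.noise_sd > 0:
        signal = signal + config.noise_sd * rng.standard_normal(n)

    return Recording(
        subject_id=f"S{subject_index + 1:03d}",
        fs=config.fs,
        samples=signal,
        sbp_ref=sbp,
        dbp_ref=dbp,
    )


def generate_cohort(config: SyntheticConfig) -> list[Recording]:
    """Generate ``config.n_subjects`` independent recordings S001, S002, ..."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]
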