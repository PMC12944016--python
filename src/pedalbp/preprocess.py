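"""Recording-level conditioning and per-window normalization.

The pipeline order is fixed: the full recording is linearly detrended,
bandpass-filtered with a zero-phase Chebyshev type-II filter (0.4–8 Hz),
and only then segmented; each retained window is z-scored independently.
Detrending and filtering act on the whole recording so that window edges
see no filter transients; normalization is per-window so that slow
amplitude drifts between windows cannot leak across them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_formats import Recording

__all__ = [
    "FilterSpec",
    "DegenerateWindowError",
    "detrend_recording",
    "bandpass_zero_phase",
    "znorm_window",
]


class DegenerateWindowError(ValueError):
    """Window standard deviation below 1e-12; must be rejected by QC instead."""


@dataclass
class FilterSpec:
    """Zero-phase Chebyshev type-II bandpass settings.

    ``low_hz``/``high_hz`` are the stopband edges where the single-pass
    response reaches ``stop_atten_db`` of attenuation; the forward–backward
    application squares the magnitude response, doubling the attenuation in
    dB. Order 4 per pass with 40 dB stopband attenuation gives sharp band
    edges with modest passband droop at the cardiac fundamental.
    """

    low_hz: float = 0.4
    high_hz: float = 8.0
    order: int = 4
    stop_atten_db: float = 40.0

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise ValueError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) < fs/2 ({fs / 2})"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.cheby2(
            self.order,
            self.stop_atten_db,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=fs,
            output="sos",
        )


def detrend_recording(rec: Recording) -> Recording:
    """Subtract the least-squares straight line fit over the full recording."""
    if rec.samples.size < 2:
        raise ValueError("detrending needs at least 2 samples")
    return rec.replace(samples=sps.detrend(rec.samples, type="linear"))


def bandpass_zero_phase(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Forward–backward Chebyshev-II bandpass; output length equals input.

    Edges are handled by odd-symmetric extension so recording ends do not
    ring into the first and last analysis windows.
    """
    spec = spec or FilterSpec()
    sos = spec.sos(rec.fs)
    # sosfiltfilt needs the signal longer than its padding; the default
    # padlen for an order-4 bandpass is small, but guard anyway.
    min_len = 3 * (2 * spec.order) + 1
    if rec.samples.size <= min_len:
        raise ValueError(
            f"recording of {rec.samples.size} samples too short to pad "
            f"(need > {min_len})"
        )
    filtered = sps.sosfiltfilt(sos, rec.samples, padtype="odd")
    return rec.replace(samples=filtered)


def znorm_window(x: np.ndarray) -> np.ndarray:
    """Z-score a window with the population (1/N) standard deviation.

    With this convention the sum of squares of the output equals the window
    length exactly, which the energy features rely on. A window whose SD is
    below 1e-12 cannot be normalized and raises
    :class:`DegenerateWindowError`; such windows are dropped by QC.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    sd = float(np.std(x))
    if sd < 1e-12:
        raise DegenerateWindowError(f"window SD {sd} below 1e-12")
    return (x - np.mean(x)) / sd
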