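"""Smoothed velocity (VPG) and acceleration (APG) plethysmograms.

Derivatives are computed per window on the normalized signal: a central
finite difference scaled by the sampling rate (one-sided at the window
ends, so lengths stay aligned), followed by Savitzky–Golay smoothing with
polynomial order 3 and frame length 11. The APG is obtained by applying
the same scheme to the smoothed VPG. No fiducial points (peaks, feet,
APG a–e waves) are detected anywhere: the method is peak-independent by
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["WindowTriplet", "vpg_of", "apg_of", "SG_POLYORDER", "SG_FRAME"]

SG_POLYORDER = 3
SG_FRAME = 11


def _smooth_derivative(x: np.ndarray, fs: float, polyorder: int, frame: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < frame:
        raise ValueError(f"need at least {frame} samples, got {x.size}")
    d = np.gradient(x) * fs  # central differences, one-sided at the ends
    return savgol_filter(d, window_length=frame, polyorder=polyorder)


def vpg_of(
    ppg: np.ndarray, fs: float, polyorder: int = SG_POLYORDER, frame: int = SG_FRAME
) -> np.ndarray:
    """First derivative of the normalized PPG (units 1/s), smoothed."""
    return _smooth_derivative(ppg, fs, polyorder, frame)


def apg_of(
    ppg: np.ndarray, fs: float, polyorder: int = SG_POLYORDER, frame: int = SG_FRAME
) -> np.ndarray:
    """Second derivative of the normalized PPG (units 1/s²).

    Computed as the smoothed derivative of the smoothed VPG so both
    derivative signals share the same noise-suppression behaviour.
    """
    return _smooth_derivative(vpg_of(ppg, fs, polyorder, frame), fs, polyorder, frame)


@dataclass
class WindowTriplet:
    """One 30 s analysis window: normalized PPG with aligned VPG and APG.

    ``qc_pass`` and ``qc_reasons`` record the window-level quality verdict;
    the subject's reference pressures ride along because every window of a
    recording shares the same cuff labels.
    """

    subject_id: str
    window_index: int
    start_s: float
    fs: float
    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    sbp_ref: float
    dbp_ref: float
    qc_pass: bool = True
    qc_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.ppg) == len(self.vpg) == len(self.apg)):
            raise ValueError("ppg, vpg, apg must have equal length")
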