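"""Overlapping-window segmentation and peak-independent quality control.

Recordings are cut into 30 s windows advancing by 5 s. QC never detects
beats: a window is judged against the recording's own windows on three
statistical criteria — peak-to-peak amplitude ratio, variance ratio, and
the fraction of APG samples that are extreme outliers within the window —
plus a degeneracy guard for flat windows. Reference statistics are medians
over the same recording's windows (self-referential QC), because
normalization is per subject and no population reference exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .derivatives import apg_of
from .io_formats import Recording

__all__ = [
    "QCSpec",
    "RawWindow",
    "RecordingStats",
    "segment",
    "recording_stats",
    "quality_check",
]

WIN_S_DEFAULT = 30.0
STEP_S_DEFAULT = 5.0


@dataclass
class QCSpec:
    """Thresholds for the three statistical QC criteria.

    ``amp_ratio_bounds``: admissible window peak-to-peak amplitude relative
    to the recording's median window peak-to-peak. ``var_ratio_max``:
    maximum window variance relative to the median window variance.
    ``apg_spike_frac_max``: maximum fraction of |APG| samples above
    q3 + 5·IQR of the window's own |APG| distribution. Defaults reject the
    synthetic generator's ×3–×8 artifact bursts while passing clean windows.
    """

    amp_ratio_bounds: tuple[float, float] = (0.2, 5.0)
    var_ratio_max: float = 9.0
    apg_spike_frac_max: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.amp_ratio_bounds
        if not (0 < lo < 1 < hi):
            raise ValueError("amp_ratio_bounds must straddle 1 with 0 < low < 1 < high")
        if self.var_ratio_max <= 1:
            raise ValueError("var_ratio_max must exceed 1")
        if not (0 < self.apg_spike_frac_max < 1):
            raise ValueError("apg_spike_frac_max must be in (0, 1)")


@dataclass
class RawWindow:
    """One segmented (filtered, not yet normalized) window with its labels."""

    subject_id: str
    window_index: int
    start_s: float
    fs: float
    samples: np.ndarray
    sbp_ref: float
    dbp_ref: float


@dataclass
class RecordingStats:
    """Recording-level reference statistics over all of its windows."""

    median_ptp: float
    median_var: float


def segment(
    rec: Recording, win_s: float = WIN_S_DEFAULT, step_s: float = STEP_S_DEFAULT
) -> list[RawWindow]:
    """Cut a recording into overlapping windows.

    Windows start at 0, step, 2·step, ... seconds; the count is
    ``floor((N - W) / S) + 1`` for N ≥ W and zero otherwise. Every window
    inherits the subject's reference SBP/DBP (labels are subject-level).
    """
    if win_s <= 0 or step_s <= 0:
        raise ValueError("win_s and step_s must be positive")
    w = int(round(win_s * rec.fs))
    s = int(round(step_s * rec.fs))
    n = rec.samples.size
    if n < w:
        return []
    count = (n - w) // s + 1
    return [
        RawWindow(
            subject_id=rec.subject_id,
            window_index=i,
            start_s=i * step_s,
            fs=rec.fs,
            samples=rec.samples[i * s : i * s + w],
            sbp_ref=rec.sbp_ref,
            dbp_ref=rec.dbp_ref,
        )
        for i in range(count)
    ]


def recording_stats(windows: list[RawWindow]) -> RecordingStats:
    """Median peak-to-peak amplitude and variance across a recording's windows."""
    if not windows:
        raise ValueError("no windows to summarize")
    ptps = [float(np.ptp(w.samples)) for w in windows]
    variances = [float(np.var(w.samples)) for w in windows]
    return RecordingStats(
        median_ptp=float(np.median(ptps)), median_var=float(np.median(variances))
    )


def quality_check(
    window: RawWindow, rec_stats: RecordingStats, spec: QCSpec | None = None
) -> tuple[bool, list[str]]:
    """Judge one window against its recording's reference statistics.

    Returns ``(qc_pass, reasons)``; ``reasons`` lists every violated
    criterion ("amplitude", "variance", "derivative", "degenerate").
    A degenerate (flat) window short-circuits the derivative criterion.
    """
    spec = spec or QCSpec()
    x = window.samples
    reasons: list[str] = []

    if float(np.std(x)) < 1e-12:
        return False, ["degenerate"]

    if rec_stats.median_ptp > 0:
        ratio = float(np.ptp(x)) / rec_stats.median_ptp
        lo, hi = spec.amp_ratio_bounds
        if not (lo <= ratio <= hi):
            reasons.append("amplitude")

    if rec_stats.median_var > 0:
        if float(np.var(x)) / rec_stats.median_var > spec.var_ratio_max:
            reasons.append("variance")

    abs_apg = np.abs(apg_of(x, window.fs))
    q1, q3 = np.percentile(abs_apg, [25, 75])
    threshold = q3 + 5.0 * (q3 - q1)
    spike_frac = float(np.mean(abs_apg > threshold))
    if spike_frac > spec.apg_spike_frac_max:
        reasons.append("derivative")

    return (len(reasons) == 0), reasons
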