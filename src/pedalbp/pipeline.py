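"""End-to-end orchestration: recordings → windows → features → lag matrix.

Each recording is detrended and bandpass-filtered as a whole, segmented
into overlapping 30 s / 5 s windows, QC'd against its own window
statistics, and only the passing windows are z-normalized, differentiated,
and featurized. QC-rejected windows leave gaps that break lag contiguity
downstream, so no feature row ever mixes information across an artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .derivatives import SG_FRAME, SG_POLYORDER, WindowTriplet, apg_of, vpg_of
from .features import (
    ENTROPY_BINS_DEFAULT,
    LAGS_DEFAULT,
    FeatureRow,
    LagMatrix,
    build_lag_matrix,
    extract_features,
)
from .io_formats import Recording
from .preprocess import DegenerateWindowError, FilterSpec, bandpass_zero_phase, detrend_recording, znorm_window
from .windowing_qc import (
    QCSpec,
    STEP_S_DEFAULT,
    WIN_S_DEFAULT,
    quality_check,
    recording_stats,
    segment,
)

__all__ = ["PipelineConfig", "windows_of", "features_of", "cohort_lag_matrix"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables from raw recording to lag matrix, with study defaults."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    qc_spec: QCSpec = field(default_factory=QCSpec)
    win_s: float = WIN_S_DEFAULT
    step_s: float = STEP_S_DEFAULT
    sg_polyorder: int = SG_POLYORDER
    sg_frame: int = SG_FRAME
    entropy_bins: int = ENTROPY_BINS_DEFAULT
    lags: tuple[int, ...] = LAGS_DEFAULT


def windows_of(rec: Recording, config: PipelineConfig | None = None) -> list[WindowTriplet]:
    """Condition one recording and return every window as a triplet.

    QC-failed windows are returned too (with ``qc_pass=False`` and their
    reasons) so callers can audit rejection; their derivative series are
    computed from the un-normalized window when normalization is
    ill-posed.
    """
    config = config or PipelineConfig()
    rec = bandpass_zero_phase(detrend_recording(rec), config.filter_spec)
    raw_windows = segment(rec, config.win_s, config.step_s)
    if not raw_windows:
        return []
    stats = recording_stats(raw_windows)
    triplets: list[WindowTriplet] = []
    for w in raw_windows:
        qc_pass, reasons = quality_check(w, stats, config.qc_spec)
        try:
            x = znorm_window(w.samples)
        except DegenerateWindowError:
            x = w.samples  # flat window; kept only for audit, never featurized
            qc_pass = False
            if "degenerate" not in reasons:
                reasons.append("degenerate")
        vpg = vpg_of(x, rec.fs, config.sg_polyorder, config.sg_frame)
        apg = apg_of(x, rec.fs, config.sg_polyorder, config.sg_frame)
        triplets.append(
            WindowTriplet(
                subject_id=w.subject_id,
                window_index=w.window_index,
                start_s=w.start_s,
                fs=rec.fs,
                ppg=x,
                vpg=vpg,
                apg=apg,
                sbp_ref=w.sbp_ref,
                dbp_ref=w.dbp_ref,
                qc_pass=qc_pass,
                qc_reasons=reasons,
            )
        )
    n_fail = sum(not t.qc_pass for t in triplets)
    if n_fail:
        log.info("%s: %d/%d windows rejected by QC", rec.subject_id, n_fail, len(triplets))
    return triplets


def features_of(rec: Recording, config: PipelineConfig | None = None) -> list[FeatureRow]:
    """Feature rows for the QC-passed windows of one recording."""
    config = config or PipelineConfig()
    return [
        extract_features(t, bins=config.entropy_bins)
        for t in windows_of(rec, config)
        if t.qc_pass
    ]


def cohort_lag_matrix(
    recordings: Sequence[Recording], config: PipelineConfig | None = None
) -> LagMatrix:
    """Full cohort pipeline: features per subject, then the lag matrix."""
    config = config or PipelineConfig()
    rows: list[FeatureRow] = []
    for rec in recordings:
        rows.extend(features_of(rec, config))
    return build_lag_matrix(rows, lags=config.lags)
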