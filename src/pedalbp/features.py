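"""Peak-independent feature bank and temporal lag matrix.

Per retained window, five feature families are computed, none requiring
beat detection:

* distributional statistics (mean, SD, median, IQR, skewness) of the
  normalized PPG and of its VPG and APG;
* window energy E = Σx² of the normalized PPG, plus a kinetic-energy
  descriptor KTE = (dx/dt)² summarized by its interquartile range;
* Shannon entropy of the amplitude histograms of PPG and APG;
* zero-crossing counts of VPG and APG.

Because windows are z-scored with the population-SD convention, the PPG
energy sum is identically the window length; it is stored for completeness
but excluded from the default modeling feature set, leaving 20 informative
base features. The lag matrix augments each window's vector with the same
features from the 1–3 preceding windows (5–15 s of hemodynamic memory at
the 5 s step); rows whose history is incomplete — including gaps left by
QC rejection — are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .derivatives import WindowTriplet, vpg_of

__all__ = [
    "FeatureRow",
    "LagMatrix",
    "stat_features",
    "energy",
    "kte_series",
    "kte_iqr",
    "teager_kaiser_series",
    "shannon_entropy",
    "zcr",
    "extract_features",
    "build_lag_matrix",
    "MODEL_FEATURES",
    "ENTROPY_BINS_DEFAULT",
    "LAGS_DEFAULT",
]

log = logging.getLogger(__name__)

ENTROPY_BINS_DEFAULT = 16
LAGS_DEFAULT = (1, 2, 3)

# Default modeling feature set: every base feature except the normalized-PPG
# energy sum, which is constant (= window length) under the population-SD
# z-score convention and therefore carries no information.
MODEL_FEATURES: tuple[str, ...] = tuple(
    f"{m}_{s}" for m in ("ppg", "vpg", "apg") for s in ("mean", "sd", "median", "iqr", "skew")
) + ("ppg_kte_iqr", "ppg_entropy_bits", "apg_entropy_bits", "vpg_zcr", "apg_zcr")


def stat_features(x: np.ndarray) -> dict[str, float]:
    """Mean, population SD, median, IQR, and population skewness of a series.

    Quantiles use linear interpolation; skewness is the standardized third
    central moment and is defined as 0 (with a log note) for a flat series.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for distributional statistics")
    mean = float(np.mean(x))
    sd = float(np.std(x))
    q25, q75 = np.percentile(x, [25, 75])
    if sd < 1e-12:
        log.info("degenerate series: skewness defined as 0")
        skew = 0.0
    else:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
    return {
        "mean": mean,
        "sd": sd,
        "median": float(np.median(x)),
        "iqr": float(q75 - q25),
        "skew": skew,
    }


def energy(x: np.ndarray) -> float:
    """Window energy Σ x(t)² of a (normalized) series."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def kte_series(x: np.ndarray, fs: float) -> np.ndarray:
    """Per-sample kinetic-energy descriptor (dx/dt)², via the smoothed VPG."""
    v = vpg_of(np.asarray(x, dtype=float), fs)
    return v * v


def kte_iqr(x: np.ndarray, fs: float) -> float:
    """Interquartile range of the kinetic-energy series — the retained
    dispersion statistic, robust to contact-pressure scaling."""
    k = kte_series(x, fs)
    q25, q75 = np.percentile(k, [25, 75])
    return float(q75 - q25)


def teager_kaiser_series(x: np.ndarray) -> np.ndarray:
    """Classical discrete Teager–Kaiser operator x(t)² − x(t−1)·x(t+1).

    Optional alternative to the squared-derivative kinetic-energy series;
    endpoints are padded by replication so the length matches the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    core = x[1:-1] ** 2 - x[:-2] * x[2:]
    return np.concatenate([[core[0]], core, [core[-1]]])


def shannon_entropy(x: np.ndarray, bins: int = ENTROPY_BINS_DEFAULT) -> float:
    """Shannon entropy (bits) of the amplitude histogram over [min, max].

    Equal-width bins; a flat series (range below 1e-12) has zero entropy.
    The value is bounded by log2(bins).
    """
    x = np.asarray(x, dtype=float)
    if x.size < bins:
        raise ValueError(f"need at least {bins} samples for {bins} bins")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def zcr(x: np.ndarray) -> int:
    """Number of strict sign changes between consecutive samples.

    Exact zeros inherit the previous nonzero sign (leading zeros are
    skipped), so grazing the axis does not count as a crossing.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


@dataclass
class FeatureRow:
    """Named feature map for one QC-passed window, with its labels."""

    subject_id: str
    window_index: int
    start_s: float
    sbp_ref: float
    dbp_ref: float
    features: dict[str, float]


def extract_features(w: WindowTriplet, bins: int = ENTROPY_BINS_DEFAULT) -> FeatureRow:
    """Assemble the full named feature map for one window.

    Refuses QC-failed windows: features are only defined on windows whose
    statistics are physiologically plausible and whose normalization is
    well-posed.
    """
    if not w.qc_pass:
        raise ValueError(
            f"window {w.subject_id}/{w.window_index} failed QC ({w.qc_reasons}); "
            "features are not extracted from rejected windows"
        )
    feats: dict[str, float] = {}
    for name, series in (("ppg", w.ppg), ("vpg", w.vpg), ("apg", w.apg)):
        for stat, value in stat_features(series).items():
            feats[f"{name}_{stat}"] = value
    feats["ppg_energy"] = energy(w.ppg)
    k = w.vpg * w.vpg  # kinetic-energy series from the already-smoothed VPG
    q25, q75 = np.percentile(k, [25, 75])
    feats["ppg_kte_iqr"] = float(q75 - q25)
    feats["ppg_entropy_bits"] = shannon_entropy(w.ppg, bins=bins)
    feats["apg_entropy_bits"] = shannon_entropy(w.apg, bins=bins)
    feats["vpg_zcr"] = float(zcr(w.vpg))
    feats["apg_zcr"] = float(zcr(w.apg))
    if not all(np.isfinite(v) for v in feats.values()):
        bad = [k_ for k_, v in feats.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite features {bad} in window {w.window_index}")
    return FeatureRow(
        subject_id=w.subject_id,
        window_index=w.window_index,
        start_s=w.start_s,
        sbp_ref=w.sbp_ref,
        dbp_ref=w.dbp_ref,
        features=feats,
    )


@dataclass
class LagMatrix:
    """Lag-augmented design matrix with aligned targets and subject groups.

    ``X`` holds one row per emitted window with columns ``<feature>`` for
    the base features and ``<feature>_lag<k>`` for each lagged copy;
    ``meta`` carries subject_id, window_index, start_s, sbp, dbp row-aligned
    with ``X``.
    """

    X: pd.DataFrame
    meta: pd.DataFrame
    base_features: tuple[str, ...]
    lags: tuple[int, ...]
    lag_features: tuple[str, ...]

    @property
    def groups(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    def targets(self, which: str) -> np.ndarray:
        if which not in ("sbp", "dbp"):
            raise ValueError("target must be 'sbp' or 'dbp'")
        return self.meta[which].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.X)

    def frame(self) -> pd.DataFrame:
        """Single flat table (meta + design columns) for CSV export."""
        return pd.concat(
            [self.meta.reset_index(drop=True), self.X.reset_index(drop=True)], axis=1
        )


def build_lag_matrix(
    rows: Iterable[FeatureRow],
    lags: Sequence[int] = LAGS_DEFAULT,
    lag_features: Sequence[str] | None = None,
    base_features: Sequence[str] = MODEL_FEATURES,
) -> LagMatrix:
    """Assemble the temporal lag matrix from per-window feature rows.

    For each subject (rows sorted by window index), window t is emitted
    only when windows t−1 … t−max(lags) all exist contiguously; QC gaps
    break contiguity, so no value is ever interpolated across a rejected
    window. Lagged columns are exact copies of the earlier windows'
    base values.
    """
    lags = tuple(sorted(int(k) for k in lags))
    if any(k < 1 for k in lags):
        raise ValueError("lags must be positive integers")
    base_features = tuple(base_features)
    lag_features = tuple(lag_features) if lag_features is not None else base_features
    unknown = set(lag_features) - set(base_features)
    if unknown:
        raise ValueError(f"lag_features not in base set: {sorted(unknown)}")
    max_lag = max(lags) if lags else 0

    by_subject: dict[str, list[FeatureRow]] = {}
    for row in rows:
        by_subject.setdefault(row.subject_id, []).append(row)

    records: list[dict[str, float]] = []
    meta: list[dict[str, object]] = []
    for subject_id in sorted(by_subject):
        srows = sorted(by_subject[subject_id], key=lambda r: r.window_index)
        by_index = {r.window_index: r for r in srows}
        if len(by_index) != len(srows):
            raise ValueError(f"duplicate window indices for subject {subject_id}")
        emitted = 0
        for r in srows:
            history = [by_index.get(r.window_index - j) for j in range(1, max_lag + 1)]
            if any(h is None for h in history):
                continue
            rec = {name: r.features[name] for name in base_features}
            for k in lags:
                prev = by_index[r.window_index - k]
                for name in lag_features:
                    rec[f"{name}_lag{k}"] = prev.features[name]
            records.append(rec)
            meta.append(
                {
                    "subject_id": subject_id,
                    "window_index": r.window_index,
                    "start_s": r.start_s,
                    "sbp": r.sbp_ref,
                    "dbp": r.dbp_ref,
                }
            )
            emitted += 1
        if emitted == 0:
            log.info(
                "subject %s contributes no rows (needs %d contiguous windows)",
                subject_id,
                max_lag + 1,
            )

    columns = list(base_features) + [
        f"{name}_lag{k}" for k in lags for name in lag_features
    ]
    X = pd.DataFrame.from_records(records, columns=columns) if records else pd.DataFrame(
        columns=columns
    )
    meta_frame = pd.DataFrame.from_records(
        meta, columns=["subject_id", "window_index", "start_s", "sbp", "dbp"]
    )
    lm = LagMatrix(
        X=X,
        meta=meta_frame,
        base_features=base_features,
        lags=lags,
        lag_features=lag_features,
    )
    _audit_lag_consistency(lm, by_subject)
    return lm


def _audit_lag_consistency(lm: LagMatrix, by_subject: dict[str, list[FeatureRow]]) -> None:
    """Verify on every build that lag-k columns equal the base values of the
    window k steps earlier. A violation is a construction bug and aborts."""
    if len(lm.X) == 0 or not lm.lags:
        return
    base = pd.DataFrame.from_records(
        [
            {"subject_id": r.subject_id, "window_index": r.window_index, **r.features}
            for srows in by_subject.values()
            for r in srows
        ]
    ).set_index(["subject_id", "window_index"])
    for k in lm.lags:
        idx = list(zip(lm.meta["subject_id"], lm.meta["window_index"] - k))
        expected = base.loc[idx, list(lm.lag_features)].to_numpy()
        actual = lm.X[[f"{name}_lag{k}" for name in lm.lag_features]].to_numpy()
        if not np.array_equal(expected, actual):
            raise AssertionError(f"lag consistency violated for lag {k}")
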