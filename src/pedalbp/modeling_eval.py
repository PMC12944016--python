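"""Regressors, leakage-safe dual evaluation protocols, and agreement analysis.

Because every window of a subject shares one cuff label, naive K-fold
would leak near-duplicate windows across the train/test split. Two
protocols bracket the clinically relevant scenarios:

* **diagnosis** — subject-independent grouped K-fold: all windows of a
  subject land in exactly one test fold and the train/test subject sets
  are disjoint in every fold (audited on every run). Headline metrics are
  subject-level, after median aggregation of a subject's window
  predictions.
* **monitoring** — window-level stratified K-fold, strata being the
  clinical BP category of each window's subject. Windows of one subject
  may span train and test by design: this emulates personalized tracking
  after a single cuff calibration. Headline metrics are window-level.

Both reports also carry the other level's metrics, Bland–Altman agreement
(bias ± 1.96·SD limits), and physiological reliability flags.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process import kernels as gpk
from sklearn.model_selection import StratifiedKFold

from .features import LagMatrix
from .io_formats import DBP_RANGE, SBP_RANGE

__all__ = [
    "BPCategory",
    "bp_category",
    "rq_kernel",
    "ModelSpec",
    "EvaluationReport",
    "fit_predict",
    "grouped_subject_folds",
    "diagnosis_eval",
    "monitoring_eval",
    "aggregate_subject",
    "metrics",
    "bland_altman",
    "reliability_check",
]

log = logging.getLogger(__name__)


class BPCategory(enum.Enum):
    """Clinical blood-pressure category (ACC/AHA-style cut points)."""

    NORMAL = "normal"
    ELEVATED = "elevated"
    STAGE1 = "stage1"
    STAGE2 = "stage2"


def bp_category(sbp: float, dbp: float) -> BPCategory:
    """Classify a pressure pair: stage 2 if SBP ≥ 140 or DBP ≥ 90; stage 1
    if SBP ≥ 130 or DBP ≥ 80; elevated if SBP ≥ 120 (with DBP < 80);
    normal otherwise."""
    if sbp >= 140 or dbp >= 90:
        return BPCategory.STAGE2
    if sbp >= 130 or dbp >= 80:
        return BPCategory.STAGE1
    if sbp >= 120:
        return BPCategory.ELEVATED
    return BPCategory.NORMAL


def rq_kernel(
    x: np.ndarray,
    x2: np.ndarray,
    sigma2: float = 1.0,
    length_scale: float = 1.0,
    alpha: float = 1.0,
) -> float:
    """Rational-quadratic covariance σ²(1 + ‖x−x′‖²/(2αl²))^(−α).

    A scale mixture of RBF kernels over length scales; in the α → ∞ limit
    it converges to the RBF kernel with length scale l.
    """
    if sigma2 <= 0 or length_scale <= 0 or alpha <= 0:
        raise ValueError("sigma2, length_scale, alpha must be positive")
    d2 = float(np.sum((np.asarray(x, float) - np.asarray(x2, float)) ** 2))
    return float(sigma2 * (1.0 + d2 / (2.0 * alpha * length_scale**2)) ** (-alpha))


@dataclass
class ModelSpec:
    """Regressor family and hyperparameters.

    ``M`` is the ensemble size (trees); ``eta`` the boosting learning rate;
    the Gaussian-process fields initialize the kernel before
    marginal-likelihood optimization. One seed governs all model
    randomness and fold shuffling.
    """

    family: str = "extra_trees"
    M: int = 500
    eta: float = 0.05
    kernel: str = "rational_quadratic"
    sigma2: float = 1.0
    length_scale: float = 1.0
    alpha: float = 1.0
    noise_level: float = 1.0  # mmHg², additive white-noise kernel term
    n_restarts: int = 5
    seed: int = 0

    _FAMILIES = ("random_forest", "extra_trees", "gradient_boosting", "gaussian_process")
    _KERNELS = ("rbf", "rational_quadratic", "matern52")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"family must be one of {self._FAMILIES}")
        if self.kernel not in self._KERNELS:
            raise ValueError(f"kernel must be one of {self._KERNELS}")
        if self.M < 1 or not (0 < self.eta <= 1):
            raise ValueError("need M >= 1 and 0 < eta <= 1")
        if min(self.sigma2, self.length_scale, self.alpha) <= 0:
            raise ValueError("sigma2, length_scale, alpha must be positive")

    def build(self):
        if self.family == "random_forest":
            return RandomForestRegressor(n_estimators=self.M, random_state=self.seed, n_jobs=1)
        if self.family == "extra_trees":
            return ExtraTreesRegressor(n_estimators=self.M, random_state=self.seed, n_jobs=1)
        if self.family == "gradient_boosting":
            return GradientBoostingRegressor(
                n_estimators=self.M, learning_rate=self.eta, random_state=self.seed
            )
        base = {
            "rbf": gpk.RBF(length_scale=self.length_scale),
            "rational_quadratic": gpk.RationalQuadratic(
                length_scale=self.length_scale, alpha=self.alpha
            ),
            "matern52": gpk.Matern(length_scale=self.length_scale, nu=2.5),
        }[self.kernel]
        kernel = gpk.ConstantKernel(self.sigma2) * base + gpk.WhiteKernel(
            noise_level=self.noise_level
        )
        return GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=self.n_restarts,
            random_state=self.seed,
        )


def fit_predict(
    model: ModelSpec,
    X_train: np.ndarray | pd.DataFrame,
    y_train: np.ndarray,
    X_test: np.ndarray | pd.DataFrame,
) -> np.ndarray:
    """Train one regressor and return its window-level predictions (mmHg).

    Zero-variance training columns are dropped (from both splits) with a
    log entry; predictions are deterministic given the spec's seed.
    """
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.asarray(X_test, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if Xtr.ndim != 2 or Xte.ndim != 2 or Xtr.shape[1] != Xte.shape[1]:
        raise ValueError("X_train and X_test must be 2-D with matching columns")
    keep = Xtr.std(axis=0) > 0
    if not keep.all():
        log.info("dropping %d zero-variance columns", int((~keep).sum()))
        Xtr, Xte = Xtr[:, keep], Xte[:, keep]
    if Xtr.shape[1] == 0:
        return np.full(Xte.shape[0], float(np.mean(y)))
    est = model.build()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # GP convergence chatter
        est.fit(Xtr, y)
        return np.asarray(est.predict(Xte), dtype=float)


def aggregate_subject(window_preds: Sequence[float]) -> float:
    """Median of a subject's window predictions (midpoint for even counts).

    The median resists outlier windows from transient motion artifacts
    better than the mean."""
    preds = np.asarray(window_preds, dtype=float)
    if preds.size == 0:
        raise ValueError("no window predictions to aggregate")
    return float(np.median(preds))


def metrics(y: Sequence[float], y_hat: Sequence[float]) -> tuple[float, float, float]:
    """(MAE, RMSE, R²) of predictions against references, both in mmHg."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 pairs")
    err = y - y_hat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot <= 0:
        raise ValueError("variance of y is zero; R² undefined")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return mae, rmse, r2


def bland_altman(y: Sequence[float], y_hat: Sequence[float]) -> tuple[float, float, float]:
    """Agreement summary: bias and ±1.96·SD limits of the differences ŷ − y
    (sample SD, divisor n−1)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need equal-length arrays of at least 2")
    d = y_hat - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class EvaluationReport:
    """Everything one protocol run produced, serializable to JSON."""

    protocol: str  # "diagnosis" | "monitoring"
    target: str  # "sbp" | "dbp"
    folds: int
    window_level: dict[str, float]
    subject_level: dict[str, float]
    per_subject: list[dict]
    bland_altman: dict[str, float]
    fold_assignments: dict[str, list]
    reliability_flags: list[dict]
    config: dict

    def __post_init__(self) -> None:
        for level in (self.window_level, self.subject_level):
            if level and level["mae"] > level["rmse"] + 1e-9:
                raise AssertionError("MAE exceeded RMSE — metric computation bug")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def grouped_subject_folds(
    groups: np.ndarray, K: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-disjoint K-fold: shuffle subjects with the run seed, deal
    them round-robin into K folds, and return (train_idx, test_idx) pairs.

    Disjointness of train/test subject sets is audited for every fold; a
    violation aborts the run.
    """
    groups = np.asarray(groups)
    subjects = np.unique(groups)
    if subjects.size < K:
        raise ValueError(f"need at least K={K} subjects, got {subjects.size}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    folds = [order[k::K] for k in range(K)]
    splits = []
    for test_subjects in folds:
        test_mask = np.isin(groups, test_subjects)
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        train_set = set(groups[train_idx])
        test_set = set(groups[test_idx])
        if train_set & test_set:
            raise AssertionError("subject leakage across a grouped fold — aborting")
        splits.append((train_idx, test_idx))
    return splits


def _merged_strata(sbp: np.ndarray, dbp: np.ndarray, K: int) -> np.ndarray:
    """Per-row BP-category labels, merging categories with fewer than K
    windows into the adjacent lower-severity category (with a warning)."""
    order = [BPCategory.NORMAL, BPCategory.ELEVATED, BPCategory.STAGE1, BPCategory.STAGE2]
    labels = np.array([bp_category(s, d).value for s, d in zip(sbp, dbp)], dtype=object)
    names = [c.value for c in order]
    merged = {n: n for n in names}
    # Repeatedly fold the smallest under-populated stratum into its neighbor.
    for _ in range(len(names)):
        counts = pd.Series(
            [merged[lbl] for lbl in labels], dtype=object
        ).value_counts()
        small = [n for n in names if 0 < counts.get(merged[n], 0) < K and merged[n] == n]
        if not small:
            break
        victim = small[0]
        i = names.index(victim)
        neighbor = names[i - 1] if i > 0 else names[i + 1]
        log.warning("BP category %r has < %d windows; merging into %r", victim, K, neighbor)
        for n in names:
            if merged[n] == victim:
                merged[n] = merged[neighbor]
    out = np.array([merged[lbl] for lbl in labels], dtype=object)
    counts = pd.Series(out, dtype=object).value_counts()
    if (counts < K).any():
        raise ValueError(f"stratum smaller than K={K} even after merging: {dict(counts)}")
    return out


def reliability_check(
    target: str,
    meta: pd.DataFrame,
    window_preds: np.ndarray,
    sd_max: float = 15.0,
    jump_max: float = 20.0,
) -> list[dict]:
    """Physiological plausibility flags over window-level predictions.

    Flags (never removes) predictions outside the plausibility gate,
    subjects whose prediction SD exceeds ``sd_max`` mmHg, and
    consecutive-window jumps larger than ``jump_max`` mmHg.
    """
    lo, hi = SBP_RANGE if target == "sbp" else DBP_RANGE
    flags: list[dict] = []
    for sid, grp in meta.assign(pred=window_preds).groupby("subject_id", sort=True):
        grp = grp.sort_values("window_index")
        preds = grp["pred"].to_numpy()
        for wi, p in zip(grp["window_index"], preds):
            if not (lo <= p <= hi):
                flags.append(
                    {"subject_id": sid, "window_index": int(wi), "flag": "implausible",
                     "value": float(p)}
                )
        if preds.size >= 2 and float(np.std(preds, ddof=1)) > sd_max:
            flags.append(
                {"subject_id": sid, "flag": "intra_subject_sd",
                 "value": float(np.std(preds, ddof=1))}
            )
        jumps = np.abs(np.diff(preds))
        for j, (w0, w1) in enumerate(zip(grp["window_index"][:-1], grp["window_index"][1:])):
            if w1 == w0 + 1 and jumps[j] > jump_max:
                flags.append(
                    {"subject_id": sid, "window_index": int(w1), "flag": "jump",
                     "value": float(jumps[j])}
                )
    return flags


def _levels(
    meta: pd.DataFrame, y: np.ndarray, preds: np.ndarray
) -> tuple[dict, dict, list[dict]]:
    """Window- and subject-level metric dicts plus the per-subject table."""
    w_mae, w_rmse, w_r2 = metrics(y, preds)
    window_level = {"mae": w_mae, "rmse": w_rmse, "r2": w_r2}
    per_subject = []
    for sid, grp in meta.assign(pred=preds, y=y).groupby("subject_id", sort=True):
        per_subject.append(
            {
                "subject_id": sid,
                "y": float(grp["y"].iloc[0]),
                "y_hat": aggregate_subject(grp["pred"].to_numpy()),
                "n_windows": int(len(grp)),
            }
        )
    ys = [p["y"] for p in per_subject]
    yhats = [p["y_hat"] for p in per_subject]
    if len(per_subject) >= 2 and np.std(ys) > 0:
        s_mae, s_rmse, s_r2 = metrics(ys, yhats)
        subject_level = {"mae": s_mae, "rmse": s_rmse, "r2": s_r2}
    else:
        subject_level = {}
    return window_level, subject_level, per_subject


def diagnosis_eval(
    lagmat: LagMatrix, model: ModelSpec, K: int = 5, target: str = "sbp"
) -> EvaluationReport:
    """Subject-independent grouped K-fold evaluation (no calibration).

    Every subject is tested exactly once, by a model that never saw any of
    that subject's windows. Headline metrics are subject-level after median
    aggregation; Bland–Altman agreement is computed on the subject level.
    """
    y = lagmat.targets(target)
    groups = lagmat.groups
    splits = grouped_subject_folds(groups, K, model.seed)
    preds = np.full(len(lagmat), np.nan)
    fold_assignments: dict[str, list] = {}
    for k, (train_idx, test_idx) in enumerate(splits):
        preds[test_idx] = fit_predict(
            model, lagmat.X.iloc[train_idx], y[train_idx], lagmat.X.iloc[test_idx]
        )
        fold_assignments[str(k)] = sorted(set(groups[test_idx]))
    assert not np.isnan(preds).any()

    window_level, subject_level, per_subject = _levels(lagmat.meta, y, preds)
    ys = [p["y"] for p in per_subject]
    yhats = [p["y_hat"] for p in per_subject]
    bias, lo, hi = bland_altman(ys, yhats)
    return EvaluationReport(
        protocol="diagnosis",
        target=target,
        folds=K,
        window_level=window_level,
        subject_level=subject_level,
        per_subject=per_subject,
        bland_altman={"bias": bias, "loa_low": lo, "loa_high": hi},
        fold_assignments=fold_assignments,
        reliability_flags=reliability_check(target, lagmat.meta, preds),
        config=dataclasses.asdict(model),
    )


def monitoring_eval(
    lagmat: LagMatrix, model: ModelSpec, K: int = 5, target: str = "sbp"
) -> EvaluationReport:
    """Subject-calibrated stratified K-fold evaluation (window level).

    Strata are the clinical BP categories of each window's subject, so
    every fold preserves the cohort's pressure distribution; windows of one
    subject may appear in both train and test, emulating personalized
    tracking after a cuff calibration. Headline metrics and Bland–Altman
    agreement are window-level.
    """
    y = lagmat.targets(target)
    strata = _merged_strata(
        lagmat.meta["sbp"].to_numpy(), lagmat.meta["dbp"].to_numpy(), K
    )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=model.seed)
    preds = np.full(len(lagmat), np.nan)
    fold_assignments: dict[str, list] = {}
    for k, (train_idx, test_idx) in enumerate(skf.split(lagmat.X, strata)):
        preds[test_idx] = fit_predict(
            model, lagmat.X.iloc[train_idx], y[train_idx], lagmat.X.iloc[test_idx]
        )
        fold_assignments[str(k)] = [int(i) for i in test_idx]
    assert not np.isnan(preds).any()

    window_level, subject_level, per_subject = _levels(lagmat.meta, y, preds)
    bias, lo, hi = bland_altman(y, preds)
    return EvaluationReport(
        protocol="monitoring",
        target=target,
        folds=K,
        window_level=window_level,
        subject_level=subject_level,
        per_subject=per_subject,
        bland_altman={"bias": bias, "loa_low": lo, "loa_high": hi},
        fold_assignments=fold_assignments,
        reliability_flags=reliability_check(target, lagmat.meta, preds),
        config=dataclasses.asdict(model),
    )
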