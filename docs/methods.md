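# Methods

## Problem setting

Distal (foot) PPG waveforms are attenuated and easily distorted by motion,
which makes classical fiducial-point pipelines (systolic peak, dicrotic
notch, APG a–e waves) unreliable. pedalbp therefore treats each 30 s
window as a statistical object: every feature is a functional of the full
sample distribution of the normalized PPG and its derivatives, and the
mapping to blood pressure is learned by ensemble regression. Reference
pressures exist only at the subject level (one cuff measurement per
recording), so all windows of a subject share one label — the central
methodological hazard is label leakage through overlapping, near-duplicate
windows, and the evaluation design exists to control it.

## Signal conditioning

* **Detrending** is a single least-squares line over the whole recording.
  The slow drift it targets (sensor settling, posture) is approximately
  linear over 2–6 min; anything oscillatory below 0.4 Hz is left to the
  bandpass. Polynomial or moving-average detrending would also be
  defensible; linear was fixed for transparency.
* **Bandpass**: Chebyshev type-II, stopband edges 0.4 and 8 Hz, order 4
  per pass, 40 dB stopband attenuation, applied forward–backward
  (`sosfiltfilt`, odd-symmetric padding). The backward pass cancels phase
  distortion — essential because the features live on derivatives — and
  squares the magnitude response, so effective stopband rejection is
  80 dB. Measured single-sided behaviour: DC leakage < 1e−3, gain 0.99 at
  the 1 Hz cardiac fundamental, < 1e−5 at 20 Hz. The 0.4 Hz edge rings
  for several seconds; filtering whole recordings (not windows) keeps
  these transients out of the analysis windows.
* **Normalization** is per-window z-scoring with the *population* (1/N)
  standard deviation. The divisor is a convention choice; population SD
  was fixed because it gives the exact identity Σx² = N used to validate
  the energy features, and because window lengths (3000 samples) make the
  1/N vs 1/(N−1) difference negligible for modeling.

Pipeline order is fixed: detrend → filter → segment → QC → normalize.

## Windowing and quality control

Windows are 30 s long with a 5 s step (half-open intervals, 0-based
indices), giving ⌊(N−3000)/500⌋+1 windows per recording at 100 Hz. QC is
peak-independent and self-referential: a window is compared with the
median peak-to-peak amplitude and median variance of its *own* recording's
windows. Defaults — amplitude ratio outside [0.2, 5], variance ratio > 9,
or more than 5% of |APG| samples above q3 + 5·IQR — reject the synthetic
generator's ×3–×8 artifact bursts while passing clean windows (0% false
rejections at zero artifact rate in the shipped tests). Because the
reference is the recording's own median, QC saturates if artifacts
dominate a recording: rejection rises monotonically with artifact rate up
to roughly 2 bursts/min at these settings, then flattens. All thresholds
are exposed in configuration.

## Features and lag matrix

Twenty informative base features per window: five distributional
statistics (mean, population SD, median, IQR with linear-interpolation
quantiles, population skewness) for each of PPG/VPG/APG; the
kinetic-energy dispersion KTE-IQR (IQR of the squared smoothed first
derivative); Shannon entropy (bits, 16 equal-width amplitude bins —
the bin count is a fixed convention, configurable) of PPG and APG; and
strict-sign-change counts of VPG and APG (exact zeros inherit the previous
sign). The PPG energy sum Σx² is also computed and stored, but excluded
from the default modeling set: under the population-SD z-score convention
it is identically the window length and carries no information. The
classical Teager–Kaiser operator x(t)² − x(t−1)x(t+1) is available as a
configurable alternative to the squared-derivative kinetic-energy series.

Derivatives are central finite differences scaled by fs (one-sided at
window ends so lengths stay aligned), each followed by Savitzky–Golay
smoothing of polynomial order 3 and frame length 11; the APG applies the
same scheme to the smoothed VPG. Order-3 frames preserve cubic trends
exactly, so smooth waveform morphology passes through undistorted.

The lag matrix augments each window's 20 features with exact copies from
windows t−1, t−2, t−3 — 5, 10, 15 s of history at the 5 s step — for an
80-column design matrix. All base features are lagged by default (a
whitelist is accepted); rows are emitted only when the full contiguous
history exists, and QC gaps break contiguity rather than being
interpolated across. Lag-shift consistency is re-audited on every build.

## Models and evaluation

Four regressor families (random forest, extra trees, gradient boosting,
Gaussian process with RBF / rational-quadratic / Matérn-5/2 kernels), each
trained separately for SBP and DBP. Defaults: 500 trees (300 in the
acceptance script for speed), boosting learning rate 0.05, GP kernel
initialized at σ² = 1, l = 1, α = 1 with an additive 1 mmHg² white-noise
term and five restart optimizations of the marginal likelihood. Trees are
scale-invariant, so features are not re-standardized. Zero-variance
training columns are dropped with a log entry. One seed governs tree
randomness and all fold shuffling and is recorded in every report.

* **Diagnosis protocol** (first use, no calibration): K = 5 grouped folds
  built by seeded subject shuffle and round-robin assignment; subject
  disjointness of every train/test split is asserted at run time. Headline
  metrics are subject-level after median aggregation of window predictions
  (the median's 50% breakdown point absorbs outlier windows).
* **Monitoring protocol** (after one cuff calibration): stratified K-fold
  at the window level, strata being ACC/AHA-style categories (stage 2 if
  SBP ≥ 140 or DBP ≥ 90; stage 1 if SBP ≥ 130 or DBP ≥ 80; elevated if
  SBP ≥ 120 with DBP < 80; normal otherwise). Categories with fewer than
  K windows are merged into the adjacent category with a warning. Headline
  metrics are window-level; both levels are always reported.

K = 5 balances fold size against cohort sizes of a few dozen subjects.
Reports include Bland–Altman agreement (bias, bias ± 1.96 × sample SD of
the differences) and reliability flags: predictions outside the
physiological gate (40–260 / 20–160 mmHg), subjects with window-prediction
SD > 15 mmHg, and consecutive-window jumps > 20 mmHg. Flags are reported,
never silently removed.

## Synthetic cohort generator

Each subject draws SBP ~ U[95, 175] and DBP ~ U[55, 105] mmHg (resampled
until DBP < SBP − 15), spanning normotensive through stage-2 ranges;
uniform sampling keeps all strata populated at small n. Beats are sums of
two Gaussians: a unit systolic pulse whose width
w_s = 0.09·(1 − c_sbp·(SBP−120)/120) s narrows with SBP (clipped to
[0.25, 2]×base), and a broader reflected pulse at 0.35 of the beat period
with amplitude 0.4 + c_dbp·(DBP−80)/80 (clipped to [0, 0.9]). Heart rate
is N(70, 8) bpm per subject; beat intervals jitter with CV 0.04. Nuisances:
two baseline-wander sinusoids in 0.05–0.3 Hz (total amplitude 0.3 of the
pulse), white noise of SD 0.05, and Poisson artifact bursts (0.5/min,
1–3 s, ×3–×8 multiplicative). Default coupling gains are 0.5. Everything
is reproducible from (config, seed, subject index).

The generator emulates exactly what the pipeline's claims need — monotone
BP-to-morphology coupling plus realistic nuisance structure — and nothing
more. It has no Windkessel dynamics, no respiratory modulation, no
intra-recording BP variation, and its within-subject windows are far more
self-similar than real physiology. Consequently, passing tests demonstrate
that the pipeline recovers coupled morphology, respects subject
separation, and orders the two protocols correctly; they do not establish
clinical accuracy on real recordings, and the absolute errors it yields
(diagnosis MAE ≈ 3–4 mmHg SBP at default settings) are optimistic relative
to what heterogeneous human data produce.

## Problem sizes and numerical conventions

The shipped tests and the acceptance script use cohorts of 40 subjects ×
150 s (≈ 1000 segmented windows, ≈ 740 lag-matrix rows) and 56 × 90 s for
the fold audit, with 300-tree ensembles — sizes at which every property
under test is already stable. Degenerate inputs are handled explicitly:
flat windows raise a degeneracy error in normalization and are QC-rejected
("degenerate"); flat series get skewness 0 with a log note and entropy 0;
constant targets make R² undefined and raise. Quantiles use linear
interpolation throughout; Bland–Altman uses the sample (n−1) SD, metric
definitions the plain means.

## Known limitations

Single subject-level label per recording (no within-subject BP dynamics to
learn or test against); no adaptive or transfer calibration; no
frequency-domain or beat-segmented features by design; no permutation
feature importances; QC thresholds calibrated against the synthetic
artifact model only.
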