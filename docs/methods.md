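# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices in `rollgait`, in the spirit of a package methods section.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stability outcomes

The pipeline predicts two per-trial outcomes of lateral balance control
during treadmill walking under platform roll:

* **Peak COM excursion** (m): the maximum absolute deviation of the
  mediolateral center-of-mass position from its trial mean. Other readings
  of "peak excursion" exist (per-stride peak-to-peak, condition-pooled); the
  trial-level maximum deviation is the simplest scalar consistent with
  "peak" and is what `stability.peak_com_excursion` implements.
* **MOS variability** (m): the sample SD (ddof = 1) of the margin of
  stability evaluated at right heel strikes only. The MOS at a right heel
  strike is `boundary − XCOM`, signed so that positive means the
  extrapolated COM lies medial to (inside) the lateral base-of-support
  boundary. `XCOM = y + v/ω₀` with `ω₀ = √(g/ℓ)`; the pendulum length is the
  subject's leg length and `g = 9.81 m/s²`.

Both are computed from gold-standard kinematics (in a real study: motion
capture; here: the generator's planted COM/BOS series), never from the
accelerometer — the accelerometer side only ever produces features.

## Step detection and features

Heel strikes are the local maxima of vertical pelvis acceleration subject to
a minimum separation (default 0.4 s) and a minimum prominence. The default
prominence is scale-aware: half the spread between the channel's 95th
percentile and its median, which rejects the smooth gait oscillation while
keeping every impact transient, and leaves detections invariant under
positive rescaling of the signal. Side labels alternate; the first step's
side is read from the sign of its mean lateral acceleration (positive =
rightward by convention — some convention is required because the right-limb
MOS needs sides, and a single pelvis sensor carries no intrinsic label).

Within each half-open step window `[hs_i, hs_{i+1})` the phase sub-windows
are fixed fractions: initial 10%, double stance = first 20%, mid-stance =
30–60%. Published double-support and single-support proportions motivate the
20% and 30–60% figures; both are configurable (`PhaseFractions`) because
they are conventions, not measurements. Steps shorter than 10 samples raise
a window-degeneracy error.

Per step, 20 base features: windowed means of the resultant magnitude
`√(ml² + vt² + ap²)` or of a single axis' absolute value ("vector magnitude"
is read as a mean, not an RMS or integral; RMS is available via
`magnitude="rms"`); signed per-axis values at the heel-strike sample;
per-axis population SDs over the initial 10% window (population rather than
sample SD so the statistic stays defined for very short windows); and step
time. Trial-level aggregation: `aX` = mean across steps, `vX` = sample SD
across steps (CV available via `variability="cv"`), and the symmetry index
`sX = |mean_L − mean_R| / |0.5 (mean_L + mean_R)|` with 0 for a zero
denominator — the standard gait symmetry index. Feature tables are centered
per column; inside validation, test rows are centered with *training* means
so no test-set statistic ever reaches the model.

## Feature selection

* **LASSO / elastic net** — the penalty is expressed in
  "added-to-raw-RSS" units: `RSS + λ‖β‖₁` and
  `RSS + λ(α‖β‖₁ + (1−α)‖β‖₂²/2)`, so α = 1 reduces to the LASSO at the same
  λ and, on an orthonormal design, the LASSO solution is the soft-thresholded
  least-squares estimate `sign(b)(|b| − λ/2)₊`. Internally this maps to
  scikit-learn's per-sample convention as `alpha = λ/(2n)`, `l1_ratio = α`.
  When λ is not fixed it is chosen by 10-fold cross-validation over 60
  automatic log-spaced values. Features are standardized to unit variance
  inside the estimator; coefficients are reported back on the centered
  feature scale, but the *ranking* uses the standardized-scale magnitudes —
  otherwise small-scale features (e.g. symmetry indices, typically ~10⁻²)
  would dominate a raw-coefficient ranking and the ordering would change
  under unit changes. `standardize=False` reproduces unscaled behaviour.
* **F-test** — per-feature univariate regression F-test; ranked by ascending
  p-value, ties broken by larger F; zero-variance features get p = 1 and
  rank last.
* **RReliefF** — the regression Relief variant. For each instance, its k
  nearest neighbours (default k = 10) by Manhattan distance on
  min-max-normalized features receive rank-based exponential weights
  `exp(−(rank/σ)²)`, σ = 20, normalized to sum to one. Accumulating the
  weighted probabilities of the feature differing, the response differing,
  and both differing gives `W[f] = N_dYdF/N_dY − (N_dF − N_dYdF)/(n − N_dY)`,
  bounded in [−1, 1]. Duplicate rows are legitimate zero-distance
  neighbours; a constant response yields all-zero weights. The constants
  follow the canonical regression-ReliefF description; no installed library
  provides this estimator, so it is implemented here and verified against an
  independent naive-loop oracle in the tests.
* **Selection frequency** — "most selected" rankings count how often a
  feature appears in a method's top 10 across the repeated training splits,
  with ties broken by mean score; single-run rankings are also exposed.

Neighbourhood component analysis is deliberately absent: like the elastic
net it is scale-sensitive in the comparison this package reproduces, and the
final method comparison is LASSO vs F-test vs RReliefF.

## Model fitting and validation

`VifGatedRegressor` computes `VIF_j = 1/(1 − R²_j)` for each selected
feature by regressing it (with intercept) on the others; any VIF > 5 flags
multicollinearity and routes fitting to ridge regression, otherwise ordinary
least squares. Perfectly collinear columns report VIF = ∞; a rank-deficient
design in the linear branch also falls back to ridge. The ridge penalty is
selected over a log-spaced grid (default 10⁻⁴–10², 25 points) by analytic
leave-one-out cross-validation — exact and orders of magnitude cheaper than
refitting K folds inside the 100-iteration protocol; K-fold selection is
available via the `cv` parameter.

The validation protocol draws one fixed sequence of `n_iterations = 100`
random 70/30 row splits (train size `⌈0.7 n⌉`) from the seed and reuses it
for every method and every model size m ∈ {1,…,10}, so method comparisons
never differ in their test sets. Per iteration: rank features on the
training rows, take the top m (iterations in which a sparse method ranks
fewer than m features are skipped for that cell, mirroring the blank cells
such comparisons produce), fit the VIF-gated model on training rows, predict
the test rows, record the MAE. The (method × m) grid of mean MAEs picks the
best model (minimum mean MAE, ties toward fewer features); pooled
(actual, predicted) test pairs across iterations feed a two-sided paired
t-test and Cohen's d `= |μ₁ − μ₂|/σ₁` with σ₁ the SD of the actual values.
Splits are by trial row by default; `split_by_subject=True` assigns whole
subjects to one side, because trials of one subject are correlated and
row-level splitting lets subject identity leak across the split — both
conventions are defensible, so both exist.

## Synthetic-data generator

The generator emulates the study conditions: 30 subjects × five roll
amplitudes (0, 5, 10, 15, 20°), one 2-minute trial per cell at 100 Hz.
Cadence (1.6–2.0 steps/s) and leg length (0.80–1.00 m) are drawn per subject
from uniform ranges — conventional self-selected treadmill values; the
emulated protocol reports demographics but no gait parameters, so these are
explicit conventions. Heel strikes are planted at `(k + ½)/cadence`
(count = round(cadence × duration), except that strikes in the last ~0.2 s
are trimmed: an impact transient truncated by the trial edge has reduced
peak prominence and would be undetectable, as a real recording's trailing
partial step would be discarded).

Channels (m/s²):

* vertical: 9.81 + a step-frequency cosine (amplitude 0.8–1.2, crests
  phase-locked to heel strikes) + a Gaussian impact transient at each strike
  (amplitude 2.5–3.5, i.e. >2× the oscillation, σ = 30 ms) — the
  highest-peak detector is therefore well posed by construction;
* lateral: per-step half-sine sway humps signed by stance side plus an
  independently jittered late-swing bump; both jitters scale linearly with
  roll amplitude, and a slow sinusoid at the 8-s platform roll period with
  amplitude 0.05 m/s² per degree is added. Lateral variance is thus monotone
  in roll by construction;
* anterior-posterior: a step-frequency fundamental, a second harmonic and a
  heel-strike transient with independent subject-level amplitudes — without
  these, the whole-step, double-stance and mid-stance AP magnitudes of a
  pure sinusoid would be mutually proportional and unidentifiable.

White Gaussian measurement noise (default SD 0.3 m/s², ~10% of the impact
amplitude) is added to all three channels. All subject- and step-level draws
depend on (seed, subject) only, so the five conditions of a subject share
their randomness and roll acts as a pure amplitude scaling (common random
numbers); outcome noise is drawn per (seed, subject, condition).

**Planted outcomes.** Each outcome is an exact linear function of three
designated features — by default step time `aST`, lateral-magnitude
variability `vLM` and anterior-posterior magnitude `aAM` — extracted from
the *noise-free* signal with the planted segmentation, plus Gaussian noise
(default SD 0.02 m for peak excursion, 0.0012 m for MOS variability). The
three defaults tap independent variation sources (subject cadence,
roll-driven sway jitter, subject AP effort) and their coefficients are set
so each contributes comparable outcome variance; otherwise the sparse truth
would not be identifiable among its correlated sibling features and
selection-recovery tests would be ill-posed. Intercepts (−0.628 m and
−0.0539 m) offset the feature means so the outcomes land at realistic
rolling-platform magnitudes (peak excursion ≈ 0.35 m, MOS variability
≈ 0.02 m); values below a small positive floor are clipped with a warning
(untouched under the defaults).

The gold-standard kinematics are then *constructed to realize the planted
outcomes exactly*: the COM trace (stride-frequency plus roll-period
sinusoids, with analytic velocity) is rescaled so its maximum deviation
equals the planted peak excursion, and per-right-step MOS values are drawn
and standardized to have exactly the planted SD, with the BOS boundary
placed at `XCOM + MOS`. Applying the stability module to the clean
simulation therefore recovers the ground truth to floating-point precision —
the self-consistency the recovery tests assert at 10⁻⁹.

**What the generator does not emulate** — and hence what passing tests do
not show: no musculoskeletal or inverted-pendulum dynamics (kinematics are
kinematically planted, not mechanically simulated); noise is white and
Gaussian, unlike real IMU drift, soft-tissue artifact or sensor tilt; the
outcome–feature link is linear by construction, so recovery results validate
the pipeline's correctness, not the real-world predictability of gait
stability; roll is the only platform motion. Conclusions about real cohorts
require real recordings imported through the documented CSV format.

## Numerical choices and degenerate inputs

* 0-based sample indices, half-open windows everywhere; phase boundaries at
  `floor(fraction × length)` — prevents off-by-one drift between phases.
* Fixed-λ LASSO/elastic-net solves use coordinate descent at tolerance
  1e-10 (oracle-grade); cross-validated paths use tolerance 1e-5 and 60
  grid points, adequate for ranking at protocol scale.
* λ = 0 is solved by `lstsq` directly rather than coordinate descent.
* VIF of a constant or perfectly collinear column is the ∞ sentinel
  (R² ≥ 1 − 1e-12), always flagged.
* Degenerate statistics raise typed errors rather than returning NaN:
  zero-variance paired differences, zero actual-value SD for Cohen's d,
  empty LASSO selections warn and return empty rankings.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` fan-out; identical seeds give bit-identical
  cohorts, splits and reports.
* CSV artifacts are written with 17 significant digits and read back with
  round-trip float parsing, so write/read cycles are lossless; every
  artifact carries a JSON sidecar with the config hash and seed.

## Problem sizes used by the checks

The test suite exercises small cohorts (typically 6 subjects × 3 conditions,
30-s trials) for unit-level behaviour and the full 30 × 5 study size for
planted-truth recovery; `scripts/acceptance.py` runs the full study at the
complete 100-iteration protocol, plus a 20-iteration noise-free recovery
replicate, and completes in a few minutes on one CPU.
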