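# Methods

This note documents the modelling choices behind `segconn`: what each stage
computes, why the defaults are what they are, and where the synthetic
generator deliberately simplifies reality.

## Synthetic cohorts (`segconn.synthdata`)

A cohort consists of subjects aged uniformly on 10–16 years. Each subject
carries:

- **Movie coding.** A timeline of 978 two-second intervals whose
  change counts (0–5 situational changes) are drawn from the fixed category
  distribution (512, 276, 104, 46, 30, 10)/978. The distribution is a design
  constant, not a fitted quantity.
- **Responses.** Boundary key presses are Bernoulli per interval with
  P(response) = logistic(b0 + u_i + s_i · changes), where b0 = −3.36,
  u_i ~ N(0, 0.5²), and the subject slope is
  s_i = 0.30 + γ·(age_i − 13)·nc_i + ε, with γ = −0.346, ε ~ N(0, 0.05²).
  Response times are placed uniformly inside responding intervals.
- **Connectivity ground truth.** nc_i = |N(0, 0.2)| is the planted directed
  nonlinear connectivity (cingulate/SMA → lingual analog). It is half-normal
  because the estimated NC (a log error ratio with a removed pathway in the
  numerator) is nonnegative by construction; a signed ground truth could not
  be recovered in the same metric.
- **EEG (optional).** Two beta-band sources, AR(2) resonators at 20 Hz
  (pole radius 0.95, fs = 300 Hz), coupled one-directionally
  (cingulate → lingual, linear lag-1 coefficient 0.05) plus a per-subject
  quadratic coupling with gain 0.3 · nc_i. Innovations are normalized so each
  uncoupled source has unit variance; the coupled source sits slightly above
  unit variance because the coupling energy is re-amplified by its own
  resonance. Source amplitude is multiplicatively reduced (factor 0.7,
  ±0.5 s) around each response — the boundary-locked beta decrease. Sources
  occupy the most interior voxel of their atlas regions (a boundary voxel's
  leadfield varies too quickly for an extended patch to look dipolar), are
  projected through a random-geometry leadfield as small patches with
  per-source sensor-RMS-normalized gain, and sensor white noise is added at
  snr = 5 (signal RMS / noise RMS).

The sensor model is a synthetic stand-in: 60 channels, an 8×8×8 source grid
partitioned into 8 atlas regions, and a smooth but random leadfield. It
preserves the structural properties the analysis depends on (depth bias,
spatial mixing, patch extent) without modelling a head.

## Behavioral models (`segconn.behavior`)

Per-subject GLMs are plain logistic regressions of response on change count.
The mixed model is a random-intercept logistic regression fit by maximum
likelihood with **adaptive** 25-node Gauss–Hermite quadrature: nodes are
recentred at each subject's conditional mode and rescaled by the local
curvature. With ~10³ Bernoulli trials per subject the conditional posterior
of u_i is far narrower than its prior, and fixed-grid quadrature at the prior
scale is measurably biased (≈0.1 on the intercept at the study size).

Outlier screening uses the scaled MAD: exclude iff
|count − median| > 3 · 1.4826 · MAD, strict inequality, no exclusions when
MAD = 0.

## Markers and spectra (`segconn.markers`, `segconn.spectral`)

Responses closer than 2 s to the previous kept response are discarded
(greedy, left to right). Two-second bins with a response are boundary
intervals (BI); each valid BI (marker ±2 s inside the recording, no other
response within ±2 s) is paired with a randomly drawn no-boundary interval
carrying a virtual marker at the same within-bin offset, sampled without
replacement and subject to the same validity rule. Epochs are cut at
−2..+2 s; Morlet power (width 5, 3–30 Hz) is computed after zero-padding to
the next whole second, and band power is averaged over −1..+1 s so wavelet
edge effects stay outside the summary window.

## Sensor statistics (`segconn.clusterstat`)

Paired t per channel (BI vs NBI mean beta power), supra-threshold channels
(two-tailed p < 0.05) that have at least `min_neighbors` supra-threshold
neighbors are grouped into sign-split connected components scored by summed
t. The null distribution of the maximum |cluster sum| comes from random
within-subject condition swaps (sign flips), with the +1-corrected p-value.

## Source analysis (`segconn.source`)

DICS: trial-averaged cross-spectral density over the beta FFT bins of the
−0.5..0.5 s window, diagonal loading 0.05 of mean sensor power,
optimal-orientation scan, and neural-activity-index normalization
(projected-noise denominator, σ² = smallest eigenvalue of the regularized
CSD) to remove depth bias.

Clustering defaults are sized to the desk-scale grid: per atlas region, keep
the top 15 % of NAI voxels and DBSCAN them (eps = 1.5 × edge, min 4 voxels).
With ~35 voxels per region, a tail as extreme as the top 1 % used on
full-resolution template grids would leave fewer voxels than any reasonable
DBSCAN minimum. Per-region clustering (threshold *and* DBSCAN within each
region) is what lets two nearby hotspots resolve as separate region-labelled
clusters.

LCMV virtual channels are reconstructed at cluster peak voxels with unit-gain
scalar filters (dominant orientation via SVD). The pipeline default
`lcmv_reg = 0.2` is deliberately heavier than the DICS loading: unit gain at
a weak-leadfield (deep) voxel otherwise amplifies sensor noise past the point
where an MVAR model can describe the time course, and the extra leakage costs
less than the noise. At the generator's snr = 5 this keeps the virtual
channels ~80 % predictable by the connectivity stage.

## Connectivity (`segconn.ncreann`)

A single-hidden-layer network (tanh units with trainable per-unit scaling)
implements x(n) = f(past p samples of all regions) + noise. Defaults: order
9 (BIC-selected on the generator's sources), 6 hidden units, parameters
initialized uniformly on [−0.5, 0.5], incremental backpropagation with
momentum and adaptive learning rate, early stopping on a 10 % validation
split, five permuted 80/10/10 folds.

From the network's first-order Taylor expansion at the origin: **LC** is the
L2 norm over lags of the linear coefficients from source region to target;
**NC** is ln(mse when the source acts only through its linearized pathway /
mse of the full network). Fits with mean test R² below 0.5 are excluded by a
ledger gate.

## Outcome statistics (`segconn.modstats`)

Simple OLS regressions (slope outcome on one neural predictor) report R², F,
p and Durbin–Watson. Moderation fits Y ~ X + age + X·age, uncentered, with
HC3 inference; the interaction test is the HC3 Wald F with 1 df and ΔR² is
against the no-interaction model. Johnson–Neyman boundaries solve the
quadratic (b1 + b3 w)² = t²(v11 + 2 w v13 + w² v33) analytically and keep
real roots inside the observed age range. Benjamini–Hochberg families report
both the standard monotone adjustment and the rank-scaled variant
p·m/rank (no cumulative minimum), with values above 0.999 formatted as
"> 0.999". Cook's distance and simple slopes at mean ± 1 SD of age complete
the influence/probing toolkit.

## Pipeline and ledger (`segconn.pipeline`)

Gates run in order: scripted pre-exclusions → response-count outliers →
GLM convergence → (optionally) nCREANN fit quality. The ledger records each
gate's before/after counts and named exclusions and asserts conservation.
When the source/connectivity stages are disabled the moderation stage uses
each subject's planted nc_i, which is the low-noise configuration used for
recovery checks.

## Known simplifications

- The leadfield is synthetic; localization statements are about grid edges,
  not anatomy.
- Sources are stationary narrowband oscillators; real beta bursts are
  non-stationary.
- The boundary envelope is a fixed multiplicative dip, identical across
  subjects except for its timing.
- Problem sizes in the tests (6–12 subjects, 100–400 intervals of EEG) are
  chosen for run time; the generator's defaults (72 subjects, 978 intervals)
  define the study-scale configuration.
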