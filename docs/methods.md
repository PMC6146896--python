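# Methods

`libscal` implements a complete chemometric calibration chain for
quantifying a trace element (cadmium) in plant tissue from
laser-induced breakdown spectroscopy (LIBS), together with a synthetic
spectrum generator that stands in for real instrument data.  This note
describes the models, the defaults and why they were chosen, and what
the synthetic data can and cannot demonstrate.

## The measurement model behind the generator

An averaged LIBS spectrum of a pressed pellet is modelled as

    I(lambda) = b(lambda) + f * sum_l h_l * phi_l(lambda) + eps(lambda)

where

- `phi_l` is a pseudo-Voigt profile (Gaussian/Lorentzian mix, default
  mixing fraction 0.3, FWHM 0.1 nm) for emission line `l`, normalised
  so that the channel nearest the line centre reads exactly `h_l`.
  Atomic line widths and shapes vary with plasma conditions; the
  pseudo-Voigt with a ~0.1 nm FWHM is a conventional stand-in at this
  spectral resolution.  Normalising at the nearest grid channel (rather
  than the continuous maximum) makes single-channel peak extraction
  exact on any grid, which the noiseless recovery tests rely on.
- `h_l` is `sensitivity * c` for analyte (Cd) lines, a fixed base
  height times `(1 + trend * c)` for matrix and interferent lines
  (default trend 0.02 per mg/g, echoing the observation that matrix
  lines strengthen mildly under metal stress), and a fixed base height
  for background-like lines.
- `f = exp(N(0, sigma_shot))` is one multiplicative shot factor shared
  by **all** lines of a shot (default `sigma_shot = 0.2`, a ~20%
  relative intensity scatter typical of shot-to-shot laser-energy and
  ablation variability).  This single shared factor is the simplest
  mechanism that makes internal-standard ratio indices work: any ratio
  of two line intensities cancels `f` exactly.
- `eps` is i.i.d. additive detector noise (default sigma 0.3 intensity
  units against Cd peak heights of up to ~15).
- `b(lambda)` is a polynomial baseline, zero by default: the analysis
  chain operates on denoised spectra where the continuum has no
  modelled role, and a zero baseline keeps the ratio-index invariance
  exact rather than approximate.

A pellet's spectrum averages `replicates` shots (default 80) that share
the true concentration but not `f` or `eps`.  Concentrations are drawn
per stress group from normal distributions truncated at zero; the five
default groups (12, 12, 18, 18, 18 samples with means 0.001, 0.015,
2.304, 6.663 and 11.577 mg/g) reproduce the hydroponic design the
reference measurements describe.  For heavily truncated groups (mean
near zero, spread larger than the mean) the realised group mean
necessarily exceeds the nominal one; tests of mean recovery therefore
use the far-from-zero groups.

The default line catalog contains nine Cd I analyte lines (326.10,
340.36, 346.61, 361.05, 361.28, 361.44, 467.81, 508.58, 643.84 nm) with
sensitivities graded so that 508.58 nm is the strongest, cleanest
tracker of concentration; an Fe I interferent at 360.88 nm adjacent to
Cd I 361.05 nm; a strong stable line at 466.23 nm carrying no analyte
signal (the internal-standard denominator of the ratio indices); a few
smooth background-like signals (331.24, 474.64, 493.51, 507.47 nm);
and the strong Ca, Mg, Na, K, Cu, C and CN matrix features of root
tissue.  The relative analyte sensitivities are a design choice
mirroring the reported per-line calibration quality, with 508.58 nm
dominant; they are not fitted to anything.

### Desk-scale preset

`small_config()` is the preset used by the test suite, examples and the
acceptance script: 8 samples per group (40 total), 4,342 channels over
the same 229.99-880.01 nm range (~0.15 nm spacing), 3 averaged shots.
These sizes keep a full selection run in seconds while preserving every
structural feature (line density, group structure, both noise types).
The full-scale default (22,015 channels, 80 shots, 78 samples) is what
the generator produces when no preset is applied.

### What the generator does not emulate

Self-absorption, Stark broadening and plasma-physics couplings between
lines; wavelength-dependent detector response; correlated (pink)
detector noise; echelle-order stitching artefacts; matrix-effect
nonlinearity beyond the mild linear trend.  Passing tests therefore
demonstrate the correctness of the algorithms and the internal
consistency of the chain under the stated noise model — not
instrument-grade figures of merit.  Real-data metrics depend on
spectra this package cannot fabricate, and no claim is made about them.

## Preprocessing

Wavelet denoising uses Daubechies-6 at decomposition level 3.  The
thresholding rule is not dictated by the level/wavelet choice alone, so
the package uses the standard assumption-light default: soft
thresholding of each detail band at the universal threshold
`sigma * sqrt(2 log n)`, with `sigma` estimated per band (and per
spectrum) from the median absolute deviation, symmetric boundary
extension, reconstruction truncated to the input length.  Denoising is
applied per averaged spectrum, row-wise, and never uses other samples'
spectra — so it cannot leak information across the split.

The calibration/prediction split sorts samples by reference
concentration (stable sort; ties keep original order) and assigns three
of every four to calibration and the fourth to prediction.  A trailing
partial block of fewer than four samples goes to calibration, keeping
the prediction set a strict every-fourth subsample.  For 68 samples
this yields 51/17.

## Interval selection

Channels are partitioned into `k` contiguous intervals whose sizes
differ by at most one, with the larger (`ceil(p/k)`-sized) intervals
first.  This remainder-first convention is the unique one consistent
with every entry of the published 28-interval removal ledger for the
22,015-channel axis, which the test suite replays as exact integer
bookkeeping (a pure arithmetic check — no model fitting involved).

Interval scoring fits a single-response PLS model on the interval's
channels and reports the leave-one-out RMSECV minimised over 1 to
`max_lv` latent variables (ties to fewer).  Leave-one-out is used for
all PLS scoring; the latent-variable choice is stated as leave-one-out
in the source protocol and the interval-scoring fold scheme follows it
for consistency.  iPLS scans `k` in a configurable range (2-30 at full
scale; the desk-scale runs use 2-20) and keeps the single best interval
(ties: smaller `k`, then lower interval index).  BiPLS starts from all
intervals of one partition and repeatedly discards the interval whose
removal yields the lowest remaining-model RMSECV; each ledger row
records the channel count and RMSECV of the model on the intervals
still present *before* that row's removal, which is the count semantics
the published ledger uses.  The best recorded step (ties: fewer
channels) defines the selected interval set.

The hot path uses an internal vectorised PLS1 (NIPALS with triangular
coefficient recovery) that returns the whole latent-variable
coefficient path in one pass; its predictions are pinned to
scikit-learn's `PLSRegression` at 1e-9 in the test suite, and
scikit-learn remains the implementation used by the public PLS model
fit.

## Successive projections

`spa_chain` grows a greedy chain from a seed column: columns are
mean-centred and scaled to unit norm, and each step adds the candidate
with the largest residual norm after orthogonal projection onto the
span of the chain so far (ties: lowest index; numerically dependent
columns are never picked while independent ones remain).  The chain is
validated against a brute-force Gram-Schmidt oracle on exhaustive small
instances.  `spa_select` grows a chain from every candidate start and
scores every prefix by the leave-one-out RMSECV of an
intercept-augmented ordinary least-squares fit (closed-form leverage
identity) on the calibration samples.  Classical SPA scores prefixes on
a separate validation set; since no second split is defined here,
leave-one-out on the calibration set avoids inventing one.

## Univariate calibration and ratio indices

Line intensities are read from the denoised spectrum at the nearest
channel by default (`window_max` mode is available for catalogs whose
wavelengths are slightly offset from the instrument axis).  The two
indices are

    index1 = (I_508.58 + I_361.05) / (2 * I_466.23)
    index2 = I_508.58 / I_466.23

with the denominator required positive.  A published restatement of
the first index reads as multiplication by the denominator line; the
display-equation form above (division by `2 * I_466.23`) is
implemented, as it is the only reading under which the index cancels
the shared shot factor.  Univariate fits are ordinary least squares of
concentration on the predictor; RMSECV is leave-one-out (closed form,
checked against explicit refits at 1e-10); prediction-set metrics come
from the held-out samples only.

## Multivariate calibration

PLS: mean-centred, no per-channel scaling (intensities share units);
latent variables 1..`max_lv` chosen by leave-one-out RMSECV, ties to
fewer.  With all components on full-rank data PLS reproduces ordinary
least squares, which the tests assert.

SVM: spectra are mean-centred and projected onto the top principal
components fitted on the calibration set only (again no per-channel
autoscaling — autoscaling would inflate noise-only channels and bury
the signal directions); the scores are standardised so that one RBF
width grid serves every component count; then an epsilon-insensitive
RBF support-vector regression is fitted.  Cost (1..1000 by decades),
kernel width (2^-8..2^2, log grid), epsilon (0.01, 0.1) and the
component count (up to 13 by default — treated as a cap, with the
count chosen by CV) are selected by seeded fivefold cross-validation
RMSE.  The reported RMSECV is the winning fold-mean; tuning and
reporting share the same folds, so it is an optimistic estimate, and is
documented as such rather than nested.

Evaluation reports R^2 on calibration fitted values, the model's own
cross-validated RMSECV, and R^2/RMSE on the prediction set.

## Pipeline and leakage contract

`run_pipeline` chains simulate/load, optional denoising, the rank
split, selection (`full`, `ipls`, `bipls`, `ipls_spa`, `bipls_spa`) and
one model family (`pls`, `svm`, `univariate`, `index1`, `index2`),
then writes metric, selection and split reports.  Selection and every
model choice see only the calibration rows; the test suite enforces
this by permuting prediction-set spectra and asserting that selected
channels, factor counts and all calibration-side metrics are unchanged.
All randomness flows through explicit seeds, and repeated runs produce
byte-identical reports.

## Numerical choices and degenerate inputs

- PLS deflation stops when the weight norm falls below 1e-13 of the
  data scale; folds that exhaust rank early carry their last available
  component's prediction forward.  A constant-channel matrix yields the
  mean predictor.
- OLS prefix scoring uses the pseudo-inverse (rcond 1e-12) so that
  near-collinear prefixes are scored rather than crashing; a leverage
  of 1 (a sample its own sole support) scores infinite.
- Ties everywhere break deterministically (fewer factors / fewer
  channels / lower index / smaller `k`), so every run is reproducible.
- Dataset CSV round trips exactly (17-significant-digit writes,
  round-trip float parsing).

## Known limitations

- BiPLS recomputes a full cross-validated model per candidate removal;
  at full scale (22,015 channels, k up to 30) this is minutes, not
  seconds.  The desk-scale preset exists for iteration speed.
- The SVM RMSECV is optimistic by construction (see above).
- On coarse desk-scale grids an emission line can straddle two
  channels; single-channel selection methods (SPA) may then prefer the
  neighbouring half of the same peak.  The `window_max` extraction mode
  and finer grids both remove the ambiguity.
- The generator's group concentration means are nominal parameters of
  truncated normals, not the realised means, for groups near zero.
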