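# Methods

`spectrafuse` implements a two-sensor chemometrics workflow for predicting
the primordial leaf count (LC) of potato tubers — the number of leaf
primordia on the sprouting eyes, a direct indicator of sprouting activity
during storage — from VIS/NIR interactance spectra and hyperspectral-imaging
mean spectra. This note records the models, the tunable parameters, the
synthetic-data design, and the numerical choices, in the order the pipeline
applies them.

## Radiometric normalization

Raw intensities are converted to dimensionless relative spectra against a
Teflon reference after background (dark) subtraction:

- relative interactance: RI = (I_s − I_d) / (I_r − I_d), per wavelength;
- hyperspectral cubes are first averaged over both spatial coordinates
  (scan line and pixel jointly), then ratioed the same way:
  RR = (AS_s − AS_b) / (AS_r − AS_b).

Mean-then-ratio is deliberate; on spatially heterogeneous cubes it differs
from ratio-then-mean, and a regression test documents the difference. A
denominator is degenerate when |I_r − I_d| ≤ 1e−9 × max|I_r|; this raises an
error naming the offending wavelengths rather than clamping, because silent
clamping corrupts downstream calibration.

## Wavelength selection (forward IPLS)

The wavelength axis is tiled into contiguous intervals of width W (the last
interval may be shorter). A greedy forward search adds, at each step, the
interval whose inclusion minimizes the 4-fold cross-validated RMSE of a PLS1
model; the latent-variable count is re-optimized over 1..20 at every step.
Choices the search fixes:

- **Stopping rule:** stop when the best candidate fails to improve RMSECV by
  a relative 1e−4 (the trace is therefore strictly decreasing). An optional
  `max_steps` cap bounds the search for large replicated studies.
- **Folds:** one seeded random fold assignment is drawn per search and shared
  by every candidate, so candidates compete on identical folds.
- **Ties:** exactly equal RMSECV goes to the lowest interval index.
- **Reporting:** selected-channel counts are split at 700 nm into visible
  and NIR ranges; the boundary is configurable.
- Selection runs on the raw relative spectra with the untransformed LC
  response, before any preprocessing (the pipeline's stage order).

Candidate scoring runs in Gram space: each fold's centered X'X and X'y are
precomputed once over all channels, and a candidate subset only slices them,
making per-candidate cost independent of the sample count. The Gram-space
engine is algebraically identical to the NIPALS fit (asserted in tests).

## Mid-level fusion

Each sensor's selected-channel matrix is normalized column-by-column by the
maximum of that column over the **calibration** rows (the literal signed
maximum; a non-positive maximum is an error), and the blocks are
concatenated row-wise, aligned by sample id. The stored calibration maxima
are reapplied unchanged to prediction rows, which may exceed 1. A side
effect of this normalization worth knowing: the calibration sample that
attains the maximum of *every* column becomes an all-ones row, on which
row-wise scatter corrections (SNV) are undefined; the recipe grid treats
such recipes as infeasible for that dataset and drops them from the
competition (see below).

## Preprocessing grid

Sixty-three recipes = stage 1 × stage 2 × reference transform:

| stage 1 | stage 2 | reference |
|---|---|---|
| A0 none | B1 mean center | C0 none |
| A1 SG 1st derivative | B2 MSC | C1 log10 |
| A2 SG 2nd derivative | B3 OSC | C2 power |
| A3 unit-norm rows | | |
| A4 SNV | | |
| A5 MSC | | |
| A6 median center | | |

Every stateful statistic (MSC reference spectra, center vectors, OSC
weights/loadings) is fitted on the calibration split and replayed unchanged
on prediction data. Defaults and rationale:

- **Savitzky–Golay:** window 7, polynomial order 2 (the smallest common
  window distinguishing first from second derivatives); derivatives operate
  within contiguous runs of selected channel indices per sensor block,
  treating index spacing as uniform; runs shorter than the window pass
  through unchanged with a warning rather than being extrapolated.
- **A3 normalization** is unit Euclidean row norm — the most common
  chemometric row normalization distinct from SNV, which is also in the grid.
- **MSC** reference = mean calibration spectrum of the sensor block being
  corrected (scatter is a per-instrument property); SNV and unit-norm act on
  whole rows.
- **OSC** (classic Wold): the dominant principal score is orthogonalized
  against the response, projected back onto the spectra for weights, and
  iterated to convergence; the deflating score is exactly y-orthogonal.
  One component by default — more risks overfitting at 160 calibration
  samples. OSC centers its input internally and stores the center.
- **C2 power transform** defaults to the square root (forward y^0.5,
  inverse squaring, with negative predictions clipped at zero before
  inversion — the monotone completion). The exponent is configurable to 2.
  The sqrt default is chosen because reported fused-model RMSEP magnitudes
  (~0.13–0.22 LC-transform units against an LC SD of 8.6–13.6) are consistent
  with a sqrt-scale response and not with a squared one, and because sqrt is
  the natural linearizer of a signal that grows sublinearly with count data.

## PLS regression and model selection

PLS1 by NIPALS with internal centering of X and y (no scaling): unit-norm
weight vectors, mutually orthogonal scores, coefficients
B = W(PᵀW)⁻¹q. Latent variables are capped at 20. Cross-validation uses
4 folds (sizes differing by at most one, seeded permutation); out-of-fold
predictions are assembled for every LV count in one pass and RMSECV is the
root mean squared out-of-fold error, computed by the same RMSE function
used for prediction-set RMSEP. The winning recipe is the one with minimum
RMSECV on its transformed reference scale; ties go to fewer latent
variables, then lexicographic recipe code. Recipes that fail on the data
at hand (zero-variance rows after normalization, spectrally flat rows under
MSC) are logged and excluded rather than aborting the run; an error is
raised only if every recipe fails.

RMSECV is computed on the transformed reference scale the model is fitted
on. Because the three reference scales are not commensurate, the final
evaluation reports r, RMSEP and RPD on **both** the transformed scale and
the original LC scale (predictions back-transformed); cross-model
comparisons (fused vs single sensor, the improvement summary) always use
the original LC scale.

## Evaluation

r is the Pearson correlation between measured and predicted values; RMSEP
is the root mean squared prediction error; RPD is SD(measured, n−1
denominator) / RMSEP, reported as +inf for a perfect fit. Improvements are
100 × (fused − single)/single, rounded to one decimal.

## Synthetic data generator

The generator is the package's study stand-in: every downstream stage is
testable against known ground truth.

- **LC distribution.** A standard log-normal moment-matched to the target
  coefficient of variation, affine-rescaled and clipped to
  [4.33, 57.66] (defaults: mean 13.47, SD 13.62, n = 200 — the broad,
  right-skewed distribution a multi-temperature storage experiment
  produces). Clipping shrinks both moments, so the affine constants are
  calibrated by a deterministic fixed point on the clipped distribution's
  quadrature moments; the clipped *population* mean/SD match the targets to
  1e−10, and individual n = 200 samples scatter around them with the usual
  √n sampling error.
- **Spectra.** x_i(λ) = g_i·[b(λ) + Σ_b e_b·G(λ; c_b, w_b)·√(lc_i) +
  u_i·interferents] + o_i + ε: a smooth baseline in (0,1), Gaussian band
  profiles, √LC as the latent spectral driver (so the power reference
  transform is its natural linearizer), per-sample gain g_i ~ N(1, 0.05),
  offset o_i ~ N(0, 0.01) and white noise (SD 0.006).
- **Two sensors.** Sensor A (interactance analogue): 600 channels over
  400–1000 nm; sensor B (hyperspectral mean-spectrum analogue): 256
  channels, same range. Three informative bands each — one shared (705 nm)
  and two unique — with effects 0.012–0.016 absorbance units per √LC unit.
- **Complementarity.** Each band is overlaid by a same-profile,
  sensor-specific interferent (strength 0.015, drawn N(0,1) per sample per
  sensor). Within one sensor the LC signal is therefore partially
  confounded with independent nuisance variation; the confounders are
  independent across sensors, so fusing the two instruments genuinely
  disambiguates the signal instead of merely averaging noise. With these
  frozen defaults a single sensor reaches a prediction RPD around 2.3 and
  the fused model around 3.2 — the same regime as the tuber study — and
  the fused model beats the best single sensor in ≥ 8 of 10 seeds.
- **Cubes.** A line-scan cube replicates a spectrum over
  n_scan_lines × line_length pixels between constant background and
  reference levels plus white spatial noise; the mean-then-ratio correction
  recovers the input within the pooled standard error.

What the generator does **not** emulate: radiative transfer or tuber
geometry, wavelength-dependent detector noise, instrument drift between
sessions, cultivar biology, or any correlation between scatter artifacts
and LC. Passing recovery tests therefore demonstrate that the pipeline's
machinery is correct and leakage-free under the stated statistical
structure — not that the spectroscopy of real tubers is this clean.

## Replicated study sizes

The ten-seed fusion study behind the recovery checks runs the full pipeline
per seed at n = 200 with window width W = 2, an IPLS cap of 30 forward
steps, and a compact four-recipe grid ("A0,B1;C2", "A4,B1;C2", "A5,B1;C2",
"A1,B1;C2") — a representative slice of the 63-recipe grid chosen to keep a
ten-fold replication inexpensive while exercising derivative, scatter- and
non-corrected branches. Single runs through the CLI default to the full
grid and W ∈ {1, 2, 3}.

## Known limitations

- Only the selection → fusion → preprocessing → PLSR stage order is
  implemented; a preprocess-before-selection variant is not offered because
  the recipe to apply ahead of selection is underdetermined and the search
  cost multiplies by the recipe count.
- Selecting by raw RMSECV across different reference scales favors
  transforms that compress the response range; the original-scale report
  is the comparable one (both are emitted).
- Forward IPLS is greedy; it can absorb chance improvements on pure-noise
  data (the stopping tolerance bounds, but does not eliminate, this).
- Column-max normalization is sensitive to single high calibration samples
  (no robust quantile variant is provided, by design fidelity).
- PLS1 only (single response); no PLS2, kernel PLS, or uncertainty
  intervals.
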