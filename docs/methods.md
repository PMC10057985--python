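# Methods

`nirtrace` implements a complete chemometric workflow for two-class
geographical-origin discrimination from near-infrared (NIR) diffuse-
reflectance spectra: spectral pretreatment, PCA-based outlier screening,
Monte-Carlo cross-validation (MCCV), and three pattern-recognition methods
(PLSR/PLS-DA, SVM, SIMCA) together with the SIMCA inter-model distance.
Because no public spectral dataset of the target system exists, a synthetic
generator provides data with the statistical structure the workflow assumes;
it is first-class, tested code, not a fixture.

## Data model

Spectra live on a shared strictly monotonic wavenumber grid, stored
descending from 12,000 to 4,000 cm⁻¹ as instruments report it.  The number
of grid points is not hard-coded: the full-size scenario uses 2074 points
(the effective digitization of an 8 cm⁻¹-resolution instrument over that
range is instrument-specific, so any monotonic grid is accepted).
Absorbance (log 1/R) is assumed already computed.  The on-disk format is a
wide CSV (id, label, wavenumber columns); floats are written with the
shortest round-tripping representation so read∘write is bitwise exact.

## Preprocessing operators

Nine single pretreatments plus polynomial detrending, combinable in any
order.  Order is significant (`snv → detrend` ≠ `detrend → snv`) and
pipelines replay their fitted chain exactly.

| operator | definition | state fitted on train |
|---|---|---|
| SNV | per-row (x−mean)/sd, sd with denominator P−1 | none |
| MSC | regress x = a + b·ref over wavenumbers, return (x−a)/b | reference = train column mean |
| OSC | Wold-style: iterate PC score → orthogonalize against span[1, y] → regress back onto X; deflate X by t·pᵀ | weight/loading vectors |
| first/second derivative | Savitzky–Golay, signed grid step (descending grid ⇒ negative step) | none |
| S-G smoothing | local least-squares polynomial, polynomial edge handling | none |
| baseline correction | subtract the chord through the first and last point | none |
| detrending | subtract per-row least-squares polynomial in wavenumber | none |
| mean centering | subtract train column means | column means |
| area normalization | divide each row by Σ\|x\| | none |

Numerical choices:

* **Baseline correction** is not uniquely defined in the chemometric
  literature; we use the two-point endpoint chord — the simplest reading of
  the name that stays distinct from least-squares detrending.  This is an
  interpretive choice.
* **Savitzky–Golay defaults**: window 15, polyorder 2 (smoothing and first
  derivative), polyorder 3 (second derivative) — conventional for NIR
  spectra of ~10³ points; all overridable.  Derivatives use S-G kernels
  rather than plain finite differences because derivative NIR spectra are
  conventionally smoothed; the window must not exceed P.
* **OSC**: 1 component by default, tolerance 1e−8 on the weight vector,
  500 iterations.  Deflation at fit time uses t = Xw (at the fixed point
  this equals the orthogonalized score exactly when X has full row rank),
  which keeps fit and apply the same linear operation and makes replay on
  the training set bitwise exact.
* **Area normalization** uses the sum of absolute values (robust to the
  sign changes derivatives introduce); a trapezoidal ∫|x|dν variant is
  selectable.
* **Detrend** default degree 2, the usual companion to SNV; the wavenumber
  axis is rescaled to [−1, 1] before the Vandermonde fit for conditioning.

## Outlier screening

PCA on the mean-centered matrix; a sample is flagged when **either** its
Hotelling T² (score leverage, normalized by per-component score variance)
or its Q residual (squared off-model reconstruction norm) exceeds the
critical limit at significance α = 0.05.  T² limit:
k(N−1)/(N−k)·F₁₋α(k, N−k).  Q limit: Jackson–Mudholkar normal approximation
from the residual eigenvalue moments θ₁, θ₂, θ₃ (a χ²-matching alternative
g·χ²₁₋α(h) with g = θ₂/θ₁, h = θ₁²/θ₂ is selectable).  When the residual
eigenvalues are numerically zero (data exactly in the model subspace) the Q
limit is disabled with a warning rather than flagging everything.

k defaults to the smallest value reaching 95% cumulative explained
variance.  Screening runs once on the full dataset before splitting, so
every MCCV repeat sees the same cleaned sample; there is no iterative
re-screening.  On null multivariate-normal data the T² exceedance rate
reproduces α within Monte-Carlo error (checked at N = 5000).

## Monte-Carlo cross-validation

Random 70/30 train/test partitions without replacement, repeated (default
10×), stratified by class by default because origin datasets are typically
imbalanced (~1.4:1 in the motivating design).  Metrics are reported as mean
± standard deviation over repeats; single-split numbers hide split variance.
All draws derive from one integer seed.

## Models

**PLSR / PLS-DA.**  NIPALS with univariate dummy-coded response
(y ∈ {0, 1}): each factor maximizes cov(Xw, y) under ‖w‖ = 1, followed by
rank-one deflation.  The factor expansion collapses to a coefficient vector
B = W(PᵀW)⁻¹q; at full rank predictions coincide with ordinary least
squares (verified to 1e−6 against an explicit OLS solve, and against
scikit-learn's PLS implementation).  Reported as R² and RMSE, with the
conventional R² > 0.91 adequacy flag, plus PLS-DA accuracy from
thresholding ŷ at 0.5.  Component count: 10-fold CV minimizing RMSECV is
implemented (`select_plsr_components`); the benchmark grid uses a fixed
default of 8 components so grid runtime stays proportionate.

**SVM.**  Soft-margin SVC (scikit-learn), RBF kernel, C = 1,
gamma = 1/(P·var(X)).  The decision-function semantics, not the QP solver,
are the contract here.  These conservative defaults can collapse to the
majority class on weakly separated standardized spectra; a CV grid-search
helper over (C, γ) is provided but off by default.

**SIMCA.**  One PCA model per class.  Sample-to-class similarity is the
residual variance ratio s²/s₀² with s² = ‖r‖²/(P−k_c) and the pooled
training residual variance s₀² = Σr²/((N_c−k_c−1)(P−k_c)), the classical
residual degrees-of-freedom convention; the membership limit is
F₁₋α(P−k_c, (N_c−k_c−1)(P−k_c)) at α = 0.05.  Per-class k: smallest k
reaching 95% cumulative variance, **capped at min(10, N_c−2)** — after
scatter-removing pretreatment the within-class covariance is nearly
isotropic and an uncapped variance rule would absorb most of the sample
rank, leaving no residual degrees of freedom.  Accuracy uses forced-choice
assignment (smallest ratio; exact ties go to the first class in sorted
label order) because soft accept/reject semantics cannot produce a single
accuracy percentage; membership flags are reported alongside for soft
interpretation.

**SIMCA model distance.**  D(r,g) = √[(S²_{r→g}+S²_{g→r})/(S²_{r→r}+S²_{g→g})]
with every term the mean per-sample residual variance (‖r‖²/(P−k) averaged
over the class), so a model against itself gives exactly 1; D > 3 is the
conventional "well separated" flag.  The published typesettings of this
statistic are frequently garbled; the definition here is the standard
cross-fitted/self-fitted residual-variance ratio and is isolated in a
single function so an alternative reading can be swapped in one place.

## Synthetic generator

Clean class spectra are sums of Gaussian bands at the C–H/CH₂ combination
(4090–4396, 4140–4450 cm⁻¹), first-overtone (5620–5885, 5680–6060), and
second-overtone (6855–7020, 7010–7288) regions plus the C=O second overtone
(5230–5370); band centers/sigmas are the interval midpoints/half-ranges.
Origin differences enter as fractional band-amplitude modulation
(constituent-concentration differences), weighted toward the combination
and C=O bands.  Separation presets: none = 0, weak = 0.02, moderate = 0.1,
strong = 0.3 fractional effect; "strong" is defined as separation clearly
beyond the D > 3 model-distance convention.

Observed spectra: gain·clean + offset + slope·(ν−ν̄) + white noise, with
lognormal gain (σ = 0.10), offset σ = 0.02 AU, tilt σ = 2.5·10⁻⁶ AU/cm⁻¹,
white noise σ = 0.002 AU — plausible magnitudes for powdered-sample diffuse
reflectance.  Optional gross outliers multiply the gain (default ×5).  The
corruption is exactly the affine family that SNV/MSC/detrending assume, so
the expected efficacy ordering (scatter correction ≫ raw) is realizable by
construction.  What the generator does **not** emulate: wavelength-dependent
scatter, instrument line-shape, water-vapor interference, batch drift, and
within-class constituent variability.  Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated model,
not field performance on real powders.

Scenario scales: `tiny` (40+60 samples, 200 points; seconds),
`balanced` (100+100, 200 points; null-calibration runs), `full`
(1530+2127, 2074 points over 12,000–4,000 cm⁻¹; the motivating study's
dimensions).  The analyses and tests run on the tiny/balanced scales so the
whole suite completes in well under a minute on one CPU; the full
scale is exercised for shape only.

## Benchmark integrity

The grid driver removes outliers once, then per MCCV repeat fits each
preprocessing pipeline on the training partition only and replays it on the
test partition; models are fitted on preprocessed training spectra only.
Identical config + seed gives identical result tables.  Cell failures
(degenerate spectra after a transform, solver errors) are recorded per cell
with the error class instead of aborting the grid.  The default grid is the
19-spec comparison set: raw, the nine singles, and nine SNV-centred
combinations, literally ordered (e.g. `deriv1+snv` applies the derivative
first).

## Known limitations

* Forced-choice SIMCA accuracy is robust to any corruption a class PCA can
  span; with the generator's low-rank affine scatter, raw-spectrum SIMCA
  degrades only through the k-rule leaving part of the scatter uncaptured,
  which is milder than the degradation typically seen on real scattered
  powders.
* OSC is known to overfit (perfect training accuracy, reduced test
  accuracy) — visible in the benchmark output and expected.
* The R² > 0.91 adequacy flag and the D > 3 separability flag are field
  conventions, not statistical tests.
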