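# Methods

This note records the modelling choices behind `sersdx`: what each stage
assumes, which parameters matter and why their defaults are what they
are, what the synthetic cohorts do and do not emulate, and the known
limitations a user should weigh before trusting a result.

## Preprocessing chain

Order: rubberband baseline (per replicate) → replicate average →
normalization → region selection → Savitzky-Golay second derivative.
Mean-centering is deliberately deferred to the model so that external
samples are always centered with *training* means.

**Rubberband baseline.** The baseline is the piecewise-linear
interpolation of the lower convex hull of the (wavenumber, intensity)
polyline; subtracting it leaves a non-negative spectrum that is exactly
zero at the hull's anchor points. This removes any background that is
convex on the recorded window — the smooth, monotonically decaying
autofluorescence of serum measurements fits that description — but will
eat genuinely concave signal plateaus; it is a deliberate, conservative
choice over parametric (polynomial, asymmetric-least-squares)
alternatives, which are out of scope.

**Replicate averaging.** Four acquisitions per sample are averaged
point-wise. Baseline correction is applied per replicate before
averaging by default (each acquisition has its own fluorescence
realization); the order can be switched in `PreprocessConfig` since both
orders are defensible and the difference is second-order for smooth
baselines.

**Normalization.** Default is unit Euclidean norm ("vector"). Area and
max normalization are available; which variant the original instrument
software applied is not documented, so the choice is a config knob and
the default is stated in every report. Note that any closed-sum
normalization introduces *closure*: raising the planted bands of one
class necessarily lowers that class's remaining bands, so strong
class-neutral bands acquire a small anti-correlated class signal. This
is real chemometric behaviour, not an artifact of the implementation,
and it matters for band attribution (see Limitations).

**Region.** 750–1750 cm⁻¹ (`REGION_DEFAULT`). The source material quotes
both 750–1720 (abstract) and 750–1750 (model construction); the
model-construction value governs and the alternative ships as
`REGION_ABSTRACT`.

**Savitzky-Golay second derivative.** 25 points (48 cm⁻¹ at the 2 cm⁻¹
grid), polynomial order 3 (the usual choice for second derivatives;
order 2 gives identical second-derivative coefficients for interior
points, order 4 is noisier — 2–4 supported). Edge points without a full
window — 12 per side — are truncated rather than padded: padding invents
data and the fingerprint region is interior to the recorded 600–2300
range anyway. The derivative of a peak of half-width w is a multiplet:
a sharp central lobe flanked by opposite-signed side lobes roughly
±2.4 w away. With w = 10 cm⁻¹ the side lobes fall ~24 cm⁻¹ from each
band centre.

## OSC-PLS-DA

"OPLS-DA" is implemented as sequential orthogonal signal correction
followed by PLS1 discriminant analysis — the form the workflow is
actually run in by the commercial packages it replicates — not the
integrated Trygg–Wold O-PLS decomposition.

**OSC.** Per component: take the leading singular direction of the
Y-orthogonalized data, iterate weight-vector estimation (min-norm least
squares of the orthogonalized score on X) to a fixed point, store
(w, p, t) with t = Xw, deflate X ← X − t pᵀ. Because t is an exact
linear function of X, unseen spectra are deflated identically with no
access to their labels. With more samples than retained variables the
fixed point makes t exactly orthogonal to the centered class vector; the
fit asserts |corr(t, y)| < 1e-6. Default `n_osc = 1`.

**PLS-DA.** NIPALS PLS1 against y coded FM = 1 / non-FM = 2 (midpoint
1.5 as decision threshold; exact ties — a probability-zero event — go to
class 2). The inner loop is run to a 1e-12 weight-change tolerance with
a 500-iteration cap, although for a single response it converges in one
pass. Per-LV explained X- and Y-variance are both reported, since
"explained variance" claims are ambiguous between the two. Default
`n_lv = 7`; `n_lv = 0` is allowed and yields the null model predicting
the training mean (useful as a CV baseline). The regression vector is
b = W(PᵀW)⁻¹q.

**Class coding.** FM is always the positive class for
sensitivity/specificity, and reports say so in their headers.

## Validation

* LOOCV refits *everything* leak-prone per fold: column means, OSC and
  PLS. Per-spectrum transforms (baseline, normalization, derivative)
  involve no cross-sample statistics and are applied once upstream.
* SECV and SEP use denominator n (not n−1 or n−LV): the common SEP
  definition; the alternative only rescales.
* R² is squared Pearson correlation between predictions and coded y
  (matching the "correlation coefficient" language of the source
  workflow); the 1 − SS_res/SS_tot variant is computed alongside as
  `r2_ss`.
* ROC/AUC: empirical curve over all thresholds with ties grouped; the
  trapezoidal area equals the Mann-Whitney probability with ties counted
  one half (asserted against a pair-counting oracle in the tests).
  Orientation is higher-score-more-FM-like; if the AUC comes out below
  0.5 the score sign is flipped and the flip recorded.
* Outlier screening: leverage hᵢ = 1/n + tᵢᵀ(TᵀT)⁻¹tᵢ over the LV
  scores, internally studentized residual eᵢ/(RMSE·√(1−hᵢ)); a sample is
  flagged when h > 3(n_lv+1)/n **and** |r| > 3. Removal is a single
  curation pass before the final calibration fit — never inside CV
  folds — capped at 3% of samples, worst offenders first.

## Synthetic cohorts

The generator emulates the *statistical structure* the analysis assumes,
not SERS physics. Each sample's template is a sum of Lorentzian bands
(HWHM 10 cm⁻¹ by default; Gaussian available) at the literature band
positions on a 600–2300 cm⁻¹ grid with 2 cm⁻¹ spacing, plus an
exponential fluorescence background a·exp(−(ν−600)/τ) with τ = 800 cm⁻¹
and a lognormal per-sample amplitude (median 2.0, σ = 0.3) — smooth and
convex enough for the rubberband to remove, which is the role the real
autofluorescence plays. Per sample: lognormal per-band intensity jitter
(σ = 0.1, biological variability), a lognormal global intensity scale
(σ = 0.2, SERS enhancement variability; removed by vector
normalization). Per replicate: a multiplicative scalar jitter (σ = 0.05)
and additive white noise (σ = 0.02 a.u. against strong-band amplitude
1.0). Band amplitudes follow a qualitative strong/medium hierarchy
(strong: 1014, 1222, 1354, 1448, 1586 cm⁻¹); they are free parameters of
the generator, not measured values.

Class structure is multiplicative: a band with fractional effect δ is
generated at amplitude ×(1 + δ/2) in FM and ×(1 − δ/2) in non-FM
samples (healthy controls get the unmodulated template), so vector
normalization cannot trivially erase it. The eight discriminant bands
carry effect 1.0 by default, modulated by a global `effect_scale`
(default 0.5); `effect_scale = 0` produces an exact null cohort for
leakage tests. Default cohort: 83 FM / 54 non-FM / 9 NC samples, four
replicates each, mirroring the study; the calibration/validation split
pins the study's 68+41 / 15+13 head counts when the sizes match and
falls back to a seeded stratified 80/20 otherwise.

Seeding: one master seed; each sample's random stream is derived from it
by sample counter, so cohorts are bit-reproducible and stable under
subsetting.

What the generator does **not** emulate: hot-spot enhancement
statistics, substrate aggregation chemistry, solvent effects,
instrument drift, cosmic rays, wavenumber calibration error, or
realistic inter-band correlation structure (band jitters are
independent). Perfect classification on these cohorts therefore shows
the pipeline is correct and leak-free, not that real FM serum is this
separable.

A photodegradation artifact (broad band at 1535 cm⁻¹, the
amorphous-carbon signature of laser damage) can be injected at chosen
severity; the QC flag compares the band's local prominence over its
±35 cm⁻¹ chord against 2× the median absolute fingerprint intensity and
is used to drop burned replicates before modelling.

## Problem sizes used in the test suite

Unit tests run on desk-scale cohorts (typically 20 FM / 14 non-FM,
occasionally 83/54 where split head counts matter); the seeded
study-replica checks use the full 83/54 × 4-replicate cohort across 20
seeds, and the null-leakage check runs full LOOCV (109 refits per seed)
across 20 seeds. These sizes were chosen to exercise every code path at
the study's dimensions while keeping the default test run fast.

## Known limitations

* **Internally studentized residuals break down at high leverage.** A
  flexible latent-variable model interpolates a single-sample artifact:
  its leverage approaches 1 while its training residual — and hence its
  internally studentized residual — collapses to 0, and a 1-component
  OSC filter removes sample-specific artifact directions outright
  (they are almost orthogonal to the class vector by construction). The
  leverage+residual screen is therefore most informative for low-rank
  fits; the planted-spike tests run it on a rank-1 PLS fit for exactly
  this reason. Externally studentized (leave-one-out) residuals would
  avoid the breakdown but are not the formulation replicated here.
* **Band attribution in second-derivative space is ambiguous.** The
  regression-vector report ranks local extrema of |b|; derivative side
  lobes sit ~24 cm⁻¹ from their parent band — often exactly on a
  neighbouring literature band — and unit-norm closure gives strong
  class-neutral bands a genuine anti-correlated signal. Overlapping
  table entries quoted at 1–4 cm⁻¹ separation (1013/1014, 1582/1586,
  1448/1453) cannot be resolved at 2 cm⁻¹ grid spacing with 10 cm⁻¹
  half-widths. Consequently a weak planted band adjacent to a strong
  neutral one (1582 beside 1586) is routinely displaced from the top of
  the report even when classification is perfect; the report is a map of
  discriminative *features*, not a deconvolution into physical bands.
* **The model p-value of the replicated workflow is not computed**: the
  source analysis reports one without naming a test, so none is guessed
  here (a label-permutation test would be the natural addition).
* Multiclass discrimination, integrated O-PLS, kernel PLS and
  ASDF-compressed JCAMP-DX input are out of scope.
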