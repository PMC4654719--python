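# Methods

Design notes for the thyrotex pipeline: the models implemented, the
parameter values and where they come from, the numerical conventions,
and the limitations of the synthetic validation. Symbols: `S(b)` is
diffusion-weighted signal at b-value `b` (s/mm²), ADC in mm²/s, `G`
gray levels after quantization.

## 1. ADC mapping

The two-point mono-exponential model assumes Gaussian diffusion and
identical TE between acquisitions:

    ADC = ln(S(0) / S(b)) / b,     default b = 500 s/mm²

**Noise floor.** Magnitude MRI noise is Rician; at low SNR it biases
`S(b)` upward and hence ADC downward. The optional correction
`S' = sqrt(max(S² − NF², 0))` removes the quadrature noise
contribution before taking the log; `NF` should be set to the measured
background noise SD. Pixels where either corrected signal is
non-positive are marked invalid; negative ADC estimates (noise pushing
`S(b) > S(0)`) are clipped to 0 and counted in `ADCMap.n_clipped` so a
high clip rate can flag bad data.

**Pooling.** Per-nodule ADC is the ROI-area-weighted mean of slice ROI
means. Weighting by pixel area approximates a volume average over an
anisotropically sampled nodule and keeps thin end-slices from dominating.

## 2. Texture catalogue

278 features per slice ROI, following the MaZda naming convention so
that feature lists are portable across analyses. The full name →
formula mapping is in `feature_registry.txt` (regenerate with
`thyrotex registry`).

**Quantization.** Intensities inside the ROI are mapped to integer
levels `1..G`, `G = 2^bits`, default 6 bits (64 levels). Default
normalization is `mu3sigma` (window `μ ± 3σ`, values outside clipped),
which makes co-occurrence statistics robust to outliers and roughly
intensity-scale invariant; `minmax` and `perc1_99` are available. A
constant ROI maps to level 1.

**Co-occurrence (GLCM).** 20 offsets: `(d,0), (0,d), (d,d), (d,−d)`
for `d = 1..5` pixels, written `S(dx,dy)` with `dx` the column offset
(rightward) and `dy` the row offset (downward). Matrices are
symmetric (both pixel orders counted) and normalized to sum 1; 11
Haralick statistics per offset. Conventions: natural logarithms,
`0·log 0 ≡ 0`, and sum variance is centred on the sum average (not on
sum entropy, a known erratum in the original formula table).

**Run length.** 4 directions (horizontal, vertical, both diagonals), 5
statistics, runs of identical quantized level; `Fraction` is runs per
ROI pixel. Runs are scanned within the ROI bounding box only — pixels
outside the mask break runs.

**Histogram.** Mean, population variance, skewness, excess kurtosis,
and the 1/10/50/90/99th percentiles of the raw (unquantized) in-ROI
intensities.

**Gradient.** Central-difference gradient magnitude at interior ROI
pixels (all 4 neighbours inside the mask); mean, variance, skewness,
kurtosis, and the fraction of non-zero magnitudes. Skewness/kurtosis
are set to 0 when the magnitude variance is numerically zero relative
to its mean (guard: `var > 1e-24·(1 + mean²)`).

**Autoregressive model.** Causal neighbours `(i,j−1), (i−1,j−1),
(i−1,j), (i−1,j+1)`, least-squares fit on mean-centred intensities
using only pixels whose whole neighbourhood lies in the ROI; `Teta1..4`
are the coefficients, `Sigma` the RMS residual. Fewer than 5 usable
pixels → NaN.

**Wavelet.** Haar DWT (periodization mode) of the ROI bounding box,
edge-replicated to a multiple of `2^3`; `WavEn{LL,LH,HL,HH}_s-{1,2,3}`
is the mean squared coefficient over subband blocks whose `2^s`-pixel
footprint overlaps the mask.

**Geometry.** Centroid position, centroid offsets within the bounding
box, and area-normalized second central moments of the binary mask.
These encode nodule size and shape, not signal texture: informative on
real data (malignant nodules trend larger) but a leakage channel in
simulations where size distributions differ by class, so
`TextureConfig(include_geometry=False)` excludes the family.

**Undefined values.** Features that cannot be computed for a given ROI
(wavelet scale larger than the ROI, no interior gradient pixels, too
few AR pixels) are NaN. The table builder drops feature columns that
are NaN for every slice and excludes (with a log message) slices with
remaining NaNs, so small-ROI cohorts degrade gracefully instead of
failing.

## 3. Feature selection

Three rankings are computed on the training slice table:

- **Fisher coefficient** `F = (μ₁−μ₂)² / (s₁²+s₂²)` with unbiased
  variances — fast, univariate, favours well-separated means.
- **Mutual information** between each feature (equal-frequency 10-bin
  discretization) and the class label, in nats — captures non-linear
  association.
- **POE+ACC**: greedy forward selection minimizing
  `POE + |average correlation|`, where POE is the probability of error
  of a nearest-class-mean rule on the standardized feature and ACC the
  mean absolute Pearson correlation with already-selected features —
  penalizes redundancy.

The top `k = 10` from each method are pooled (union, ordered by mean
within-method rank, absent → rank k+1, Fisher score as tie-break).
Backward elimination then evaluates head subsets of size
`m = |pool|..2` by resubstitution LDA error and keeps the smallest
subset attaining the minimum. Resubstitution error is optimistic; it is
used here only as a subset-comparison criterion, never reported as an
unbiased performance estimate.

## 4. Discriminant and decision rules

Features are z-scored with training statistics. The LDA direction is
`w ∝ Sw⁻¹(μ_mal − μ_ben)` with pooled within-class covariance; if `Sw`
is ill-conditioned (condition number > 1e8) a ridge term is increased
by factors of 10 from 1e-8 until it is not. `w` is unit-normalized and
oriented so malignant scores high; the offset centres the training
scores at zero. MDF1 = the projection onto `w`.

The slice cutoff sweeps midpoints between consecutive sorted training
scores, minimizing training error with maximum Youden's `J` as
tie-break. A nodule is called malignant when its *minimum* slice score
exceeds the cutoff: all slices of a nodule share its histology, so a
nodule is benign-looking only if even its most benign-looking slice
is. This lowest-slice rule is provably no more malignant-calling than
an any-slice rule and matches clinical conservatism about partial
sampling.

Models serialize to JSON (`LDAModel.to_json`) so training and
deployment can be separated.

## 5. Evaluation

Misclassification percentages are reported to one decimal.
Sensitivity/specificity carry Clopper–Pearson exact 95% intervals
(beta quantiles) — appropriate at the small n typical of nodule
studies, where normal approximations misbehave. ROC curves sweep
distinct score thresholds (ties move the operating point diagonally);
AUC is trapezoidal with a Hanley–McNeil standard error. Group ADC
comparisons use Welch's t-test with Satterthwaite degrees of freedom —
class variances are not assumed equal (and in this domain are not).

## 6. Synthetic cohort generator

The generator emulates a two-site study: a training site and an
independent test site with 25% higher Rician noise SD, so held-out
performance reflects a genuine acquisition shift, not just new noise
draws.

Per nodule: a diameter is drawn from a class-conditional normal
(benign 29.3 ± 8.0 mm, malignant 33.3 ± 10.4 mm, floor 8 mm,
redrawn until every slice ROI has ≥ 17 pixels); 1–7 slices (uniform)
cut an ellipsoid, end slices scaled by the spherical chord; elliptical
ROIs with eccentricity U(0.6, 1.0); position independent of class. The
nodule-mean ADC is drawn from class-conditional normals
(benign 2.24·10⁻³ ± 0.30·10⁻³, malignant 1.92·10⁻³ ± 0.39·10⁻³ mm²/s —
between-nodule SDs back-computed from published 95% CIs of class
means), with 0.05·10⁻³ between-slice jitter. Within-slice texture is a
Gaussian random field whose correlation length and amplitude differ by
class (benign: smoother, 4.0 mm correlation length, 0.10·10⁻³ SD;
malignant: rougher, 1.5 mm, 0.35·10⁻³), planting the
heterogeneity-based separability the texture pipeline is designed to
detect. Background ADC is 1.2·10⁻³. Signals are synthesized as
`S(0) = s0·(1 + 0.05·GRF)` and `S(b) = S(0)·exp(−b·ADC)`, then
Rician-corrupted (default SD 8 at `s0 = 400`). Matrix 256, FOV 220 mm
(0.859 mm pixels), matching common clinical DWI geometry.

`CohortConfig.null()` zeroes every class difference (ADC means,
diameters, texture parameters equalized) for calibration controls.

**What the generator does not emulate:** real histological subtypes
(each class is one homogeneous population), partial-volume and
susceptibility artifacts, anisotropic voxels and slice gaps, reader
variability in ROI placement, and any correlation between nodule size
and ADC. Its purpose is pipeline validation against known ground
truth, not data augmentation.

## 7. Calibration and validation choices

- **Planted-signal recovery.** With noise off, ADC maps reproduce the
  planted fields to 1e-12 relative error, and 200 nodules per class
  recover the class mean ADCs within 3 standard errors — the generator
  and the estimator are checked against each other, not tuned jointly.
- **Null control is out-of-sample.** On a null cohort, *resubstitution*
  slice AUC is well above 0.5 (≈ 0.7 at 26 nodules) — an expected
  consequence of selecting ~30 of 278 features on the same data, not a
  bug. Chance-level behaviour is therefore asserted on an independent
  null test split (held-out AUC ≈ 0.4–0.6). Any in-sample null band
  would either fail or have to be widened until meaningless.
- **Oracles.** Every texture family is tested against independent
  brute-force double-loop implementations; LDA against a generalized
  eigenvector solution; AUC against the Mann–Whitney statistic;
  selection against exhaustive greedy re-computation.
- **Problem sizes.** Default study sizes (16+8 training, 9+9 test
  nodules) are small on purpose — they match the regime the method
  targets, where exact intervals and conservative decision rules
  matter. Tests use reduced matrices (64–96 px) with the study's pixel
  spacing preserved so texture length scales are unchanged.

## 8. Known limitations

- The two-point ADC estimator cannot separate perfusion (IVIM) from
  diffusion; low-b contamination inflates ADC.
- Resubstitution-driven backward elimination can overfit at very small
  n; the held-out site run is the honest performance estimate.
- The feature catalogue is 2-D per slice; no 3-D texture is computed.
- The LDA cutoff is trained on slices pooled across nodules, ignoring
  within-nodule correlation; intervals on slice-level metrics are
  accordingly anti-conservative.
- Synthetic results transfer to real data only to the extent the
  generator's simplifications (Section 6) are tolerable.
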