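# Methods

This note documents the models and procedures behind fibroquant, the defaults
that matter, and what the synthetic experiments do and do not establish.

## Forward model: synthetic trichrome tiles

A slide is modeled as a per-pixel class map over four classes — GLASS,
MYOCARDIUM, FIBROSIS, OTHER — where OTHER stands for inflammation, necrosis
and glass-like clearings inside the tissue. Phantoms are built from smoothed
Gaussian random fields: one field thresholded at a quantile defines the
tissue/glass split (default 75% tissue), a second defines small OTHER blobs
(default 2% of tissue), and a third, anisotropically smoothed field
(default sigma 5 px, 3× stretched along columns, giving strand-like collagen)
is thresholded *by pixel count* inside the effective tissue so that the
fibrosis fraction of MYOCARDIUM+FIBROSIS pixels equals the requested target
to within one pixel. Only the area fraction and a plausible spatial
contiguity matter downstream; no attempt is made at nuclei, cell morphology
or scanner artifacts.

Rendering follows Beer–Lambert: each pixel carries the three stain amounts of
its class (plus optional i.i.d. Gaussian amount noise, default SD 0.02 OD,
clipped at 0), the OD triple is `amounts · V`, and the transmitted intensity
`I0 · 10^(−OD)` is rounded to 8-bit. Defaults:

| parameter | default | why |
|---|---|---|
| OD vectors `V` | iron hematoxylin ≈ (0.577, 0.577, 0.577); red (0.100, 0.737, 0.668); collagen blue (0.800, 0.591, 0.105), unit rows | iron hematoxylin is a near-neutral blue-black absorber; the triple keeps the matrix well conditioned (cond ≈ 8.8) so unmixing does not amplify quantization noise. Config-overridable; no canonical trichrome matrix exists. |
| background `I0` | (252, 252, 252) | just-off-white glass as scanners produce |
| class amounts | myocardium (0.20, 0.70, 0.02); fibrosis (0.05, 0.05, 0.75); other (0.03, 0.02, 0.02); glass 0 | strong single-stain dominance per class with per-channel OD ≤ ~0.8, keeping 8-bit quantization error below 0.01 OD after unmixing |
| amount noise SD | 0.02 OD | visible texture without class overlap — per-pixel amounts stay ≥ 5 SD from the 0.15 thresholds |

OTHER is rendered at near-zero OD, i.e. visually glass-like. This is the one
substantive modeling choice with downstream consequences: the colocalization
route, whose tissue denominator is "any stained pixel", then excludes OTHER
just as the ground-truth denominator and the stereology rule do. Had OTHER
been rendered stained, the colocalization estimate would carry a systematic
~2% multiplicative bias by construction of its denominator.

Cohorts draw per-slide targets stratified-uniform over 0–90% so the range is
always covered. Pathologist scores are truth + Gaussian noise (default SD
4 pp), rounded to the nearest 5 pp and clipped to [0, 100]; two readings are
simulated with independent seeds. Slide-to-slide staining variability is not
modeled by default (an OD-amount jitter hook exists in the stain model but
there is no principled value to set it to).

## Colocalization route

`OD_c = −log10(max(pixel_c, 1)/I0_c)`, clamped at 0 above the white level;
the 1-count floor guards the zero pixel (a black pixel maps to
`log10 I0 ≈ 2.4`). Unmixing solves `amounts = OD · V⁻¹` exactly. A stain is
*present* iff its deconvolved amount is strictly greater than its threshold
(default 0.15 OD per stain; thresholds act in amount space, not channel
intensity). Negative amounts arising from noise are kept and simply fail the
threshold. Fibrosis % = share of non-NONE pixels in patterns 3, 2+3, 1+3.
The eight-color markup uses a fixed documented palette with NONE white.

Numerically, the noiseless round trip (compose → quantize to 8 bits →
unmix) recovers per-class amounts to < 0.01 OD; this bound is what makes the
route's recovery error on noiseless tiles essentially zero, limited to
boundary pixels only in principle (phantom classes are pixel-pure, so in
practice even those vanish).

## Pixel classifier (pattern-recognition surrogate)

The engine is a multinomial logistic model fitted by SGD (log loss,
`max_iter` = the iteration budget, default 1000) on standardized 9-feature
vectors: the OD triple plus local mean and local population SD of each OD
channel over an odd square window (default 7 px ≈ 3.5 µm at 0.5 µm/px),
reflect-padded; window 1 degenerates to raw OD with zero SD. "Spatial
recognition only" is interpreted as exactly these pointwise + local-window
statistics — no connected-component or shape descriptors. Class imbalance is
handled with inverse-frequency class weights (switchable). Training accuracy
is reported by reclassifying the training pixels, and the variance of local
features is computed after centering each channel so constant inputs yield
exactly zero. Models persist to a single joblib file with a format-version
header. The three classes the route distinguishes are myocardium, fibrosis
and glass; OTHER tissue is never marked for training and, being rendered
glass-like, is absorbed by the glass class, which the tissue rule then
ignores.

## Stereology

Grids are square lattices anchored at the ROI origin plus an offset, with a
half-open convention on the ROI; `offset="random"` draws the offset uniformly
in `[0, interval)²` (seeded), which is what makes the estimator unbiased.
`pattern_size` only affects the drawn marker, never counting. The fraction is
`n_fib / (n_fib + n_myo)` — glass and other excluded from the denominator,
and likewise from the `n` entering the uncertainty. Uncertainty is the
binomial point-counting relative SE `sqrt((1−p)/(p·n))`, undefined at p = 0
(reported as None, never NaN); this is the standard expected relative error
for point counts and is validated against a binomial Monte-Carlo in the test
suite. On multi-megapixel slides the default 200 px interval yields ≥ 500
points on ≥ 4.5 Mpx of tissue; the desk-scale study uses interval 8 on
256×256 tiles for the same reason (~750 effective points per tile, the study
size chosen to keep a full run in seconds per cohort).

Calibration note: with random offsets on smoothed-field phantoms
(correlation length ≪ grid spacing), the empirical SD over offsets sits
within ~10% of the binomial prediction; systematic grids on strongly
structured tissue could beat the binomial bound, which would make the quoted
RSE conservative.

## Agreement battery

* Summary stats use the n−1 SD and midpoint medians; range = max − min.
* Pearson p-values are two-sided via the t distribution with n−2 df;
  zero-variance columns yield explicit NaN entries.
* Friedman uses within-slide average ranks with the tie-corrected statistic
  `[12/(nk(k+1)) Σ R_j² − 3n(k+1)] / [1 − Σ(t³−t)/(nk(k²−1))]`, df = k−1,
  computed in-package so that fully tied data (identical columns) is defined
  as χ² = 0 rather than 0/0; scipy's implementation is the cross-check on
  tie-free data. Default columns: stereology, colocalization, genie,
  pathologist_mean (four methods, df 3, with the two pathologist readings
  collapsed to their arithmetic mean).
* Wilcoxon signed-rank drops zero differences, uses average ranks on tied
  absolute differences, the tie-corrected variance `n(n+1)(2n+1)/24 −
  Σ(t³−t)/48`, and no continuity correction; Z is signed by the rank-sum
  excess so reversing a pair flips it. The normal approximation is compared
  against exhaustive 2⁸ sign enumeration at n = 8 in the tests (agreement
  within 0.03 in p). The Bonferroni-adjusted alpha is family α / #pairs
  (0.05/4 = 0.0125 for the default four pairs). Reported mean/SD are of the
  raw differences.
* Regression is OLS with r² = squared Pearson r and a 95% mean-response
  confidence band; the ln variant transforms both variables by `ln(x + 1)` —
  the +1 pp offset makes zero measurements finite and is configurable.
* Bland–Altman plots differences (test − reference) against the *reference*
  values, not the pairwise mean, since stereology is treated as the criterion
  standard; LoA = mean ± 2·SD (sample SD), multiplier configurable; p-values
  below 0.001 are always displayed as "<0.001".

## Study pipeline

One tile stands for one slide. The synthetic study defaults to 116 slides of
256×256 px at 0.5 µm/px nominal scale, amount noise 0.02 OD, grid interval 8,
classifier trained once on regions subsampled from the first three slides
(up to 4000 px per class). All seeds derive from the single config seed;
identical configs produce byte-identical CSVs (fixed float formatting, no
timestamps in the metadata). Failures abort with a stage-named error.

## What the synthetic experiments show — and what they do not

Passing tests establish internal correctness: the unmixing inverts the
forward model, the grid estimator is unbiased with calibrated uncertainty,
the classifier recovers known fractions under the modeled noise, and the
statistics match independent oracles. They do not establish performance on
real slides: real trichrome staining varies between labs and slides, stain
colocalization within a pixel is genuine (not class-pure), collagen borders
are diffuse, and pathologist error is not i.i.d. Gaussian. In this clean
setting the two digital routes agree almost perfectly with each other and
with the reference (r ≈ 1), i.e. the synthetic study exercises the machinery
end to end but cannot reproduce the method *disagreements* that arise from
real-tissue ambiguity — only their statistical treatment.

## Known limitations

* The classifier surrogate is linear in its 9 features; heavily overlapping
  stain mixtures would need a richer model (the interface hides the learner,
  so swapping it is local).
* Colocalization thresholds are global scalars; no per-slide adaptation.
* The stereology route counts single pixels at lattice nodes; projection
  effects of 3 µm-thick sections are inherited from the imagery and not
  modeled.
* `le`-style guarantees on round-trip error hold for the default stain model;
  severely ill-conditioned user matrices will degrade them (the constructor
  rejects only near-singular ones).
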