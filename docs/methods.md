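# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what the synthetic phantom does and does not establish.

## Imaging model

A specimen is a ~5 mm tumour slice imaged twice without moving it, giving a
17-channel stack pre-registered on one 0.15 mm pixel grid:

- **micro-CT** (1 channel): linear attenuation coefficient mu in mm^-1 at a
  50 kVp tube setting. Raw scanner units are converted through a two-point
  affine calibration anchored at air (mu = 0) and water (mu = mu_water,
  default 0.0227 mm^-1 — a configurable placeholder, not a measured value).
  Negative results are clamped to zero and counted.
- **SFDI** (16 channels): calibrated diffuse reflectance R_d at four
  wavelengths (490/550/600/700 nm) x four illumination spatial frequencies
  (0.00/0.15/0.61/1.37 mm^-1). For f > 0 the projector casts
  `I_k(x) = S R(x) [1 + cos(2 pi f x + phi_k)] / 2` with three equispaced
  phases (modulation depth 1); the AC amplitude is recovered per pixel by
  `M_AC = (sqrt(2)/3) sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)`, which is
  exactly the sinusoid amplitude and invariant to a global phase offset.
  The f = 0 channel is planar illumination; its amplitude is the
  three-frame mean. Calibration divides by the amplitude of a standard of
  known reflectance imaged under the same illumination:
  `R_d = (M_sample / M_ref) R_ref`. Values above 1 are physically suspect
  (specular or noise artifacts) and are flagged and counted, not clipped.
  The standard's true reflectance per channel is a configuration input.

With zero simulated noise the forward-then-inverse chain reproduces truth
reflectance to machine precision (the test suite asserts <= 1e-9 relative
error), so any information loss in realistic runs is attributable to the
modelled noise, not the processing.

Invalid pixels (poor acrylic-plate coupling, calibration targets) are
carried as a boolean mask beside the stack, never as a magic pixel value;
sampling refuses windows touching them.

## Synthetic phantom

The generator exists so that every downstream stage has a fully specified,
seeded input distribution. It emulates:

- **Seven tissue subtypes** (adipose, normal connective, fibrocystic
  disease, IDCa low/intermediate/high grade, ILCa; the latter four are the
  malignant class) placed as non-overlapping elliptical ROIs (area drawn
  from 55-130 mm^2, in the range of reported per-subtype ROI areas) on a
  256 px field. Subtype prevalence weights default to a cohort-like
  composition in which adipose is by far the most frequent subtype.
- **Cohort structure**: one patient per specimen; specimens are benign-only
  / malignant-only / mixed in proportions 14 : 3 : 37 (largest-remainder
  apportionment), the composition of the motivating 54-specimen cohort.
- **Channel appearance**: each subtype has a mean attenuation and a mean
  reflectance per (wavelength, frequency) built as
  `dc_reflectance x wavelength_gain x frequency_falloff`. The table is
  synthetic and ordering-faithful only: adipose attenuation is strictly
  lowest; fibrous subtypes keep high reflectance at 1.37 mm^-1 (Rayleigh
  backscatter from collagen fibrils); adipose and high-grade IDCa have the
  lowest high-frequency reflectance (large Mie-regime scatterers). Adipose
  is deliberately given the *same* optical appearance as high-grade IDCa,
  and invasive cancers sit only slightly above fibrous tissue in
  attenuation, so the modalities are complementary by construction: CT
  separates adipose, high-frequency optics separates fibrous from
  malignant, and neither arm alone suffices.
- **Texture**: a per-ROI Gaussian random field (per-subtype correlation
  length 0.35-0.7 mm and amplitude 6-14% of the mean) multiplied onto the
  optical channel means. The micro-CT channel uses a subtype-independent
  texture (0.6 mm, 9%) — dense tissues are not texture-distinguishable by
  attenuation here, which keeps the fibrous/malignant texture signal
  optical-only. A subtype with texture amplitude zero gets no texture in
  any channel (the degenerate contract used by tests).
- **Patient effects**: one lognormal intensity factor per (specimen,
  modality), SD 0.08. This induces within-patient correlation, which is
  what makes patient-level splitting consequential and sample-level
  splitting measurably leaky (a test asserts the inflation).
- **Raw acquisitions**: three-phase SFDI frames plus matched
  reference-standard frames with additive Gaussian noise (default 1% of
  the signal scale), and a raw CT slice in arbitrary scanner units with
  air/water calibration disks stamped into the corners.

Not emulated: physics-based light transport, X-ray spectra and beam
hardening, specular artifacts, histology co-registration error, and any
quantitatively realistic per-subtype intensity distribution. Passing tests
therefore demonstrate the *pipeline's* correctness and the qualitative
modality-synergy mechanism, not clinical performance; synthetic AUCs are
not estimates of performance on real tissue.

## Feature quantification

92 features per channel: 18 first-order statistics plus five texture
families on fixed-bin-width discretized images
(`level = floor((x - min_edge)/W) + 1`, min_edge defaulting to the window
minimum). Bin widths are per modality — 0.002 mm^-1 for attenuation, 0.01
for reflectance — chosen so typical synthetic windows discretize to
roughly 16-128 levels; they are tuning defaults, not measured values.

Conventions (shared by the brute-force oracles in the test suite):

- **GLCM** (23 features): distance 1, four angles, symmetric; per-angle
  normalization then angle averaging, so entries sum to 1. Correlation and
  MCC are defined as 1 on a zero-variance window.
- **GLRLM** (16): maximal equal-level runs along the four directions,
  per-direction count matrices merged (summed) into one matrix before
  feature computation (merged aggregation; a single matrix per family is
  the package's data model).
- **GLSZM** (16): 8-connected zones, inherently rotation invariant.
- **GLDM** (14): dependence = neighbours within Chebyshev distance 1 whose
  level differs by at most alpha (default 0); the matrix column is
  dependence + 1 so an isolated pixel lands in column 1 and no feature
  divides by zero.
- **NGTDM** (5): 3x3 neighbourhood excluding the centre, border pixels
  averaged over available neighbours; coarseness capped at 1e6 on
  homogeneous windows.
- **First-order** (18): population moments; skewness and kurtosis defined
  as 0 on constant windows; entropy/uniformity computed on the discretized
  histogram (base-2).

Feature columns are named `{channel}__{class}__{feature}` (e.g.
`w490_f1.37__glcm__Contrast`), which makes per-channel selection-frequency
tabulation a string split.

## Feature selection

MRMR with the MID (difference) scheme: greedy forward selection maximizing
`MI(f; y) - mean MI(f; s)` over already-selected s, ties broken by column
order. Mutual information is the plug-in estimator (base 2) on
equal-frequency 10-bin codes; duplicate quantile edges collapse, so
constant features have zero relevance. Binning and ranking are computed on
whatever data is passed in — inside cross-validation that is the training
split only, so no test information reaches selection. Features are not
standardized: MRMR sees rank bins and random forests are monotone
invariant, so standardization would be a no-op.

The operating feature count is the smallest k >= 2 at which mean accuracy
changes by less than 1% relative to k - 1 (falling back to the largest k
evaluated). On the default synthetic cohort this rule lands on k = 6 (the
acceptance script recomputes this each run).

## Evaluation

- **Splits**: Monte Carlo cross-validation at the patient level;
  `round(0.3 x n_patients)` test patients per split, redrawn (bounded)
  until both classes appear on both sides. Split seeds are spawned from
  one root SeedSequence, so runs are reproducible and splits independent.
- **Classifier**: scikit-learn random forest, 500 trees and sqrt(p)
  features per node by default, seeded per split. Accuracy, recall and
  precision use a 0.5 vote-fraction threshold.
- **ROC**: empirical curves; AUC is the tie-corrected Mann-Whitney
  statistic. Averaged ROCs interpolate member TPRs onto a 101-point FPR
  grid pinned at (0,0) and (1,1); the 95% band is the pointwise envelope
  of the floor(0.95 n) member curves closest (mean absolute vertical
  distance) to the mean curve. The grid-integrated mean curve agrees with
  the mean member AUC to <= 0.01 by construction of the grid.
- **DeLong**: fast placement-value formulation; the paired variant (two
  classifiers scoring the same pooled out-of-test samples) and the
  unpaired variant are both reported, because applying a single-sample
  test to quantities averaged over many splits is ambiguous — pooling
  out-of-test scores across splits is this package's documented choice,
  presented as such. Zero variance with equal AUCs yields z = 0, p = 1;
  with unequal AUCs it is an error.

## Problem sizes

Defaults target the full design (1000 splits, 500 trees). The test suite
and the acceptance script run reduced designs chosen as the smallest that
still exercise every code path with stable statistics: 12-specimen cohorts
(~70-100 sub-images), 100 Monte Carlo splits, 100-200 trees, and a
25-split accuracy-vs-k curve. These are the package's own scaling choices
for routine verification; the full design is a configuration change.

## Known limitations

- 2D extraction only; no shape, wavelet or filtered-image features.
- No optical-property (mu_a, mu_s') inversion; reflectance is used as-is.
- The MRMR variant (MID), MI binning, and the classification threshold are
  reasonable defaults where the method family leaves them open; all are
  config-exposed.
- The exact feature-set composition matches the 92-feature default of the
  reference radiomics tooling by class counts (18/23/16/16/14/5), but no
  byte-level compatibility with any external parameter file is claimed.
- DeLong on pooled scores treats split overlap as exchangeable; p-values
  on synthetic cohorts should be read as orderings, not calibrated
  clinical inference.
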