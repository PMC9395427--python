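# Methods

## The dyadic design

All inference operates on unordered subject pairs. With *n* subjects
there are exactly n(n−1)/2 dyads; every subject appears in n−1 of them,
so dyadic observations are not independent and ordinary OLS p-values
are anti-conservative. The package therefore reports parametric
p-values only alongside Mantel-style permutation p-values, which are
the quantities of record.

## Synthetic generative model

One linear model produces every neural modality. For subject *i* and
signal unit *r* (a region, a voxel, or an EEG source):

    x_ir(t) = a·s_r(t) + γ·Σ_k p_ik·g_rk(t) + ε_ir(t)

- `p_i ∈ R^K`: latent Big Five vector, i.i.d. standard normal per trait.
- `s_r`, `g_rk`: unit-variance signals shared by all subjects,
  generated as Gaussian-smoothed white noise (kernel width
  `signal_smooth_sigma`, default 3 samples) and standardized. The
  smoothing supplies the temporal structure that ISC-style estimators
  assume; it changes the effective number of independent samples but
  not the cross-subject covariance algebra.
- `ε`: i.i.d. N(0, σ²) subject noise.

The population Pearson correlation between two subjects' series is

    ρ_ij = (a² + γ²·p_i·p_j) / sqrt((a² + γ²|p_i|² + σ²)(a² + γ²|p_j|² + σ²))

(`expected_dyad_correlation`), the oracle against which generated data
and the synchrony estimators are verified (empirical − closed-form
error < 0.02 at T = 50 000). Setting γ = 0 makes synchrony
personality-independent; this is the exact null used for calibration.

**EEG.** Sources follow the model without source noise; a fixed
forward matrix with rows normalized to unit L2 norm mixes them to
channels, and i.i.d. N(0, σ²) sensor noise is added per subject. With
unit-norm rows and independent sources, each channel's cross-subject
correlation follows the same closed form as the fMRI magnitudes, so one
oracle covers both modalities. At σ = 0 and equal traits, epochs are
identical across subjects.

**Surveys.** Facet latents are the trait latent plus a facet-specific
N(0, `facet_scatter_sd`²) offset (default 0.5), so facet-level analyses
are non-degenerate while facets still aggregate to their trait. Items
map the facet latent affinely onto the Likert range (midpoint ± 2 SD
spans the scale), add N(0, `item_noise_sd`²) noise, and are rounded and
clipped; every second item of a facet is administered reverse-keyed.
Similarity is always computed on scored traits or facets, never raw
items. The default `item_noise_sd = 1` produces short-questionnaire
reliabilities comparable to real 2-item-per-trait instruments.

**Gaze.** Each image has K attractor locations, a shared Dirichlet
mixture prior, and per-attractor trait loadings. A subject's mixture
weights interpolate between the shared prior and a softmax
trait-determined prior with coefficient `gaze_coupling`: at 0, fixation
distributions are exchangeable across subjects; at 1, equal-trait dyads
have minimal expected earth-mover distance. Fixation positions scatter
around the chosen attractor (`attractor_dispersion`, unit-square SD),
durations are Gamma(4, mean/4) milliseconds, floored at 1 ms.

**Defaults as study conditions.** The configuration defaults encode the
two emulated study designs: 66 subjects / 200 cortical + 14 subcortical
regions / 4 runs for the fMRI-like arm; 225 subjects / 104 images in 26
categories / 32 channels at 500 Hz with 3-s epochs for the EEG-like
arm; TIPI-like (5×1×2 items on 1–7) and BFI-2-like (5×3×4 items)
surveys. The coupling constants `a = 0.3, γ = 0.15, σ = 1` were chosen
once so that baseline inter-subject correlations sit in the 0.05–0.15
range typical of naturalistic-viewing data, with dyad-to-dyad variation
small relative to noise. Generating the *pattern* arrays at the full
default scale is memory-hungry (subjects × regions × voxels × time);
analyses in the tests and the acceptance script use reduced designs
(stated below) that preserve the full structure.

**Seeding.** A single master seed; per-modality substreams are derived
through fixed `SeedSequence` spawn keys (profiles/fmri/eeg/forward/
gaze), so regenerating one modality never perturbs another and every
dataset is bit-reproducible.

What the generator does *not* emulate: hemodynamics, realistic EEG
spectra or topographies, saccade dynamics, atlas geometry,
stimulus-specific coupling (γ is constant across stimuli). Passing
tests therefore demonstrate correctness of the estimators and inference
machinery under the stated model, not fidelity to any particular real
dataset.

## Estimators

**Trait scoring.** Reverse-keyed items are reflected as
`scale_min + scale_max − response`; facet = mean of items, trait = mean
of facets; missing responses are an error (no imputation). Internal
consistency is Cronbach's α.

**Similarity metrics.** Euclidean, Manhattan and Supremum are the
textbook definitions (scipy); Canberra uses the |x+y| denominator and
errors on a zero-denominator coordinate. All are negated by default so
that every predictor points "higher = more similar". Facet-level
overall similarity is Euclidean over the 15 facet scores; single-facet
similarity is the negated absolute difference.

**NM-synchrony** is the Pearson correlation of two subjects'
concatenated region time series. Runs excluded for either member of a
dyad are dropped for both (run-intersection), keeping the two series
aligned on the same stimuli. Excluded runs hold NaN in the container so
silent use is impossible.

**NP-synchrony** defaults to timepoint-wise spatial correlation across
voxels, Fisher-z averaged (r clipped to ±(1−1e−7) before arctanh);
zero-variance slices are dropped with a warning. A per-voxel temporal
variant (`variant="voxelwise"`) is exposed because the
pattern-similarity literature contains both readings; the voxelwise
variant converges to NM-synchrony when every voxel is the region signal
plus small i.i.d. noise.

**CorrCA** is fit per dyad and image: channels are centered,
`Rw = R11 + R22` is regularized as `(1−α)Rw + α·mean(diag Rw)·I`
(default shrinkage α = 0.05, exposed; 0 is exact on full-rank data),
and the eigenvectors of `Rw⁻¹Rb` with `Rb = R12 + R21` are sorted by
the real part of their eigenvalues. The reported ISC is the Pearson
correlation of the projected time courses (not the raw eigenvalue; the
two coincide under equal variances), averaged over the top 3 components
and then over images. Complex eigenpairs of the non-symmetric product
are reduced to real parts — standard practice for this eigenproblem.

**Gaze EMD.** Fixations are binned by dwell time on a 32×32 grid over
the unit square (pixel coordinates normalized by screen size; cells
half-open with the last cell closed). EMD is solved exactly as a
transportation LP (HiGHS) restricted to nonzero cells, with Euclidean
ground metric between cell centers; it is symmetric, satisfies the
triangle inequality, and is bounded by √2. Unit-square normalization
makes values comparable across images and screens. No Gaussian
smoothing is applied by default (dwell time only).

## Inference

**Standardized OLS.** Outcome and regressors are z-scored across dyads
before fitting; with a single predictor the coefficient is exactly the
dyadic Pearson correlation. Implemented directly via least squares
(validated against statsmodels in the tests) because the permutation
loop needs thousands of cheap refits; rank-deficient designs raise and
name the collinear columns.

**Permutation scheme.** The test statistic is the predictor's t-value.
Each permutation draws one random permutation of subject identities and
applies it to the rows and columns of the tested predictor's n×n dyadic
matrix — exactly equivalent to shuffling the underlying subject-level
attribute and re-deriving all dyad values, for any measure that is a
function of the two subjects' own data, and far cheaper. Covariates
stay fixed (the partial effect is tested). Two-sided p with the +1
correction; default 1 000 permutations (p-floor 1/1001), configurable
to 10 000. The t-statistic rather than the raw coefficient matters when
the tested predictor is collinear with covariates: the sampling
variance of the partial coefficient is inflated by 1/(1−R²), which
shuffled copies do not inherit, so a raw-coefficient null is
anti-conservative; the t-statistic is approximately pivotal and removes
the distortion (verified in the mediation calibration tests).

**Calibration.** Under the γ = 0 generator the permutation p-values are
uniform (KS test over 200 replicate datasets) and the rejection rate at
α = 0.05 stays within [0.03, 0.07]. The calibration design uses 16
subjects (120 dyads), 3 regions, 2 runs of 80 timepoints, and 199
permutations per replicate — small n makes Mantel tests slightly
liberal (observed ≈ 0.06–0.075 at n = 12), and 16 subjects is the
smallest design we found that holds the nominal level comfortably.

**FDR** is Benjamini–Hochberg (statsmodels), applied across regions
within each synchrony measure; facet-level analyses are left
uncorrected. **Network tests** are descriptive one-sample t-tests of a
network's regional coefficients against zero, flagged as computed on
non-independent regional coefficients.

**Mediation.** a: M~X; b: Y~M+X; c: Y~X; c′: Y~X+M; indirect = a·b,
and c = c′ + a·b holds to 1e−8 on any fixed sample. Path p-values come
from the subject-shuffling test (X's identities for a, M's for b). The
indirect effect's permutation p is the joint-significance rule
max(p_a, p_b): a joint-shuffle product null (shuffling X and M
independently and comparing a·b to a*·b*) was implemented first and
found anti-conservative under the partial null "a strong, b = 0" — the
shuffled product collapses toward zero while the sampling spread of
a·b̂ stays wide — so the level-controlling rule is used, with the
product-null quantiles still reported for inspection.

**Per-subject effects** re-run the regression on each subject's n−1
dyads and report the distribution of coefficients and the fraction
positive. **Effect-size comparison** is a pooled two-sample t-test
between two predictors' coefficient vectors across k focal effects
(df = 2k−2); a Wald contrast on two coefficients from one joint model
is available for within-model comparisons.

## Pipeline and problem sizes

`run_pipeline` executes generate → similarity → synchrony → infer into
one run directory (arrays in HDF5, everything else CSV/JSON) with a
manifest; identical config + seed reproduces every artifact
byte-for-byte. The CLI (`dyadsync generate|similarity|synchrony|infer|
run|report`) is a thin wrapper over the same functions.

The reduced-scale reference study used by the test suite and
`scripts/acceptance.py` is 20 subjects (190 dyads), 10 regions × 4
voxels over 4 runs × 100 timepoints, 20 images × 8 channels × 250
samples, 6 fixations per image, 500 permutations per test; the
calibration loops use the design above. These sizes preserve every
structural feature of the full designs (which the config defaults
encode) while keeping a complete run in the minutes range on one CPU.

## Known limitations

- The generator's linearity gives a closed-form oracle at the price of
  realism: no nonstationarity, no stimulus-specific coupling, no
  channel-noise inhomogeneity.
- Mantel permutation with fixed covariates tests the partial effect
  under exchangeability of the tested attribute; it is not an MRQAP
  replacement and no mixed-effects alternative is provided.
- Canberra similarity is undefined when a coordinate pair sums to zero;
  on Likert-scored data (all positive) this cannot occur.
- Split-half reliability of synchrony correlates region-averaged
  per-dyad values by default; the per-region option is exposed but the
  default is the minimal-variance summary.
- NP-synchrony's exact historical formula is ambiguous in the
  pattern-similarity literature; both defensible variants are
  implemented, timepoint-wise being the default.
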