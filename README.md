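# dyadsync

Do people with similar personalities experience the world more similarly?
One way to ask this quantitatively is to check whether two people's brain
activity is more *synchronized* while they view the same naturalistic
stimuli when their Big Five personality profiles are closer. `dyadsync`
is a tested, reusable pipeline for exactly this kind of dyadic analysis:
it turns per-subject surveys, neural recordings and eye-gaze data into a
table with one row per unordered subject pair, and runs
permutation-based inference that respects the dependence structure of
dyadic data. It is aimed at social-neuroscience and
individual-differences researchers who work with inter-subject
correlation designs.

## What it computes

**Similarity predictors** (one per dyad, higher = more similar):

- Personality similarity: a distance between two subjects' trait (or
  facet) score vectors, subtracted from zero —
  `s(x, y) = −d(x, y)` with `d` one of Euclidean
  `√Σᵢ(xᵢ−yᵢ)²`, Manhattan `Σᵢ|xᵢ−yᵢ|`, Canberra
  `Σᵢ|xᵢ−yᵢ|/|xᵢ+yᵢ|`, or Supremum `maxᵢ|xᵢ−yᵢ|`.
- Socio-demographic similarity: binary same/different codings for
  gender, handedness, nationality; set overlap for ethnicity; negated
  absolute differences for age and 7-point political ideology.

**Synchrony outcomes** (one per dyad):

- *NM-synchrony* — Pearson correlation of two subjects'
  spatially-averaged region time series (region-parcellated fMRI-like
  data, runs concatenated, excluded runs intersected across the dyad).
- *NP-synchrony* — timepoint-wise spatial correlation of voxel
  patterns, Fisher-z averaged (a per-voxel temporal variant is exposed
  as an option).
- *EEG ISC* via two-subject correlated components analysis (CorrCA):
  with within-subject covariances `R₁₁, R₂₂` and cross-covariances
  `R₁₂, R₂₁`, the projections `w` are eigenvectors of
  `(R₁₁+R₂₂)⁻¹(R₁₂+R₂₁)`; the dyad's ISC is the mean projected-time-
  course correlation of the top 3 components, averaged over images.
- *Gaze similarity* — negated earth-mover distance between
  dwell-time-weighted fixation histograms on a grid over the unit
  square, solved as an exact transportation LP.

**Inference** on the dyad table: standardized OLS per region with
Mantel-style permutation tests (subject identities underlying the
tested predictor are shuffled, never dyad rows), BH-FDR across regions,
per-network one-sample t-tests on coefficient distributions, split-half
reliabilities, per-subject effect distributions, linear mediation with
permuted paths, and effect-size comparisons between predictors.

Because real multi-subject recordings are large and access-restricted,
the package ships a first-class synthetic generator whose coupling
between personality and synchrony is tunable (`trait_coupling`, a.k.a.
γ) and whose expected dyadic correlation has a closed form,

    ρᵢⱼ = (a² + γ² pᵢ·pⱼ) / √((a² + γ²‖pᵢ‖² + σ²)(a² + γ²‖pⱼ‖² + σ²)),

which serves as an oracle for every synchrony estimator. γ = 0 yields
personality-independent synchrony and is the null used to calibrate the
permutation tests.

## Worked example

```bash
cat > config.json <<'EOF'
{"n_subjects": 20, "n_facets_per_trait": 3, "n_items_per_facet": 2,
 "n_regions": 10, "n_subcortical": 2, "n_voxels_per_region": 4,
 "n_runs": 4, "n_timepoints_per_run": 100, "n_images": 20,
 "n_categories": 5, "n_channels": 8, "n_sources": 4, "epoch_length": 250,
 "attractors_per_image": 4, "fixations_per_image": 6, "seed": 7}
EOF
dyadsync run --config config.json --out demo --n-perm 500
dyadsync report --out demo
```

prints (abbreviated):

```
dyadsync run c6d4772d8af1acf1 (seed 7)

Per-region personality-similarity effects (sorted by |beta|):
  NM:
    R009 (subcortical): beta=+0.618  p_perm=0.002 *FDR
    R005 (limbic): beta=+0.580  p_perm=0.002 *FDR
    ...
Split-half reliabilities: nm_split_half=0.763, np_split_half=0.871,
isc_split_half=0.967, personality_split_half=0.725

EEG ISC ~ personality similarity: beta=+0.793 (SE 0.044), p_perm=0.002
Mediation via gaze: indirect beta=-0.0032, p_perm=0.758
Per-subject effects: 100% positive (19 obs/person)
```

Read: with the generator's default coupling, personality similarity
predicts neural synchrony in every region (standardized β ≈ 0.4–0.7,
permutation p at the 1/(500+1) floor, FDR-significant), the dyadic
measures are reliable across split halves, and — as built into this
particular generator, where gaze and neural coupling are independent
channels — gaze similarity does not mediate the personality–synchrony
link. The same library calls are available in Python
(`dyadsync.run_pipeline`, `dyadsync.subject_permutation_test`, ...).

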