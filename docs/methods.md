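# Methods

## Texture model

A subject is a pair of co-registered 3-D grids: a floating-point intensity
volume (assumed skull-stripped and intensity-normalized upstream) and an
integer label volume assigning each voxel to a neuroanatomical region (0 =
background).  All computation happens in voxel index space; the only spatial
metadata used is the voxel spacing in mm, read from the NIfTI header.

**LoG filtering.**  The Laplacian-of-Gaussian response at scale σ (mm) is
computed as Gaussian smoothing (per-axis standard deviation σ/spacing in
voxel units, kernel truncated at 4σ) followed by the discrete 6-neighbour
Laplacian with each axis term divided by the squared voxel spacing.  This
two-step discrete operator is the reference implementation; a second path
convolving with the sampled analytic kernel ∇²G(r; σ) is retained for
cross-checking.  The two agree to O((h/σ)²) — a few percent at σ comparable
to the voxel size — which is why tests compare the discrete path against a
dense convolution with its own effective kernel (exact to rounding) and the
analytic path against the closed-form kernel, rather than the two paths
against each other at tight tolerance.

Choices that matter:

- **Boundary condition**: mirror (reflect) padding, so the border of a
  skull-stripped volume does not manufacture artificial edges.  Configurable.
- **No scale normalization** by default: responses are *not* multiplied by
  σ².  A `scale_normalize` flag provides the classic normalization (used in
  the blob-selection test, where the normalized center response to a Gaussian
  blob of width s peaks at σ = s·√(2/3) in 3-D).
- σ below half the largest voxel spacing logs an under-resolved warning.

**Quantifiers.**  Within each region the response multiset is summarized by
the mean A, the population (1/n) standard deviation SD, and the histogram
entropy E in bits: 256 equal-width bins spanning the region's own min–max
range (half-open bins, maximum in the last closed bin), E = −Σ p_k log₂ p_k.
Consequences worth knowing: E ∈ [0, 8] bits; E is invariant under strictly
increasing affine maps of the responses (the binning is per-region min–max);
an all-equal response set has SD = 0 and E = 0; an empty region yields
missing values with a warning instead of aborting a cohort run.  The default
scales are σ = 0.5, 1.5, 2.0 mm (fine/medium/coarse), so each region
contributes 9 features and the default 31-region sub-cortical map yields 279
features per subject.  The 31-entry default map uses standard FreeSurfer
`aseg` label ids (bilateral cerebellar white matter, thalamus, caudate,
putamen, pallidum, hippocampus, amygdala, accumbens, vessel, choroid plexus
and lateral ventricles, plus brain stem, CSF, 3rd/4th ventricles and five
corpus-callosum segments); it is a configurable convenience, not an
authority — supply a CSV map when the parcellation differs.

## Statistical analyses

**Group comparison.**  Per feature, the statistic is the absolute difference
of group medians (ABM; medians because texture features need not be normal).
Significance comes from a Monte-Carlo permutation test: N random relabelings
preserving group sizes (default N = 100,000) and, by default, the
tie-inclusive validity-corrected count p = (b + 1)/(N + 1) where b is the
number of permuted ABMs ≥ the observed one.  This keeps p > 0 and valid as a
test level; the literal "strictly greater" rule (p = b/N, which can reach 0)
is available as `tie_rule="gt"` for replication.  An exhaustive enumeration
over all group-size-preserving splits (n ≤ 12) serves as the oracle.

**Balanced bootstrap + Fisher.**  As a complementary screen, `n_samples`
balanced resamples (default 100; equal per-group sizes, default 100/100 for
diagnosis-style and 50/50 for sex-style comparisons, drawn *with*
replacement — a without-replacement subsampling mode exists) are each scored
with a two-sided Wilcoxon rank-sum test (exact for tie-free n ≤ 20,
tie-corrected normal approximation otherwise) and aggregated with Fisher's
method, X = −2 Σ ln pᵢ ~ χ²(2k).  Because resample p-values are highly
correlated, the aggregate is *anti-conservative by construction* and is
reported for relative ranking of features only — it never feeds the
significance decision.

**Multiplicity.**  All raw p-values of one analysis family are corrected
together with the Holm–Bonferroni step-down procedure (adjusted
p̃₍ᵢ₎ = min(1, max_{j≤i}(m − j + 1)·p₍ⱼ₎); missing features are excluded from
the family size m); features are significant at corrected p < α = 0.05.
Each analysis mode (group, sex, age) corrects its own family of features.

**Age correlation.**  Per feature: tie-aware Spearman ρ; a two-sided
permutation p (covariate shuffled, |ρ| counted with the same conventions as
above); a bootstrap lower bound on |ρ| — the empirical 5th percentile
(inverted-CDF convention, order statistic at ⌈0.05·B⌉; the 5th smallest of
B = 100 resampled values) of |ρ| over resampled cohorts of 100 subjects —
and a reporting flag for |ρ| > 0.4 (moderate-to-high correlation).  The
absolute value is used in the bound because the quantity of interest is the
strength of a sign-consistent correlation.  Degenerate resamples (constant
values) are skipped with a warning up to a 20% budget.

**Determinism.**  Every stochastic routine takes a seed; cohort-level
analyses derive a per-feature substream from the master seed and a CRC-32 of
the feature name, so results are independent of row and column order (the
analyses also sort subjects canonically).  Re-running with the same
configuration reproduces all output files byte for byte.

## Phantom generator

Regions are spheres or boxes painted into a shared integer grid (overlap and
out-of-grid placement are errors).  Each region's intensity is a Gaussian
random field μ + τ·Z_ℓ, where Z_ℓ is white noise smoothed with a Gaussian of
scale ℓ (mm) and divided by the *analytic* marginal standard deviation of
the smoothed field, so amplitude τ and correlation length ℓ are decoupled
(exact in the interior; reflect padding perturbs the variance slightly near
the region bounding box).  Optional extra (τ, ℓ) components are summed
independently, which is what makes *band-limited* effects possible: a group
effect confined to one component against a broadband background shared by
both groups.  Fields are drawn on the region's padded bounding box for
speed.  Per-subject streams derive from `SeedSequence([seed, 1, index])`;
demographics from `SeedSequence([seed, 0])` — the scheme is frozen, so any
subject's volume is reproducible in isolation.

Effects map a subject attribute to one parameter of one region's primary
component: categorical drivers (group, sex) via a level → value table, age
via a linear map intercept + slope·age.  Two effects on the same (region,
parameter) are rejected.  A cohort with no effects is exchangeable by
construction and is the type-I calibration instrument.

What the phantom does *not* emulate: cortical anatomy, bias fields,
scanner/site effects, motion, partial-volume mixtures, and any relation
between intensity and tissue class.  Passing the validation suite therefore
demonstrates that the *pipeline* recovers known distributional effects with
calibrated error rates — not that those effects exist in, or transfer to,
real MRI cohorts.

A practical note on region means: a region whose mean differs from the
background produces a strong step edge at its boundary, and within a filter
support of the boundary the LoG response is dominated by that edge rather
than by texture.  The validation phantoms therefore set μ equal to the
background; with real parcellations this is exactly the "responses include
content from neighbouring regions" caveat, and it is the main reason entropy
(insensitive to response magnitude) can be more robust than SD near
imperfect region boundaries.

## Frozen validation studies (`logradiomics.validation`)

Study conditions were fixed once, at desk scale (64³ grids rather than the
256³ of a full 1 mm³ acquisition), and are shared between the test suite and
`scripts/acceptance.py`:

- **Type-I calibration**: 1000 iid standard-normal features, 50 vs 50
  exchangeable subjects, N = 2000 permutations; the raw rejection rate at
  α = 0.05 must sit in the binomial band [0.037, 0.064].  Family-wise error:
  100 replicate 279-feature null cohorts under Holm; note that with N = 2000
  and validity-corrected counting the smallest achievable raw p, 1/2001,
  exceeds 0.05/279, so rejections at this permutation budget are impossible
  by construction and the observed rate is 0.
- **Group-effect recovery**: four spherical regions (radius 10) in 64³,
  baseline (τ, ℓ) = (1.0, 1.0 mm), effect τ: 1.0 → 1.5 in one region,
  50 vs 50 subjects, N = 20,000; detection = a Holm-significant SD or E
  feature in the affected region.  The 1.5× amplitude is a mid-sized effect:
  large enough to be detected in ≥ 90% of replicate cohorts, small enough
  that unaffected regions stay at the nominal false-positive level.
- **Age-trend recovery**: one spherical region (radius 14) in 48³ with
  ℓ = 0.5 mm at age 8 rising linearly to 2.5 mm at age 40, 200 subjects with
  uniform ages; the coarse-scale (σ = 2 mm) SD feature must reach |ρ| > 0.4
  with the model-implied sign.  The expected sign is derived by an
  independent two-point oracle (median feature at the two extreme ℓ values)
  rather than asserted, because the response variance of a unit-variance
  field is not monotone in ℓ at fixed σ in general.
- **Scale selectivity**: one region whose baseline mixes a strong white
  floor (τ = 6, ℓ = 0), the 2 mm component (τ = 1) and a coarse 4 mm
  component (τ = 1); group B has τ: 1.0 → 1.3 on the 2 mm component only.
  The white floor hides the effect at fine σ and the 4 mm component (whose
  response decays much more slowly than white noise under increasing σ)
  drowns it at coarse σ, so the significance of the SD feature peaks near
  σ = 2 mm.  A single-component phantom cannot produce such an interior
  peak — the relative group difference of SD is monotone in σ for any pure
  τ or ℓ effect — which is why `TextureParams` supports extra components.
  The reported curve is the mean −log₁₀ raw p over 4 replicate 30 vs 30
  cohorts (a single cohort's argmax is noisy when the curve has a plateau);
  the peak is required within one grid step (0.5 mm) of 2 mm.

`scripts/acceptance.py` reruns these studies (some at reduced replicate
counts: 30 null cohorts, 10 detection cohorts, 5 age replicates — each
reported with its n) and writes the measured quantities as JSON.

## Known limitations

- Regions are filtered in place within the whole volume; no masking is done
  before filtering, so responses near region boundaries mix neighbouring
  content.  This mirrors the intended use but makes SD boundary-sensitive.
- Entropy uses per-region min–max binning; a global-range policy would make
  E comparable across subjects in absolute terms but is not implemented as a
  default because min–max is the standard radiomics reading of uniform
  discretization.
- The Wilcoxon/Fisher screen is intentionally uncalibrated (correlated
  resamples); only the permutation p feeds decisions.
- Exhaustive permutation enumeration is limited to n ≤ 12 subjects; the
  Spearman permutation test reuses the group-test counting conventions but
  has no built-in exhaustive oracle (tests enumerate n = 5 directly).
- No covariate adjustment (site, age) in the group analyses, no FDR
  alternatives to Holm, and no longitudinal modeling.
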