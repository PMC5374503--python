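# logradiomics

Region-wise multi-scale **Laplacian-of-Gaussian (LoG) texture analysis** of
labeled 3-D brain volumes, with permutation-based group statistics and
Spearman age-correlation screening.

## The problem

Volumetry summarizes a neuroanatomical region by a single number — its size —
and misses differences in *tissue heterogeneity*.  Radiomic texture analysis
fills that gap: a skull-stripped, intensity-normalized T1-weighted volume is
band-pass filtered with the LoG operator at several spatial scales σ, and the
distribution of filter responses f_σ(x, y, z) inside each parcellated region
R_i is summarized by three quantifier functions,

- **A**  = mean of {f_σ(v) : v ∈ R_i}                        (1st moment),
- **SD** = population standard deviation of the responses     (2nd moment),
- **E**  = −Σ_k p_k log₂ p_k, the entropy of the response histogram over 256
  equal-width intervals spanning the region's min–max range,

so that with three scales (σ = 0.5, 1.5, 2.0 mm — fine, medium, coarse) every
region is a 9-dimensional texture vector, and a 31-region sub-cortical map
yields 279 features per subject.  These feature tables are screened for

- **group differences** (e.g. case vs. control, male vs. female) with a
  two-sided permutation test on the absolute difference of group medians
  (ABM), 100,000 random relabelings by default, plus a complementary
  balanced-bootstrap Wilcoxon screen aggregated with Fisher's method
  (−2 Σ ln pᵢ ~ χ²(2k), relative ranking only);
- **age association** with the Spearman rank correlation coefficient ρ,
  a permutation p-value on |ρ|, a bootstrap lower 95% confidence bound on
  |ρ|, and a |ρ| > 0.4 moderate-correlation flag;

with Holm–Bonferroni step-down control of the family-wise error over all
features and significance declared at corrected p < 0.05.

The package also ships a **phantom generator**: labeled Gaussian-random-field
cohorts with controllable per-region mean μ, noise amplitude τ and spatial
correlation length ℓ, plus injected group/sex effects and age-linked trends —
so the entire pipeline can be validated against ground truth (type-I
calibration, effect recovery, scale selectivity) without any patient data.

## Worked example

Simulate a 50-subject two-region cohort in which the "hippocampus" of the
case group has 40% higher texture amplitude (τ: 1.0 → 1.4), extract features,
and run the permutation analysis:

```python
from logradiomics.phantom import (CohortSpec, EffectSpec, PhantomRegionSpec,
                                  TextureParams, simulate_cohort, region_map_of)
from logradiomics.log_texture import extract_cohort_features
from logradiomics.group_stats import PermutationConfig, run_group_analysis

regions = [
    PhantomRegionSpec(1, "hippocampus", "sphere", (16, 16, 16), 8),
    PhantomRegionSpec(2, "thalamus", "sphere", (40, 40, 40), 8),
]
baseline = {name: TextureParams(mu=0.0, tau=1.0, ell_mm=1.0)
            for name in ("hippocampus", "thalamus")}
effects = [EffectSpec("hippocampus", "group", "tau",
                      levels={"TDC": 1.0, "ASD": 1.4})]
spec = CohortSpec(grid_shape=(56, 56, 56),
                  n_per_group={"ASD": 25, "TDC": 25}, seed=11)
cohort = simulate_cohort(spec, regions, baseline, effects)

features = extract_cohort_features(cohort.iter_volumes(), region_map_of(cohort))
results = run_group_analysis(features, cohort.metadata,
                             perm_config=PermutationConfig(10_000, seed=11))
print(results.loc[results.significant,
                  ["feature", "abm", "p_raw", "p_holm", "significant"]]
      .to_string(index=False))
```

prints

```
               feature      abm  p_raw  p_holm  significant
hippocampus__0.500__SD 0.549240 0.0001  0.0018         True
hippocampus__1.500__SD 0.093033 0.0001  0.0018         True
hippocampus__2.000__SD 0.041382 0.0001  0.0018         True
```

The injected amplitude effect is recovered in the SD features of the affected
region at all three scales (raw permutation p = 1/10001, Holm-corrected over
all 18 features), and nowhere else.  The ABM column shows the absolute
difference of group medians on the feature's own scale — largest at the fine
scale, where the unit-correlation-length texture carries the most filter
response.

The same workflow is available from the shell:

```bash
logradiomics simulate --config phantom.yaml --out data/
logradiomics extract --volumes data/volumes.csv --out features.csv
logradiomics analyze-group --features features.csv \
    --metadata data/metadata.csv --out analysis/
logradiomics sweep --volumes data/volumes.csv \
    --sigma-grid 0.5,1.0,1.5,2.0,2.5 --out sweep.csv
```

`analyze-group` writes the result table, a −log₁₀ raw-p heatmap matrix
(regions × scale/quantifier) and a parallel Holm-significance mask as CSV.

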