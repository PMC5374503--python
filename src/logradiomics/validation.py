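"""Phantom validation studies for the full pipeline.

These are the package's standard self-checks, run by the test suite and the
reproduction script: type-I-error calibration on exchangeable null cohorts,
family-wise error under Holm correction, recovery of injected group and age
effects, and scale selectivity of the significance-versus-sigma curve.  The
study conditions (cohort sizes, effect sizes, permutation counts) are frozen
here so every entry point reproduces the same experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phantom as ph
from .age_stats import run_correlation_analysis, spearman_rho
from .group_stats import PermutationConfig, run_group_analysis
from .log_texture import ScaleSet, extract_cohort_features, scale_sweep, sweep_to_feature_tables
from .phantom import (
    CohortSpec,
    EffectSpec,
    PhantomCohort,
    PhantomRegionSpec,
    TextureParams,
    simulate_cohort,
)
from .volume_io import default_region_map, feature_column


# ---------------------------------------------------------------------------
# null (exchangeable) cohorts of synthetic features


def null_feature_cohort(
    n_per_group: int, n_features: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IID standard-normal features with arbitrary (exchangeable) labels."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    ids = [f"s{i:04d}" for i in range(n)]
    feats = pd.DataFrame(
        rng.standard_normal((n, n_features)),
        index=pd.Index(ids, name="subject_id"),
        columns=[f"f{j:04d}" for j in range(n_features)],
    )
    meta = pd.DataFrame(
        {
            "subject_id": ids,
            "group": ["A"] * n_per_group + ["B"] * n_per_group,
            "sex": "M",
            "age": 20.0,
            "site": "null",
        }
    )
    return feats, meta


def type_one_error_rate(
    n_features: int = 1000,
    n_per_group: int = 50,
    n_permutations: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of null features with raw permutation p below alpha."""
    feats, meta = null_feature_cohort(n_per_group, n_features, seed)
    res = run_group_analysis(
        feats, meta, perm_config=PermutationConfig(n_permutations, seed)
    )
    return float((res["p_raw"] < alpha).mean())


def family_wise_error_count(
    n_cohorts: int = 100,
    n_features: int = 279,
    n_per_group: int = 50,
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[int, int]:
    """(number of null cohorts with any Holm-significant feature, n_cohorts)."""
    hits = 0
    for rep in range(n_cohorts):
        feats, meta = null_feature_cohort(n_per_group, n_features, seed + 1000 + rep)
        res = run_group_analysis(
            feats, meta,
            perm_config=PermutationConfig(n_permutations, seed + 1000 + rep),
        )
        hits += int(res["significant"].any())
    return hits, n_cohorts


# ---------------------------------------------------------------------------
# labeled-volume phantoms


def four_region_cohort(
    seed: int,
    n_per_group: int = 50,
    tau_effect: float = 1.5,
    grid: int = 64,
    radius: float = 10.0,
) -> PhantomCohort:
    """Four disjoint spheres; tau effect (1.0 -> tau_effect) in region r1.

    Region means equal the background so that the group difference is purely
    textural (a mean offset would add boundary-edge responses shared by both
    groups and unrelated to the effect)."""
    q = grid // 4
    centers = [(q, q, q), (3 * q, q, q), (q, 3 * q, q), (3 * q, 3 * q, 3 * q)]
    regions = [
        PhantomRegionSpec(i + 1, f"r{i + 1}", "sphere", c, radius)
        for i, c in enumerate(centers)
    ]
    baseline = {f"r{i + 1}": TextureParams(0.0, 1.0, 1.0) for i in range(4)}
    effects = [
        EffectSpec("r1", "group", "tau", levels={"A": 1.0, "B": tau_effect})
    ]
    spec = CohortSpec(
        grid_shape=(grid,) * 3,
        n_per_group={"A": n_per_group, "B": n_per_group},
        seed=seed,
    )
    return simulate_cohort(spec, regions, baseline, effects)


def aseg_box_cohort(seed: int, n_per_group: int = 2) -> PhantomCohort:
    """A phantom whose labels are the default 31-region map's ids (one box
    per region), for exercising the full default configuration."""
    rm = default_region_map()
    regions = []
    for k, (lid, name) in enumerate(zip(rm.label_ids, rm.region_names)):
        i, j = divmod(k, 4)
        k2, i = divmod(i, 4)
        regions.append(
            PhantomRegionSpec(
                lid, name, "box",
                (8.0 + 16 * j, 8.0 + 16 * i, 16.0 + 32 * k2), (5, 5, 7),
            )
        )
    baseline = {name: TextureParams(0.0, 1.0, 0.5) for name in rm.region_names}
    spec = CohortSpec(
        grid_shape=(64, 64, 64),
        n_per_group={"ASD": n_per_group, "TDC": n_per_group},
        seed=seed,
    )
    return simulate_cohort(spec, regions, baseline, ())


@dataclass
class DetectionResult:
    detected: int
    false_region_cohorts: int
    n_cohorts: int


def group_effect_detection(
    n_cohorts: int = 20,
    n_per_group: int = 50,
    n_permutations: int = 20_000,
    seed: int = 0,
) -> DetectionResult:
    """Detection of a tau 1.0 -> 1.5 effect under Holm correction.

    A cohort counts as detected when an SD or entropy feature of the
    affected region is Holm-significant; a cohort is a false-region cohort
    when any feature of an unaffected region is Holm-significant.
    """
    detected = 0
    false_cohorts = 0
    for rep in range(n_cohorts):
        co = four_region_cohort(seed + rep, n_per_group=n_per_group)
        feats = extract_cohort_features(co.iter_volumes(), ph.region_map_of(co))
        res = run_group_analysis(
            feats, co.metadata,
            perm_config=PermutationConfig(n_permutations, seed + rep),
        )
        sig = res[res["significant"]]
        detected += int(
            ((sig["region"] == "r1") & sig["quantifier"].isin(["SD", "E"])).any()
        )
        false_cohorts += int((sig["region"] != "r1").any())
    return DetectionResult(detected, false_cohorts, n_cohorts)


# ---------------------------------------------------------------------------
# age-linked correlation-length trend

AGE_TREND_FEATURE = feature_column("roi", 2.0, "SD")


def age_trend_cohort(seed: int, n_subjects: int = 200) -> PhantomCohort:
    """One spherical region whose correlation length grows linearly with age:
    ell = 0.5 mm at age 8 to 2.5 mm at age 40."""
    slope = (2.5 - 0.5) / (40.0 - 8.0)
    regions = [PhantomRegionSpec(1, "roi", "sphere", (24, 24, 24), 14)]
    baseline = {"roi": TextureParams(0.0, 1.0, 0.5)}
    effects = [
        EffectSpec("roi", "age", "ell", intercept=0.5 - 8.0 * slope, slope=slope)
    ]
    spec = CohortSpec(
        grid_shape=(48, 48, 48),
        n_per_group={"TDC": n_subjects},
        age_range=(8.0, 40.0),
        seed=seed,
    )
    return simulate_cohort(spec, regions, baseline, effects)


def expected_age_trend_sign(seed: int = 0, n_each: int = 12) -> int:
    """Independent two-point oracle for the direction of the injected trend:
    median coarse-SD feature at the youngest age (ell = 0.5 mm) versus the
    oldest (ell = 2.5 mm), each simulated directly."""
    regions = [PhantomRegionSpec(1, "roi", "sphere", (24, 24, 24), 14)]
    labels = ph.build_label_volume((48, 48, 48), regions)
    rng = np.random.default_rng(seed)
    med = {}
    for ell in (0.5, 2.5):
        vals = []
        for _ in range(n_each):
            intensity = ph.simulate_intensity(
                labels, {1: TextureParams(0.0, 1.0, ell)}, rng=rng
            )
            from .log_texture import log_filter

            resp = log_filter(intensity, (1, 1, 1), 2.0)
            vals.append(resp[labels == 1].std())
        med[ell] = float(np.median(vals))
    return 1 if med[2.5] > med[0.5] else -1


@dataclass
class AgeTrendResult:
    recovered: int
    n_replicates: int
    expected_sign: int
    rhos: list


def age_trend_recovery(
    n_replicates: int = 10,
    n_subjects: int = 200,
    seed: int = 0,
    n_permutations: int = 5000,
) -> AgeTrendResult:
    """|SRCC| > 0.4 with the model-implied sign on the coarse-scale SD
    feature, across replicate cohorts."""
    sign = expected_age_trend_sign(seed)
    recovered = 0
    rhos = []
    for rep in range(n_replicates):
        co = age_trend_cohort(seed + rep, n_subjects)
        feats = extract_cohort_features(co.iter_volumes(), ph.region_map_of(co))
        res = run_correlation_analysis(
            feats, co.metadata,
            n_permutations=n_permutations, seed=seed + rep,
            compute_bootstrap_bound=False,
        )
        rho = float(res.loc[res["feature"] == AGE_TREND_FEATURE, "rho"].iloc[0])
        rhos.append(rho)
        recovered += int(abs(rho) > 0.4 and np.sign(rho) == sign)
    return AgeTrendResult(recovered, n_replicates, sign, rhos)


# ---------------------------------------------------------------------------
# scale selectivity

SWEEP_SIGMA_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)


def band_limited_effect_cohort(seed: int, n_per_group: int = 30) -> PhantomCohort:
    """A band-limited group effect at 2 mm against a broadband background.

    Both groups share a strong white-noise floor and a coarse 4 mm
    component; group B has extra amplitude only in the 2 mm component, so
    the group difference carries information concentrated near sigma = 2 mm.
    """
    regions = [PhantomRegionSpec(1, "roi", "sphere", (32, 32, 32), 10)]
    baseline = {
        "roi": TextureParams(0.0, 1.0, 2.0, extra_components=((6.0, 0.0), (1.0, 4.0)))
    }
    effects = [EffectSpec("roi", "group", "tau", levels={"A": 1.0, "B": 1.3})]
    spec = CohortSpec(
        grid_shape=(64, 64, 64),
        n_per_group={"A": n_per_group, "B": n_per_group},
        seed=seed,
    )
    return simulate_cohort(spec, regions, baseline, effects)


def scale_selectivity_curve(
    n_cohorts: int = 4,
    n_permutations: int = 20_000,
    seed: int = 0,
) -> tuple[dict[float, float], float]:
    """Mean significance curve (-log10 raw p of the SD feature) over
    replicate cohorts across the sigma grid; returns (curve, peak sigma)."""
    from .group_stats import permutation_test

    acc = {s: 0.0 for s in SWEEP_SIGMA_GRID}
    for rep in range(n_cohorts):
        co = band_limited_effect_cohort(seed + rep)
        sw = scale_sweep(co.iter_volumes(), list(SWEEP_SIGMA_GRID),
                         ph.region_map_of(co))
        tables = sweep_to_feature_tables(sw)
        groups = co.metadata["group"].to_numpy()
        for sigma, tab in tables.items():
            col = feature_column("roi", sigma, "SD")
            p = permutation_test(
                tab[col].to_numpy(), groups,
                PermutationConfig(n_permutations, seed + rep),
            )
            acc[sigma] += -np.log10(p)
    curve = {s: v / n_cohorts for s, v in acc.items()}
    peak = max(curve, key=curve.get)
    return curve, float(peak)
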