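"""Shared fixtures: small deterministic phantom cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from logradiomics.phantom import (
    CohortSpec,
    EffectSpec,
    PhantomCohort,
    PhantomRegionSpec,
    TextureParams,
    simulate_cohort,
)


def four_region_cohort(
    seed: int,
    n_per_group: int = 10,
    tau_effect: float | None = 1.5,
    grid: int = 64,
    radius: float = 10.0,
) -> PhantomCohort:
    """Four disjoint spherical regions; optional tau effect on region r1."""
    q = grid // 4
    centers = [(q, q, q), (3 * q, q, q), (q, 3 * q, q), (3 * q, 3 * q, 3 * q)]
    regions = [
        PhantomRegionSpec(i + 1, f"r{i + 1}", "sphere", c, radius)
        for i, c in enumerate(centers)
    ]
    baseline = {f"r{i + 1}": TextureParams(0.0, 1.0, 1.0) for i in range(4)}
    effects = []
    if tau_effect is not None:
        effects.append(
            EffectSpec("r1", "group", "tau", levels={"A": 1.0, "B": tau_effect})
        )
    spec = CohortSpec(
        grid_shape=(grid,) * 3,
        n_per_group={"A": n_per_group, "B": n_per_group},
        seed=seed,
    )
    return simulate_cohort(spec, regions, baseline, effects)


@pytest.fixture(scope="session")
def tiny_cohort() -> PhantomCohort:
    """A 16-subject, 32^3 two-region cohort with a strong tau effect."""
    regions = [
        PhantomRegionSpec(1, "left-blob", "sphere", (10, 10, 10), 6),
        PhantomRegionSpec(2, "right-blob", "box", (22, 22, 22), (5, 5, 5)),
    ]
    baseline = {
        "left-blob": TextureParams(0.0, 1.0, 0.5),
        "right-blob": TextureParams(0.0, 1.0, 0.5),
    }
    effects = [EffectSpec("left-blob", "group", "tau", levels={"A": 1.0, "B": 2.0})]
    spec = CohortSpec(
        grid_shape=(32, 32, 32), n_per_group={"A": 8, "B": 8}, seed=7
    )
    return simulate_cohort(spec, regions, baseline, effects)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
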