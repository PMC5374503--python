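"""Synthetic phantom cohorts: labeled Gaussian-random-field volumes.

Each phantom region is a sphere or box painted into an integer label grid
shared by the whole cohort.  Region intensities are Gaussian random fields:
``field = mu + tau * Z_ell (+ extra components)`` where ``Z_ell`` is white
Gaussian noise smoothed at correlation length ``ell`` (mm) and re-standardized
to unit marginal variance, so the noise amplitude ``tau`` and the spatial
correlation length ``ell`` are decoupled.  Optional extra ``(tau, ell)``
components are summed independently, allowing band-limited group effects
against a broadband background.

Effects tie a texture parameter of one region to a subject attribute:
categorical drivers (group, sex) map each level to a parameter value; the
age driver applies a linear map ``intercept + slope * age``.  A cohort with
no effects is exchangeable by construction and serves for type-I-error
calibration.

Per-subject random streams are derived from the master seed and the subject
index (``SeedSequence([seed, 1, index])``), so any subject's volume can be
regenerated independently and results do not depend on generation order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import LabeledVolume, write_labeled_volume, write_metadata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomRegionSpec:
    """A sphere or box region; ``size`` is the radius or per-axis half-widths
    in voxels, ``center`` in voxel coordinates."""

    label_id: int
    region_name: str
    shape: str  # "sphere" | "box"
    center: tuple[float, float, float]
    size: float | tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValueError("label_id must be positive")
        if self.shape not in ("sphere", "box"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def half_widths(self) -> tuple[float, float, float]:
        if np.isscalar(self.size):
            return (float(self.size),) * 3
        hw = tuple(float(s) for s in self.size)  # type: ignore[arg-type]
        if len(hw) != 3:
            raise ValueError("box size must be a scalar or 3 half-widths")
        return hw


@dataclass(frozen=True)
class TextureParams:
    """Regional texture: mean ``mu``, amplitude ``tau`` (marginal SD) and
    correlation length ``ell_mm`` of the primary noise component, plus
    optional independent extra components as ``(tau, ell_mm)`` pairs."""

    mu: float = 0.0
    tau: float = 0.0
    ell_mm: float = 0.0
    extra_components: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.tau < 0 or self.ell_mm < 0:
            raise ValueError("tau and ell_mm must be non-negative")
        for t, e in self.extra_components:
            if t < 0 or e < 0:
                raise ValueError("extra component tau/ell must be non-negative")

    def components(self) -> tuple[tuple[float, float], ...]:
        return ((self.tau, self.ell_mm),) + tuple(self.extra_components)


@dataclass(frozen=True)
class EffectSpec:
    """An injected effect on one region's texture parameter.

    ``driver`` is "group", "sex" (categorical; supply ``levels`` mapping each
    level to the parameter value) or "age" (supply ``intercept`` and
    ``slope`` of the linear map applied to the subject's age).
    ``parameter`` is "mu", "tau" or "ell" and refers to the primary
    component.
    """

    region_name: str
    driver: str  # "group" | "sex" | "age"
    parameter: str  # "mu" | "tau" | "ell"
    levels: Mapping[str, float] | None = None
    intercept: float | None = None
    slope: float | None = None

    def __post_init__(self) -> None:
        if self.driver not in ("group", "sex", "age"):
            raise ValueError(f"unknown driver {self.driver!r}")
        if self.parameter not in ("mu", "tau", "ell"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.driver == "age":
            if self.intercept is None or self.slope is None:
                raise ValueError("age effect needs intercept and slope")
            if not np.isfinite(self.slope):
                raise ValueError("slope must be finite")
        elif not self.levels:
            raise ValueError(f"{self.driver} effect needs a levels mapping")

    def value_for(self, row: Mapping) -> float:
        if self.driver == "age":
            return float(self.intercept) + float(self.slope) * float(row["age"])
        level = str(row[self.driver])
        if level not in self.levels:  # type: ignore[operator]
            raise KeyError(f"effect on {self.region_name} has no level {level!r}")
        return float(self.levels[level])  # type: ignore[index]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure: grid geometry, group sizes, demographics, seed."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_per_group: Mapping[str, int] = field(default_factory=lambda: {"A": 50, "B": 50})
    male_fraction: float = 0.5
    age_range: tuple[float, float] = (8.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("need n >= 1 per group")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.age_range[1] < self.age_range[0] or self.age_range[0] < 0:
            raise ValueError("bad age range")


# ---------------------------------------------------------------------------
# label grids and intensity fields


def build_label_volume(
    grid_shape: Sequence[int], region_specs: Sequence[PhantomRegionSpec]
) -> np.ndarray:
    """Paint regions into an integer grid; 0 is background.

    Regions must be pairwise disjoint and lie fully inside the grid.
    """
    labels = np.zeros(tuple(int(s) for s in grid_shape), dtype=np.int32)
    coords = np.indices(labels.shape)
    for spec in region_specs:
        c = np.asarray(spec.center, dtype=np.float64)
        hw = np.asarray(spec.half_widths(), dtype=np.float64)
        if np.any(c - hw < -0.5) or np.any(c + hw > np.array(labels.shape) - 0.5):
            raise ValueError(f"region {spec.region_name!r} exceeds the grid")
        if spec.shape == "sphere":
            r = float(hw[0])
            d2 = sum((coords[k] - c[k]) ** 2 for k in range(3))
            mask = d2 <= r**2
        else:
            mask = np.ones(labels.shape, dtype=bool)
            for k in range(3):
                mask &= np.abs(coords[k] - c[k]) <= hw[k]
        if np.any(labels[mask] != 0):
            raise ValueError(f"region {spec.region_name!r} overlaps another region")
        labels[mask] = spec.label_id
    return labels


def _gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smoothing_sd_factor(sigma_vox: Sequence[float], truncate: float = 4.0) -> float:
    """Marginal SD of unit white noise after separable Gaussian smoothing."""
    factor = 1.0
    for s in sigma_vox:
        if s > 0:
            k = _gaussian_kernel_1d(s, truncate)
            factor *= float(np.sqrt((k**2).sum()))
    return factor


def gaussian_random_field(
    shape: Sequence[int],
    ell_mm: float,
    spacing: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-marginal-variance Gaussian field with correlation length ell_mm.

    White noise is smoothed with a Gaussian of scale ell (converted to voxel
    units per axis) and divided by the analytic marginal SD of the smoothed
    field, so the amplitude is decoupled from the correlation length (exact
    in the interior; reflect padding perturbs the variance slightly within
    ~4*ell of the grid border).
    """
    w = rng.standard_normal(tuple(int(s) for s in shape))
    if ell_mm <= 0:
        return w
    sig_vox = tuple(float(ell_mm) / float(s) for s in spacing)
    sm = ndimage.gaussian_filter(w, sigma=sig_vox, mode="reflect", truncate=4.0)
    return sm / _smoothing_sd_factor(sig_vox)


def simulate_intensity(
    labels: np.ndarray,
    params: Mapping[int, TextureParams],
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Fill each labeled region with its Gaussian-random-field texture.

    Background (label 0) stays 0.  Every label present in the grid must have
    parameters.  Deterministic given the generator state: fields are drawn
    in sorted label order, one per texture component.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    present = [int(l) for l in np.unique(labels) if l != 0]
    missing = [l for l in present if l not in params]
    if missing:
        raise ValueError(f"no texture parameters for present label(s) {missing}")
    out = np.zeros(labels.shape, dtype=np.float64)
    spacing = tuple(float(s) for s in spacing)
    for lid in sorted(present):
        p = params[lid]
        mask = labels == lid
        # fields are drawn on the region's bounding box padded by the widest
        # smoothing support, not on the whole grid
        where = np.argwhere(mask)
        lo, hi = where.min(axis=0), where.max(axis=0) + 1
        max_ell = max(ell for _, ell in p.components())
        pad = [int(np.ceil(4.0 * max_ell / s)) + 1 for s in spacing]
        lo = np.maximum(lo - pad, 0)
        hi = np.minimum(hi + pad, labels.shape)
        slices = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub_shape = tuple(int(b - a) for a, b in zip(lo, hi))
        region_field = np.full(sub_shape, float(p.mu))
        for tau, ell in p.components():
            if tau > 0:
                region_field = region_field + tau * gaussian_random_field(
                    sub_shape, ell, spacing, rng
                )
        sub_out = out[slices]
        sub_mask = mask[slices]
        sub_out[sub_mask] = region_field[sub_mask]
    return out


# ---------------------------------------------------------------------------
# cohorts


class PhantomCohort:
    """A fully specified synthetic cohort; volumes are generated on demand.

    ``metadata`` is the per-subject table (subject_id, group, sex, age,
    site); :meth:`iter_volumes` regenerates each subject's LabeledVolume
    deterministically from the master seed.
    """

    def __init__(
        self,
        spec: CohortSpec,
        regions: Sequence[PhantomRegionSpec],
        baseline: Mapping[str, TextureParams],
        effects: Sequence[EffectSpec] = (),
    ) -> None:
        self.spec = spec
        self.regions = tuple(regions)
        self.baseline = dict(baseline)
        self.effects = tuple(effects)
        names = {r.region_name for r in self.regions}
        for name in self.baseline:
            if name not in names:
                raise ValueError(f"baseline params for unknown region {name!r}")
        for r in self.regions:
            if r.region_name not in self.baseline:
                raise ValueError(f"region {r.region_name!r} has no baseline params")
        seen: set[tuple[str, str, str]] = set()
        for e in self.effects:
            if e.region_name not in names:
                raise ValueError(f"effect targets unknown region {e.region_name!r}")
            key = (e.region_name, e.parameter, e.driver)
            if any(k[:2] == key[:2] for k in seen):
                raise ValueError(
                    f"contradictory effects on ({e.region_name}, {e.parameter})"
                )
            seen.add(key)
        self.labels = build_label_volume(spec.grid_shape, self.regions)
        self._label_of = {r.region_name: r.label_id for r in self.regions}
        self.metadata = self._draw_metadata()

    def _draw_metadata(self) -> pd.DataFrame:
        rng = np.random.default_rng(np.random.SeedSequence([self.spec.seed, 0]))
        rows = []
        i = 0
        for group in self.spec.n_per_group:
            for _ in range(int(self.spec.n_per_group[group])):
                rows.append(
                    {
                        "subject_id": f"sub-{i:04d}",
                        "group": group,
                        "sex": "M" if rng.random() < self.spec.male_fraction else "F",
                        "age": float(rng.uniform(*self.spec.age_range)),
                        "site": "phantom",
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    def subject_params(self, row: Mapping) -> dict[int, TextureParams]:
        """Resolve baseline + effects into per-label texture parameters."""
        out: dict[int, TextureParams] = {}
        for name, base in self.baseline.items():
            mu, tau, ell = base.mu, base.tau, base.ell_mm
            for e in self.effects:
                if e.region_name != name:
                    continue
                val = e.value_for(row)
                if e.parameter == "mu":
                    mu = val
                elif e.parameter == "tau":
                    tau = val
                else:
                    ell = val
            out[self._label_of[name]] = TextureParams(
                mu, tau, ell, base.extra_components
            )
        return out

    def volume_for(self, index: int) -> LabeledVolume:
        row = self.metadata.iloc[index]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.spec.seed, 1, int(index)])
        )
        intensity = simulate_intensity(
            self.labels, self.subject_params(row), self.spec.spacing, rng
        )
        return LabeledVolume(
            intensity, self.labels, self.spec.spacing, str(row["subject_id"])
        )

    def iter_volumes(self) -> Iterator[LabeledVolume]:
        for i in range(len(self.metadata)):
            yield self.volume_for(i)

    def __len__(self) -> int:
        return len(self.metadata)

    def manifest(self) -> dict:
        return {
            "cohort_spec": {
                **asdict(self.spec),
                "n_per_group": dict(self.spec.n_per_group),
            },
            "regions": [asdict(r) for r in self.regions],
            "baseline": {k: asdict(v) for k, v in self.baseline.items()},
            "effects": [asdict(e) for e in self.effects],
        }

    def write(self, outdir: str | Path) -> pd.DataFrame:
        """Write NIfTI pairs, metadata CSV, a volume manifest CSV and a
        reproducibility manifest (spec + seed) to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records = []
        for i, vol in enumerate(self.iter_volumes()):
            ipath = outdir / f"{vol.subject_id}_intensity.nii.gz"
            lpath = outdir / f"{vol.subject_id}_labels.nii.gz"
            write_labeled_volume(vol, ipath, lpath)
            records.append(
                {
                    "subject_id": vol.subject_id,
                    "intensity_path": str(ipath),
                    "labels_path": str(lpath),
                }
            )
        write_metadata(self.metadata, outdir / "metadata.csv")
        volumes = pd.DataFrame(records)
        volumes.to_csv(outdir / "volumes.csv", index=False)
        manifest = self.manifest()

        def _default(o):
            if isinstance(o, Mapping):
                return dict(o)
            raise TypeError(type(o))

        (outdir / "phantom_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_default)
        )
        return volumes


def simulate_cohort(
    spec: CohortSpec,
    regions: Sequence[PhantomRegionSpec],
    baseline: Mapping[str, TextureParams],
    effects: Sequence[EffectSpec] = (),
) -> PhantomCohort:
    """Construct a deterministic synthetic cohort (volumes on demand)."""
    return PhantomCohort(spec, regions, baseline, effects)


def region_map_of(cohort: PhantomCohort):
    """RegionMap matching a phantom cohort's label grid."""
    from .volume_io import RegionEntry, RegionMap

    return RegionMap(
        tuple(
            RegionEntry(r.label_id, r.region_name, "midline")
            for r in cohort.regions
        )
    )
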