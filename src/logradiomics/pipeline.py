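"""End-to-end orchestration: exclusions -> features -> statistics -> reports.

`run_full` drives one analysis mode (group, sex or age) from volumes (or a
phantom cohort) to result tables, heatmap CSVs and a reproducibility
manifest.  Feature extraction is the expensive step, so the extracted
feature table is written once and can be re-used across the three analysis
modes.  Reruns with the same configuration and seed reproduce all outputs
exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__ as _version
from .age_stats import export_correlation_heatmaps, run_correlation_analysis
from .group_stats import (
    BootstrapFisherConfig,
    PermutationConfig,
    export_heatmap_csvs,
    run_group_analysis,
)
from .log_texture import (
    DEFAULT_SCALES,
    EntropyConfig,
    ScaleSet,
    extract_cohort_features,
)
from .phantom import (
    CohortSpec,
    EffectSpec,
    PhantomCohort,
    PhantomRegionSpec,
    TextureParams,
    simulate_cohort,
)
from .volume_io import (
    LabeledVolume,
    RegionMap,
    apply_exclusions,
    default_region_map,
    read_labeled_volume,
    validate_metadata,
    write_feature_table,
)

logger = logging.getLogger(__name__)

MODES = ("group", "sex", "age")


@dataclass
class AnalysisConfig:
    """Defaults mirror the reference study: three LoG scales, 256 entropy
    bins, 100,000 permutations, 100 balanced bootstrap resamples, Holm
    correction at alpha = 0.05."""

    scales: ScaleSet = field(default_factory=lambda: DEFAULT_SCALES)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    n_permutations: int = 100_000
    bootstrap_samples: int = 100
    bootstrap_size_group: int = 100
    bootstrap_size_sex: int = 50
    srcc_bootstrap_size: int = 100
    alpha: float = 0.05
    seed: int = 0
    #: group level treated as the control cohort; when set, the sex and age
    #: analyses are restricted to these subjects (as in case/control studies)
    control_group: str | None = None
    run_bootstrap_fisher: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "scales" in d:
            d["scales"] = ScaleSet(tuple(d["scales"]), None)
        if "entropy_bins" in d:
            d["entropy"] = EntropyConfig(int(d.pop("entropy_bins")))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales.sigmas_mm)
        d["entropy"] = {"n_bins": self.entropy.n_bins}
        return d


def phantom_from_config(cfg: Mapping) -> PhantomCohort:
    """Build a PhantomCohort from a (YAML-friendly) nested mapping."""
    cohort_cfg = dict(cfg.get("cohort", {}))
    for key in ("grid_shape", "spacing", "age_range"):
        if key in cohort_cfg:
            cohort_cfg[key] = tuple(cohort_cfg[key])
    spec = CohortSpec(**cohort_cfg)
    regions = [
        PhantomRegionSpec(
            label_id=int(r["label_id"]),
            region_name=str(r["region_name"]),
            shape=str(r["shape"]),
            center=tuple(r["center"]),
            size=r["size"] if not isinstance(r["size"], list) else tuple(r["size"]),
        )
        for r in cfg["regions"]
    ]
    baseline = {}
    for name, p in cfg["baseline"].items():
        p = dict(p)
        if "extra_components" in p:
            p["extra_components"] = tuple(tuple(c) for c in p["extra_components"])
        baseline[name] = TextureParams(**p)
    effects = [EffectSpec(**e) for e in cfg.get("effects", [])]
    return simulate_cohort(spec, regions, baseline, effects)


def load_volumes_manifest(path: str | Path) -> Iterable[LabeledVolume]:
    """Lazily read volumes listed in a manifest CSV
    (columns: subject_id, intensity_path, labels_path)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("subject_id", "intensity_path", "labels_path"):
        if col not in df.columns:
            raise ValueError(f"volumes manifest is missing column {col!r}")
    for row in df.itertuples():
        yield read_labeled_volume(row.intensity_path, row.labels_path, row.subject_id)


def run_full(
    volumes: Iterable[LabeledVolume],
    metadata: pd.DataFrame,
    mode: str,
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
    region_map: RegionMap | None = None,
    excluded_ids: Sequence[str] = (),
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run one analysis mode end to end; returns the result table.

    ``mode`` selects the comparison: "group" (two diagnosis groups), "sex"
    (M vs F, restricted to the control group if configured) or "age" (SRCC
    against age, same restriction).  Pass ``features`` to reuse a previously
    extracted table instead of re-filtering the volumes.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    config = config or AnalysisConfig()
    region_map = region_map or default_region_map()
    metadata = validate_metadata(metadata)
    t0 = time.perf_counter()

    if excluded_ids:
        metadata = apply_exclusions(metadata, excluded_ids)

    if features is None:
        keep = set(metadata["subject_id"].astype(str))
        features = extract_cohort_features(
            (v for v in volumes if v.subject_id in keep),
            region_map,
            config.scales,
            config.entropy,
        )
    t_extract = time.perf_counter() - t0
    logger.info("feature extraction: %.1f s, %d subjects x %d features",
                t_extract, *features.shape)

    analysis_meta = metadata
    if mode in ("sex", "age") and config.control_group is not None:
        analysis_meta = metadata[metadata["group"] == config.control_group]
        logger.info("restricted to control group %r: %d subjects",
                    config.control_group, len(analysis_meta))

    if mode in ("group", "sex"):
        grouping = "group" if mode == "group" else "sex"
        boot = None
        if config.run_bootstrap_fisher:
            boot = BootstrapFisherConfig(
                n_samples=config.bootstrap_samples,
                size_per_group=(
                    config.bootstrap_size_group
                    if mode == "group"
                    else config.bootstrap_size_sex
                ),
                seed=config.seed,
            )
        results = run_group_analysis(
            features,
            analysis_meta,
            grouping_variable=grouping,
            perm_config=PermutationConfig(config.n_permutations, config.seed),
            bootstrap_config=boot,
            alpha=config.alpha,
        )
    else:
        results = run_correlation_analysis(
            features,
            analysis_meta,
            covariate="age",
            n_permutations=config.n_permutations,
            bootstrap_samples=config.bootstrap_samples,
            bootstrap_size=config.srcc_bootstrap_size,
            seed=config.seed,
            alpha=config.alpha,
        )
    logger.info("analysis (%s): %.1f s", mode, time.perf_counter() - t0 - t_extract)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(features, outdir / "features.csv")
        results.to_csv(outdir / f"results_{mode}.csv", index=False)
        if mode in ("group", "sex"):
            export_heatmap_csvs(
                results,
                outdir / f"heatmap_neglog10p_{mode}.csv",
                outdir / f"significance_mask_{mode}.csv",
            )
        else:
            export_correlation_heatmaps(
                results,
                outdir / "heatmap_rho_age.csv",
                outdir / "heatmap_neglog10p_age.csv",
                outdir / "heatmap_ci_lower_age.csv",
            )
        manifest = {
            "version": _version,
            "mode": mode,
            "config": config.to_manifest(),
            "n_subjects": int(len(metadata)),
            "n_features": int(features.shape[1]),
            "excluded_ids": list(excluded_ids),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
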