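"""I/O for labeled volumes, cohort metadata, exclusion lists and tables.

The canonical on-disk volume format is NIfTI (``.nii``/``.nii.gz``); MGZ
outputs of FreeSurfer (``brain.mgz``/``aseg.mgz``) must be converted upstream
(e.g. ``mri_convert brain.mgz brain.nii.gz``).  All tabular artifacts are
UTF-8 CSV with a header row; exclusion lists are plain text, one subject ID
per line.  All spatial computation in this package happens in voxel index
space: intensity and labels are assumed co-registered, so no affine/world
transform is ever applied beyond carrying voxel spacing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("subject_id", "group", "sex", "age", "site")

#: columns of a feature table follow ``region__<sigma mm, 3 decimals>__<quantifier>``
FEATURE_COLUMN_RE = re.compile(
    r"^(?P<region>.+)__(?P<sigma>\d+\.\d{3})__(?P<quantifier>A|SD|E)$"
)


@dataclass
class LabeledVolume:
    """A co-registered intensity grid and integer region-label grid.

    Label 0 is reserved for background.  ``spacing`` is the voxel size in mm
    per axis.
    """

    intensity: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        labels = np.asarray(self.labels)
        if labels.dtype.kind == "f":
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded, atol=1e-6, rtol=0):
                raise ValueError("label grid contains non-integer values")
            labels = rounded
        self.labels = labels.astype(np.int32)
        if self.intensity.shape != self.labels.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != "
                f"labels shape {self.labels.shape}"
            )
        if self.intensity.ndim != 3:
            raise ValueError("volumes must be 3-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")


@dataclass(frozen=True)
class RegionEntry:
    label_id: int
    region_name: str
    hemisphere: str  # "left" | "right" | "midline"

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValueError("label_id must be a positive integer")
        if self.hemisphere not in ("left", "right", "midline"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")


@dataclass
class RegionMap:
    """Mapping from integer parcellation labels to named regions."""

    entries: tuple[RegionEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        ids = [e.label_id for e in self.entries]
        names = [e.region_name for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate label_ids in region map")
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names in region map")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RegionEntry]:
        return iter(self.entries)

    @property
    def label_ids(self) -> list[int]:
        return [e.label_id for e in self.entries]

    @property
    def region_names(self) -> list[str]:
        return [e.region_name for e in self.entries]

    def name_of(self, label_id: int) -> str:
        for e in self.entries:
            if e.label_id == label_id:
                return e.region_name
        raise KeyError(label_id)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionMap":
        df = pd.read_csv(path)
        required = {"label_id", "region_name", "hemisphere"}
        if not required.issubset(df.columns):
            raise ValueError(f"region map CSV needs columns {sorted(required)}")
        return cls(
            tuple(
                RegionEntry(int(r.label_id), str(r.region_name), str(r.hemisphere))
                for r in df.itertuples()
            )
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "label_id": self.label_ids,
                "region_name": self.region_names,
                "hemisphere": [e.hemisphere for e in self.entries],
            }
        ).to_csv(path, index=False)


def default_region_map() -> RegionMap:
    """The default 31-region sub-cortical map (FreeSurfer ``aseg`` labels).

    Covers the prominent sub-cortical structures, ventricles, brain stem and
    corpus callosum sub-regions.  This default is a convenience, not an
    authority: studies should supply their own map when the parcellation
    differs.
    """
    left_right = [
        (7, 46, "Cerebellum-White-Matter"),
        (10, 49, "Thalamus-Proper"),
        (11, 50, "Caudate"),
        (12, 51, "Putamen"),
        (13, 52, "Pallidum"),
        (17, 53, "Hippocampus"),
        (18, 54, "Amygdala"),
        (26, 58, "Accumbens-area"),
        (30, 62, "Vessel"),
        (31, 63, "Choroid-plexus"),
        (4, 43, "Lateral-Ventricle"),
    ]
    entries: list[RegionEntry] = []
    for lid, rid, name in left_right:
        entries.append(RegionEntry(lid, f"Left-{name}", "left"))
        entries.append(RegionEntry(rid, f"Right-{name}", "right"))
    for lid, name in [
        (16, "Brain-Stem"),
        (24, "CSF"),
        (14, "3rd-Ventricle"),
        (15, "4th-Ventricle"),
        (251, "CC_Posterior"),
        (252, "CC_Mid_Posterior"),
        (253, "CC_Central"),
        (254, "CC_Mid_Anterior"),
        (255, "CC_Anterior"),
    ]:
        entries.append(RegionEntry(lid, name, "midline"))
    rm = RegionMap(tuple(entries))
    assert len(rm) == 31
    return rm


# ---------------------------------------------------------------------------
# volumes


def read_labeled_volume(
    intensity_path: str | Path,
    labels_path: str | Path,
    subject_id: str | None = None,
) -> LabeledVolume:
    """Read a co-registered intensity/label NIfTI pair.

    Spacing is taken from the intensity image header; the two grids must have
    identical shapes and the label grid must contain (representable)
    integers.
    """
    img = nib.load(str(intensity_path))
    lab = nib.load(str(labels_path))
    intensity = np.asarray(img.dataobj, dtype=np.float64)
    labels = np.asarray(lab.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if subject_id is None:
        subject_id = Path(intensity_path).name.split(".")[0]
    return LabeledVolume(intensity, labels, spacing, subject_id)


def write_labeled_volume(
    volume: LabeledVolume,
    intensity_path: str | Path,
    labels_path: str | Path,
) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.intensity, affine), str(intensity_path))
    nib.save(
        nib.Nifti1Image(volume.labels.astype(np.int32), affine), str(labels_path)
    )


# ---------------------------------------------------------------------------
# cohort metadata / exclusions


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    if metadata["subject_id"].duplicated().any():
        dupes = metadata.loc[metadata["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject ids: {sorted(set(dupes))}")
    if (pd.to_numeric(metadata["age"]) < 0).any():
        raise ValueError("age must be non-negative")
    return metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, dtype={"subject_id": str}))


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(metadata).to_csv(path, index=False)


def read_exclusion_list(path: str | Path) -> list[str]:
    """Read an exclusion list: one subject ID per line, '#' comments allowed."""
    ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return ids


def apply_exclusions(
    metadata: pd.DataFrame, excluded_ids: Sequence[str]
) -> pd.DataFrame:
    """Drop quality-failure subjects from the cohort.

    Unknown IDs are logged as warnings, never errors, so a shared exclusion
    list can be applied to any sub-cohort.
    """
    excluded = set(str(x) for x in excluded_ids)
    present = set(metadata["subject_id"].astype(str))
    unknown = sorted(excluded - present)
    if unknown:
        logger.warning("exclusion list has %d unknown subject id(s): %s",
                       len(unknown), unknown)
    keep = ~metadata["subject_id"].astype(str).isin(excluded)
    removed = int((~keep).sum())
    logger.info("excluded %d of %d subjects", removed, len(metadata))
    return metadata.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature tables


def feature_column(region: str, sigma_mm: float, quantifier: str) -> str:
    """Canonical feature column name ``region__sigma__quantifier``."""
    if quantifier not in ("A", "SD", "E"):
        raise ValueError(f"unknown quantifier {quantifier!r}")
    return f"{region}__{float(sigma_mm):.3f}__{quantifier}"


def parse_feature_column(name: str) -> tuple[str, float, str]:
    m = FEATURE_COLUMN_RE.match(name)
    if m is None:
        raise ValueError(f"column {name!r} does not match region__sigma__quantifier")
    return m["region"], float(m["sigma"]), m["quantifier"]


def is_feature_column(name: str) -> bool:
    return FEATURE_COLUMN_RE.match(name) is not None


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write a subjects x features table; values kept to >= 12 sig. digits."""
    bad = [c for c in features.columns if not is_feature_column(c)]
    if bad:
        raise ValueError(f"unrecognized feature columns: {bad[:5]}")
    df = features.copy()
    df.index.name = "subject_id"
    df.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError("duplicate subject_id rows in feature table")
    bad = [c for c in df.columns if not is_feature_column(c)]
    if bad:
        raise ValueError(f"unrecognized feature columns: {bad[:5]}")
    return df.astype(np.float64)
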