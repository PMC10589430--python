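"""Imaging-derived predictors from binary lesion masks in atlas space.

Implements the quantification used throughout the pipeline: per-region
lesion percentages (the "segmented MRI" predictor), lesion volume within
atlas coordinates, hemisphere-ratio edema correction, cohort incidence
maps, region filtering, and the relative deviation-from-group-mean
heterogeneity statistic.

All operations work in 0-based voxel-index space on a shared grid; masks
must already be registered to the atlas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import AtlasVolume

__all__ = [
    "LesionMask",
    "RegionLesionProfile",
    "IncidenceMap",
    "region_lesion_percentages",
    "lesion_volume_in_atlas",
    "edema_corrected_volume",
    "filter_regions",
    "incidence_map",
    "deviation_from_group_mean",
    "RegionFilter",
    "quantify_cohort",
    "profiles_to_frame",
]


@dataclass
class LesionMask:
    """Binary 3D lesion mask aligned to an :class:`AtlasVolume`."""

    mask: np.ndarray
    animal_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("lesion mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_nifti(self, path: str | Path, atlas: AtlasVolume) -> None:
        img = nib.Nifti1Image(self.mask.astype(np.uint8), atlas.affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, animal_id: str) -> "LesionMask":
        img = nib.load(str(path))
        return cls(mask=np.asarray(img.dataobj) > 0, animal_id=animal_id)


@dataclass
class RegionLesionProfile:
    """Per-region lesion percentages plus lesion volumes for one animal.

    ``pct`` maps region id -> lesioned fraction of that region in percent
    (0-100 scale, as reported in the field); volumes are in mm^3.
    """

    animal_id: str
    pct: pd.Series
    lesion_volume_mm3: float
    corrected_volume_mm3: float


@dataclass
class IncidenceMap:
    """Voxelwise lesion frequency across a cohort of binary masks."""

    freq: np.ndarray
    n_animals: int

    def to_nifti(self, path: str | Path, atlas: AtlasVolume) -> None:
        img = nib.Nifti1Image(self.freq.astype(np.float32), atlas.affine())
        nib.save(img, str(path))


def _check_grid(mask: LesionMask | np.ndarray, atlas: AtlasVolume) -> np.ndarray:
    arr = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask).astype(bool)
    if arr.shape != atlas.shape:
        raise ValueError(
            f"mask shape {arr.shape} does not match atlas shape {atlas.shape}"
        )
    return arr


def region_lesion_percentages(
    mask: LesionMask,
    atlas: AtlasVolume,
    edema_correction: str = "hemisphere_ratio",
) -> RegionLesionProfile:
    """Express the lesioned volume of every atlas region in percent of the region.

    For each ontology region r, pct_r = 100 * |lesion ∩ r| / |r|, computed
    with exact integer voxel counts. Regions untouched by the lesion get 0.

    Parameters
    ----------
    edema_correction : {'hemisphere_ratio', 'none'}
        Strategy for the corrected volume reported alongside the raw
        in-atlas lesion volume.
    """
    arr = _check_grid(mask, atlas)
    ids = atlas.region_ids
    minlength = int(ids.max()) + 1
    lesion_counts = np.bincount(atlas.labels[arr].ravel(), minlength=minlength)
    region_counts = atlas.region_voxel_counts()
    pct = pd.Series(
        100.0 * lesion_counts[ids] / region_counts.values,
        index=ids,
        name=mask.animal_id,
    )
    vol = lesion_volume_in_atlas(mask, atlas)
    if edema_correction == "hemisphere_ratio":
        corrected = edema_corrected_volume(mask, atlas)
    elif edema_correction == "none":
        corrected = vol
    else:
        raise ValueError(f"unknown edema_correction strategy {edema_correction!r}")
    return RegionLesionProfile(
        animal_id=mask.animal_id,
        pct=pct,
        lesion_volume_mm3=vol,
        corrected_volume_mm3=corrected,
    )


def lesion_volume_in_atlas(mask: LesionMask, atlas: AtlasVolume) -> float:
    """Lesion volume (mm^3) restricted to atlas foreground.

    Lesion voxels with label 0 (outside the brain) are excluded, making the
    measure identical to the lesioned volume of atlas-covered tissue.
    """
    arr = _check_grid(mask, atlas)
    n = int(np.count_nonzero(arr & (atlas.labels > 0)))
    return n * atlas.voxel_volume_mm3


def edema_corrected_volume(
    mask: LesionMask,
    atlas: AtlasVolume,
    tie_break_side: str = "left",
) -> float:
    """Hemisphere-ratio edema correction of the in-atlas lesion volume.

    corrected = volume * (contralateral foreground volume / ipsilateral
    foreground volume). Swelling of the lesioned (ipsilateral) hemisphere
    inflates the raw volume; scaling by the hemisphere-volume ratio removes
    that inflation (Gerriets-style correction). The ipsilateral side is the
    hemisphere holding the majority of lesion voxels; an exact tie is broken
    to ``tie_break_side`` with a warning.
    """
    arr = _check_grid(mask, atlas)
    vol = lesion_volume_in_atlas(mask, atlas)
    if vol == 0.0:
        return 0.0
    left = atlas.hemisphere_mask("left")
    n_left = int(np.count_nonzero(arr & left))
    n_right = int(np.count_nonzero(arr & ~left))
    if n_left == n_right:
        warnings.warn(
            f"lesion of animal {mask.animal_id!r} straddles the midline exactly; "
            f"treating {tie_break_side!r} as ipsilateral",
            stacklevel=2,
        )
        ipsi_is_left = tie_break_side == "left"
    else:
        ipsi_is_left = n_left > n_right
    fg = atlas.labels > 0
    vol_left = int(np.count_nonzero(fg & left))
    vol_right = int(np.count_nonzero(fg & ~left))
    ipsi, contra = (vol_left, vol_right) if ipsi_is_left else (vol_right, vol_left)
    if ipsi == 0:
        raise ValueError("ipsilateral hemisphere has no atlas foreground")
    return vol * (contra / ipsi)


def filter_regions(profiles: Sequence[RegionLesionProfile] | pd.DataFrame) -> list[int]:
    """Region ids lesioned in at least one animal, ascending.

    Dimensionality reduction for the segmented-MRI predictor: a region that
    shows no lesion anywhere in the cohort carries no signal and is dropped.
    """
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    if len(frame) == 0:
        raise ValueError("need at least one profile")
    keep = frame.max(axis=0) > 0
    return sorted(int(r) for r in frame.columns[keep])


def incidence_map(masks: Sequence[LesionMask]) -> IncidenceMap:
    """Voxelwise lesion frequency (mean of binary masks) across a cohort."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].mask.shape
    acc = np.zeros(shape, dtype=np.float64)
    for m in masks:
        if m.mask.shape != shape:
            raise ValueError(f"mask of {m.animal_id!r} has shape {m.mask.shape}, expected {shape}")
        acc += m.mask
    return IncidenceMap(freq=acc / len(masks), n_animals=len(masks))


def deviation_from_group_mean(volumes: Iterable[float]) -> np.ndarray:
    """Relative deviation of each volume from the group mean, in percent.

    d_i = 100 * |v_i - mean(v)| / mean(v). This is the heterogeneity
    statistic used to compare stroke-volume variability across occlusion
    times.
    """
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one volume")
    m = v.mean()
    if m <= 0:
        raise ValueError("group mean volume must be positive")
    return 100.0 * np.abs(v - m) / m


def profiles_to_frame(profiles: Sequence[RegionLesionProfile]) -> pd.DataFrame:
    """Stack profiles into an animals x regions percentage matrix."""
    frame = pd.DataFrame({p.animal_id: p.pct for p in profiles}).T
    frame.index.name = "animal_id"
    frame.columns.name = "region_id"
    return frame


class RegionFilter(BaseEstimator, TransformerMixin):
    """Transformer that keeps only regions lesioned in >=1 training animal.

    Fitting on a cohort percentage matrix (animals x regions) learns
    ``kept_regions_``; transform selects those columns, so a replication
    cohort is reduced with the region list frozen from the original cohort.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "RegionFilter":
        self.kept_regions_ = filter_regions(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [r for r in self.kept_regions_ if r not in X.columns]
        if missing:
            raise ValueError(f"cohort is missing kept regions: {missing}")
        return X[self.kept_regions_]


def quantify_cohort(
    masks: Sequence[LesionMask],
    atlas: AtlasVolume,
    edema_correction: str = "hemisphere_ratio",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a cohort of masks: (percentage matrix, volume table).

    Returns the animals x regions percentage DataFrame and a per-animal
    table with columns lesion_volume_mm3 and corrected_volume_mm3.
    """
    profiles = [
        region_lesion_percentages(m, atlas, edema_correction=edema_correction)
        for m in masks
    ]
    frame = profiles_to_frame(profiles)
    vols = pd.DataFrame(
        {
            "lesion_volume_mm3": [p.lesion_volume_mm3 for p in profiles],
            "corrected_volume_mm3": [p.corrected_volume_mm3 for p in profiles],
        },
        index=[p.animal_id for p in profiles],
    )
    vols.index.name = "animal_id"
    return frame, vols
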