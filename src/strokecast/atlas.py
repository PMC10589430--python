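"""Atlas label volumes and region ontologies.

An :class:`AtlasVolume` is the coordinate frame for every lesion feature in
the pipeline: a 3D integer label image (0 = background) on a regular voxel
grid, together with a region ontology (id, acronym, name, hemisphere,
structure class) and a midline convention for the hemisphere split. Lesion
masks must live on the same grid, pre-registered; no world-space resampling
is performed anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["AtlasVolume", "load_atlas", "load_ontology", "save_ontology"]

#: ontology columns required by :class:`AtlasVolume`
ONTOLOGY_COLUMNS = ("acronym", "name", "hemisphere", "structure_class")


@dataclass
class AtlasVolume:
    """A 3D integer label volume plus its region ontology.

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        Region labels; 0 is background (non-brain).
    voxel_size_mm : float or 3-tuple of float
        Voxel edge length(s) in millimetres.
    ontology : DataFrame indexed by region id
        Columns ``acronym``, ``name``, ``hemisphere`` ('L' or 'R') and
        ``structure_class`` ('core' for striatum-like deep grey,
        'shell' for cortex-like surface structures).
    midline_axis : int
        Array axis along which the hemispheres are split; the midline is
        at index ``shape[midline_axis] // 2`` (left = lower indices).
    """

    labels: np.ndarray
    voxel_size_mm: float | tuple[float, float, float]
    ontology: pd.DataFrame
    midline_axis: int = 0
    _region_sizes: pd.Series = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        missing = [c for c in ONTOLOGY_COLUMNS if c not in self.ontology.columns]
        if missing:
            raise ValueError(f"ontology missing columns: {missing}")
        present = np.unique(self.labels)
        present = present[present > 0]
        unknown = set(present.tolist()) - set(self.ontology.index.tolist())
        if unknown:
            raise ValueError(f"labels contain ids absent from ontology: {sorted(unknown)}")
        self._region_sizes = None

    # ------------------------------------------------------------------ grid
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        v = self.voxel_size_mm
        if np.isscalar(v):
            return float(v) ** 3
        return float(np.prod(v))

    @property
    def region_ids(self) -> np.ndarray:
        """Region ids present in the ontology, ascending."""
        return np.sort(np.asarray(self.ontology.index))

    def foreground(self) -> np.ndarray:
        """Boolean mask of brain voxels (any nonzero label)."""
        return self.labels > 0

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Boolean mask of one hemisphere ('left' = lower midline-axis indices)."""
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        mid = self.shape[self.midline_axis] // 2
        idx = [slice(None)] * 3
        idx[self.midline_axis] = slice(0, mid) if side == "left" else slice(mid, None)
        out = np.zeros(self.shape, dtype=bool)
        out[tuple(idx)] = True
        return out

    # --------------------------------------------------------------- regions
    def region_voxel_counts(self) -> pd.Series:
        """Voxel count per ontology region (cached)."""
        if self._region_sizes is None:
            counts = np.bincount(self.labels.ravel(), minlength=int(self.region_ids.max()) + 1)
            self._region_sizes = pd.Series(
                counts[self.region_ids], index=self.region_ids, name="n_voxels"
            )
        return self._region_sizes

    def region_volumes_mm3(self) -> pd.Series:
        return self.region_voxel_counts() * self.voxel_volume_mm3

    def validate(self) -> None:
        """Raise if any ontology region has no voxels in the label image."""
        empty = self.region_voxel_counts()
        empty = empty[empty == 0]
        if len(empty):
            raise ValueError(f"ontology regions with zero voxels: {list(empty.index)}")

    # ------------------------------------------------------------------- I/O
    def affine(self) -> np.ndarray:
        v = self.voxel_size_mm
        if np.isscalar(v):
            v = (v, v, v)
        return np.diag([v[0], v[1], v[2], 1.0])

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(
        cls, path: str | Path, ontology: pd.DataFrame, midline_axis: int = 0
    ) -> "AtlasVolume":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(labels=labels, voxel_size_mm=zooms, ontology=ontology,
                   midline_axis=midline_axis)


def load_ontology(path: str | Path) -> pd.DataFrame:
    """Read a region ontology table from CSV or JSON.

    CSV needs columns region_id, acronym, name, hemisphere, structure_class;
    JSON is a mapping region_id -> {acronym, name, hemisphere, structure_class}.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        df = pd.DataFrame.from_dict(raw, orient="index")
        df.index = df.index.astype(int)
    else:
        df = pd.read_csv(path).set_index("region_id")
    df.index.name = "region_id"
    return df.sort_index()


def save_ontology(ontology: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {str(k): v for k, v in ontology.to_dict(orient="index").items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        ontology.reset_index().to_csv(path, index=False)


def load_atlas(labels_path: str | Path, ontology_path: str | Path,
               midline_axis: int = 0) -> AtlasVolume:
    """Convenience loader: NIfTI label image + ontology table."""
    return AtlasVolume.from_nifti(labels_path, load_ontology(ontology_path),
                                  midline_axis=midline_axis)
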