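"""Gray-matter volume containers, brain masks, and the subjects x voxels design matrix.

Volumes live on a shared template grid (NIfTI convention, (x, y, z) axes,
0-based indices). Vectorization uses C-order ascending linear indices so a
serialized model's coefficient order is reproducible on any machine; the
mask that defines the column order travels with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GMVolumeSet",
    "Mask",
    "DesignMatrix",
    "read_volumes",
    "write_volumes",
    "build_mask",
    "vectorize",
    "unvectorize",
    "save_volume",
]

_AFFINE_TOL = 1e-4


@dataclass
class GMVolumeSet:
    """Per-subject gray-matter probability volumes on one grid, plus metadata."""

    data: np.ndarray                  # (n_subjects, nx, ny, nz)
    subject_ids: list[str]
    ages: np.ndarray                  # years
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    cohort: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_subjects, nx, ny, nz)")
        n = self.data.shape[0]
        if len(self.subject_ids) != n or len(self.ages) != n:
            raise ValueError("subject_ids/ages length must match n_subjects")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class Mask:
    """Boolean brain mask with a fixed, ascending C-order linear index list."""

    volume: np.ndarray                # boolean, template grid
    voxel_index: np.ndarray = None    # ascending linear indices (C-order)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=bool)
        idx = np.flatnonzero(self.volume.ravel(order="C"))
        if self.voxel_index is None:
            self.voxel_index = idx
        else:
            self.voxel_index = np.asarray(self.voxel_index)
            if not np.array_equal(self.voxel_index, idx):
                raise ValueError("voxel_index inconsistent with mask volume")
        if self.voxel_index.size == 0:
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_index.size)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.volume.shape

    def save(self, path: str | Path, affine: np.ndarray | None = None) -> None:
        save_volume(self.volume.astype(np.uint8), path, affine)

    @classmethod
    def load(cls, path: str | Path) -> "Mask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0)


@dataclass
class DesignMatrix:
    """Stacked, vectorized GM maps: one row per subject, one column per masked voxel."""

    values: np.ndarray                # (n_subjects, n_voxels)
    subject_ids: list[str]
    voxel_index: np.ndarray
    grid_shape: tuple[int, ...]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    ages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x voxels)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count must match subject_ids")
        if self.values.shape[1] != len(self.voxel_index):
            raise ValueError("column count must match voxel_index")
        if np.isnan(self.values).any():
            raise ValueError("design matrix contains NaN")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def save_volume(data: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> None:
    """Write a 3-D array as NIfTI-1 (.nii or .nii.gz by extension)."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    nib.save(img, str(path))


def write_volumes(volumes: GMVolumeSet, out_dir: str | Path) -> Path:
    """Write one .nii.gz per subject plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(volumes.subject_ids):
        path = out_dir / f"{sid}.nii.gz"
        save_volume(volumes.data[i].astype(np.float32), path, volumes.affine)
        # store the filename only, so the manifest stays portable
        rows.append({"subject_id": sid, "path": path.name,
                     "age": volumes.ages[i], "cohort": volumes.cohort})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_volumes(manifest: str | Path) -> GMVolumeSet:
    """Load the volumes listed in a manifest CSV, in manifest order.

    Every file must share the first volume's grid shape and affine
    (within 1e-4); mismatches raise an error naming the offending file.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    required = {"subject_id", "path", "age"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if table["age"].isna().any():
        bad = table.loc[table["age"].isna(), "subject_id"].tolist()
        raise ValueError(f"missing age for subjects {bad}")
    data, affine, shape = [], None, None
    for _, row in table.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = manifest.parent / path
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if shape is None:
            shape, affine = arr.shape, img.affine
        else:
            if arr.shape != shape:
                raise ValueError(f"grid shape mismatch in {path}: "
                                 f"{arr.shape} vs {shape}")
            if np.max(np.abs(img.affine - affine)) > _AFFINE_TOL:
                raise ValueError(f"affine mismatch in {path}")
        data.append(arr)
    cohort = str(table["cohort"].iloc[0]) if "cohort" in table.columns else ""
    return GMVolumeSet(
        data=np.stack(data),
        subject_ids=[str(s) for s in table["subject_id"]],
        ages=table["age"].to_numpy(dtype=float),
        affine=affine,
        cohort=cohort,
    )


def build_mask(template: np.ndarray, threshold: float = 0.1) -> Mask:
    """Include every voxel whose template value exceeds ``threshold``."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    template = np.asarray(template)
    vol = template > threshold
    if not vol.any():
        raise ValueError("mask is empty at this threshold")
    return Mask(vol)


def vectorize(volumes: GMVolumeSet | np.ndarray, mask: Mask) -> DesignMatrix:
    """Stack masked voxels of each volume into a subjects x voxels matrix."""
    if isinstance(volumes, np.ndarray):
        data = volumes if volumes.ndim == 4 else volumes[None]
        volumes = GMVolumeSet(
            data=data,
            subject_ids=[f"s{i:06d}" for i in range(data.shape[0])],
            ages=np.zeros(data.shape[0]),
        )
    if volumes.grid_shape != mask.grid_shape:
        raise ValueError(f"volume grid {volumes.grid_shape} does not match "
                         f"mask grid {mask.grid_shape}")
    flat = volumes.data.reshape(volumes.n_subjects, -1)  # C-order
    return DesignMatrix(
        values=flat[:, mask.voxel_index],
        subject_ids=list(volumes.subject_ids),
        voxel_index=mask.voxel_index.copy(),
        grid_shape=mask.grid_shape,
        affine=volumes.affine,
        ages=volumes.ages.copy(),
    )


def unvectorize(weights: np.ndarray, mask: Mask) -> np.ndarray:
    """Place a coefficient vector back on the grid; zero outside the mask."""
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != mask.n_voxels:
        raise ValueError(f"weights length {weights.size} does not match "
                         f"mask size {mask.n_voxels}")
    flat = np.zeros(int(np.prod(mask.grid_shape)))
    flat[mask.voxel_index] = weights
    return flat.reshape(mask.grid_shape)
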