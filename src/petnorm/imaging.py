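"""Imaging containers and NIfTI I/O.

Every downstream computation operates on a subjects × masked-voxels matrix
(:class:`ParametricMapSet`) carrying explicit spatial metadata, so that maps
can be written back to disk on the grid they came from.  Masked vectors use a
fixed flattening order — x fastest, then y, then z, 0-based (Fortran order on
an (nx, ny, nz) array) — and that order is part of the container contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "BrainMask",
    "AtlasParcellation",
    "ParametricMapSet",
    "read_map_set",
    "make_probability_mask",
    "write_map",
]

_AFFINE_TOL_MM = 1e-4


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D sampling grid: dimensions plus voxel→world affine (mm)."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4×4, voxel indices → world mm

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4×4, got {aff.shape}")
        if any(d < 1 for d in dims):
            raise ValueError(f"all grid dims must be ≥ 1, got {dims}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(float(v) for v in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def matches(self, other: "VoxelGrid", tol_mm: float = _AFFINE_TOL_MM) -> bool:
        return self.dims == other.dims and bool(
            np.all(np.abs(self.affine - other.affine) <= tol_mm)
        )


def _flatten(vol: np.ndarray) -> np.ndarray:
    """Flatten an (nx, ny, nz) volume with x fastest (Fortran order)."""
    return np.asarray(vol).reshape(-1, order="F")


def _unflatten(vec: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    return np.asarray(vec).reshape(dims, order="F")


@dataclass(frozen=True)
class BrainMask:
    """Boolean analysis mask over a voxel grid."""

    grid: VoxelGrid
    flags: np.ndarray  # boolean, shape == grid.dims

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if flags.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {flags.shape} does not match grid dims {self.grid.dims}"
            )
        if not flags.any():
            raise ValueError("mask is empty: no analyzable voxels")
        object.__setattr__(self, "flags", flags)

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Indices of mask-true voxels in the fixed flattening order."""
        return np.flatnonzero(_flatten(self.flags))

    def extract(self, vol: np.ndarray) -> np.ndarray:
        """Pull the masked vector out of a full 3-D volume."""
        vol = np.asarray(vol)
        if vol.shape != self.grid.dims:
            raise ValueError(f"volume shape {vol.shape} != grid dims {self.grid.dims}")
        return _flatten(vol)[self.flat_indices]

    def insert(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked vector back into a full volume (out-of-mask=fill)."""
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_voxels,):
            raise ValueError(
                f"vector length {vec.shape} != mask n_voxels {self.n_voxels}"
            )
        full = np.full(self.grid.n_voxels, fill, dtype=float)
        full[self.flat_indices] = vec
        return _unflatten(full, self.grid.dims)


@dataclass(frozen=True)
class AtlasParcellation:
    """Integer-labelled parcellation; label 0 is background."""

    grid: VoxelGrid
    labels: np.ndarray  # non-negative int, shape == grid.dims
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.dims:
            raise ValueError("atlas labels shape does not match grid dims")
        if labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        labels = labels.astype(np.int32)
        present = set(np.unique(labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)

    def region_mask(self, label: int, within: BrainMask) -> np.ndarray:
        """Boolean selector over `within`'s masked-vector positions."""
        if label not in self.names:
            raise KeyError(f"unknown atlas label {label}")
        return within.extract(self.labels == label) > 0.5


@dataclass
class ParametricMapSet:
    """Subjects × masked-voxel matrix of parametric values (Ki or BPND)."""

    subject_ids: list[str]
    values: np.ndarray  # n_subjects × mask.n_voxels, float64
    mask: BrainMask
    tracer_tag: str = ""

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows for {len(self.subject_ids)} subjects"
            )
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"{self.values.shape[1]} columns for mask with "
                f"{self.mask.n_voxels} voxels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite parametric values inside mask")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, rows: Sequence[int] | np.ndarray) -> "ParametricMapSet":
        rows = np.asarray(rows)
        return ParametricMapSet(
            [self.subject_ids[i] for i in rows],
            self.values[rows],
            self.mask,
            self.tracer_tag,
        )


def _load_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar map, got shape {data.shape}")
    grid = VoxelGrid(tuple(data.shape), np.asarray(img.affine))
    return data, grid


def read_map_set(
    paths: Sequence[str | Path],
    mask: BrainMask,
    tracer_tag: str = "",
    subject_ids: Sequence[str] | None = None,
) -> ParametricMapSet:
    """Read one 3-D NIfTI map per subject into a masked matrix.

    All files must share the mask's grid (dims and affine, within 1e-4 mm);
    any non-finite voxel inside the mask is a hard error naming the file.
    """
    if not paths:
        raise ValueError("no map files given")
    rows = []
    for path in paths:
        data, grid = _load_volume(path)
        if not mask.grid.matches(grid):
            raise ValueError(
                f"grid mismatch: {path} has dims {grid.dims} / affine differing "
                f"from the mask grid {mask.grid.dims}"
            )
        vec = mask.extract(data)
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite voxel value inside mask in {path}")
        rows.append(vec)
    ids = (
        list(subject_ids)
        if subject_ids is not None
        else [Path(p).name.replace(".nii.gz", "").replace(".nii", "") for p in paths]
    )
    return ParametricMapSet(ids, np.vstack(rows), mask, tracer_tag)


def make_probability_mask(
    prob: np.ndarray | str | Path,
    threshold: float,
    grid: VoxelGrid | None = None,
) -> BrainMask:
    """Threshold a probabilistic map (values in [0, 1]) into an analysis mask.

    Inclusion is ``prob >= threshold`` ("at least" the given probability), the
    standard grey-matter masking convention for voxel-wise PET modelling.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if isinstance(prob, (str, Path)):
        prob, grid = _load_volume(prob)
    else:
        prob = np.asarray(prob, dtype=float)
        if grid is None:
            grid = VoxelGrid(
                tuple(prob.shape), np.diag([1.0, 1.0, 1.0, 1.0])
            )
    if prob.min() < -1e-9 or prob.max() > 1 + 1e-9:
        raise ValueError("probability map values must lie in [0, 1]")
    flags = prob >= threshold
    if not flags.any():
        raise ValueError(
            f"empty mask: no voxel reaches probability {threshold:g}"
        )
    return BrainMask(grid, flags)


def write_map(
    data: np.ndarray,
    path: str | Path,
    mask: BrainMask | None = None,
    grid: VoxelGrid | None = None,
) -> Path:
    """Write a scalar field as float32 NIfTI-1.

    Accepts either a full 3-D volume (with ``grid``) or a masked vector (with
    ``mask``); out-of-mask voxels are written as 0.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        if mask is None:
            raise ValueError("masked vector form requires a mask")
        vol = mask.insert(data)
        grid = mask.grid
    elif data.ndim == 3:
        grid = grid if grid is not None else (mask.grid if mask else None)
        if grid is None:
            raise ValueError("full-volume form requires a grid or mask")
        if data.shape != grid.dims:
            raise ValueError(f"volume shape {data.shape} != grid dims {grid.dims}")
        vol = data
    else:
        raise ValueError("data must be a masked vector or 3-D volume")
    img = nib.Nifti1Image(vol.astype(np.float32), grid.affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
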