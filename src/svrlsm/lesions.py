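"""Binary lesion masks and the participants-by-voxels lesion matrix.

Masks must arrive pre-registered on one common voxel grid (the upstream
spatial-normalization pipeline is out of scope); a geometry mismatch is
an error, never a silent resample. The lesion matrix keeps only voxels
lesioned in at least ``min_overlap`` participants (optionally after
intersection with an analysis mask such as gray matter), and carries the
voxel-index bookkeeping needed to scatter any per-voxel statistic back
onto the grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

from .exceptions import CohortGeometryError, EmptyMatrixError, InvalidInputError

__all__ = [
    "LesionMask",
    "OverlapMap",
    "LesionMatrix",
    "read_mask",
    "write_mask",
    "write_overlap_map",
    "lesion_volume_cc",
    "overlap_map",
    "build_lesion_matrix",
]

_AFFINE_TOL = 1e-6


@dataclass
class LesionMask:
    """A binary lesion mask on a voxel grid with a voxel-to-world affine."""

    participant_id: str
    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise InvalidInputError("lesion mask must be a 3D volume")
        values = np.unique(self.grid)
        if not np.all(np.isin(values, (0, 1))):
            raise InvalidInputError("lesion mask values must be binary {0,1}")
        self.grid = self.grid.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise InvalidInputError("affine must be 4x4")

    @property
    def voxel_dims(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_lesion_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class OverlapMap:
    """Voxelwise count of how many participants' lesions cover each voxel."""

    grid: np.ndarray
    affine: np.ndarray
    n_participants: int


def _check_shared_geometry(masks: Sequence[LesionMask]) -> None:
    if not masks:
        raise InvalidInputError("need at least one lesion mask")
    ref = masks[0]
    for m in masks[1:]:
        if m.grid.shape != ref.grid.shape:
            raise CohortGeometryError(
                f"grid shape mismatch: {m.participant_id} has {m.grid.shape}, "
                f"{ref.participant_id} has {ref.grid.shape}"
            )
        if not np.allclose(m.affine, ref.affine, atol=_AFFINE_TOL, rtol=0):
            raise CohortGeometryError(
                f"affine mismatch between {m.participant_id} and {ref.participant_id}"
            )


def read_mask(path, participant_id: str | None = None,
              binarize_tolerance: float = 1e-3) -> LesionMask:
    """Read a NIfTI lesion mask, binarizing non-zero voxels to 1.

    Values other than 0/1 beyond ``binarize_tolerance`` trigger a
    warning before thresholding at 0.5. An empty (all-zero) mask is
    accepted with a warning.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    off_binary = np.abs(data - np.round(data)) > binarize_tolerance
    if off_binary.any() or data.max(initial=0) > 1:
        warnings.warn(
            f"{path}: mask contains non-binary values; thresholding at 0.5",
            stacklevel=2,
        )
    grid = (data > 0.5).astype(np.uint8) if off_binary.any() else (data != 0).astype(np.uint8)
    pid = participant_id if participant_id is not None else _stem(path)
    if grid.sum() == 0:
        warnings.warn(f"{path}: lesion mask is empty", stacklevel=2)
    return LesionMask(pid, grid, img.affine)


def _stem(path) -> str:
    name = str(path).rsplit("/", 1)[-1]
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def write_mask(mask: LesionMask, path) -> None:
    """Write a mask (or any labeled volume on its grid) as NIfTI-1."""
    nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine).to_filename(str(path))


def write_overlap_map(om: OverlapMap, path) -> None:
    """Write an overlap map as an integer NIfTI volume."""
    nib.Nifti1Image(om.grid.astype(np.int16), om.affine).to_filename(str(path))


def lesion_volume_cc(mask: LesionMask) -> float:
    """Lesion volume in cubic centimetres: voxel count x voxel volume / 1000."""
    voxel_mm3 = float(np.prod(mask.voxel_dims))
    return mask.n_lesion_voxels * voxel_mm3 / 1000.0


def overlap_map(masks: Sequence[LesionMask]) -> OverlapMap:
    """Voxelwise sum of binary lesion masks across the cohort."""
    _check_shared_geometry(masks)
    total = np.zeros(masks[0].grid.shape, dtype=np.int32)
    for m in masks:
        total += m.grid
    return OverlapMap(total, masks[0].affine.copy(), len(masks))


@dataclass
class LesionMatrix:
    """Participants x included-voxels binary design matrix.

    ``voxel_index`` holds the 3D grid coordinate of each column so that
    any per-voxel vector can be scattered back onto the grid, and
    ``inclusion_mask`` marks the included voxels volumetrically.
    """

    X: np.ndarray
    voxel_index: np.ndarray  # (n_voxels, 3) int coordinates, 0-based
    inclusion_mask: np.ndarray
    affine: np.ndarray
    participant_ids: list[str]
    min_overlap: int

    @property
    def n_participants(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def voxel_dims(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-column vector back onto the 3D grid."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise InvalidInputError(
                f"expected {self.n_voxels} values, got {values.shape}"
            )
        out = np.full(self.inclusion_mask.shape, fill, dtype=float)
        i, j, k = self.voxel_index.T
        out[i, j, k] = values
        return out

    def row_volume(self, row: int) -> np.ndarray:
        """Rebuild one participant's lesion restricted to included voxels."""
        return self.to_volume(self.X[row].astype(float)).astype(np.uint8)

    def save(self, path) -> None:
        """Persist as a compressed npz plus embedded JSON metadata."""
        meta = json.dumps({
            "participant_ids": self.participant_ids,
            "min_overlap": self.min_overlap,
        })
        np.savez_compressed(
            str(path),
            X=self.X,
            voxel_index=self.voxel_index,
            inclusion_mask=self.inclusion_mask.astype(np.uint8),
            affine=self.affine,
            meta=np.array(meta),
        )

    @classmethod
    def load(cls, path) -> "LesionMatrix":
        with np.load(str(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            return cls(
                X=data["X"],
                voxel_index=data["voxel_index"],
                inclusion_mask=data["inclusion_mask"].astype(bool),
                affine=data["affine"],
                participant_ids=list(meta["participant_ids"]),
                min_overlap=int(meta["min_overlap"]),
            )


def build_lesion_matrix(
    masks: Sequence[LesionMask],
    min_overlap: int = 4,
    analysis_mask: LesionMask | np.ndarray | None = None,
    mask_before_overlap: bool = True,
) -> LesionMatrix:
    """Assemble the design matrix over voxels lesioned in >= ``min_overlap``
    participants.

    An optional analysis mask (e.g., gray matter) restricts the voxel
    set; by default it is applied before the overlap criterion is
    evaluated (``mask_before_overlap=False`` reverses the order, which
    only matters for bookkeeping since the operations commute on the
    surviving set).
    """
    _check_shared_geometry(masks)
    if min_overlap < 1:
        raise InvalidInputError("min_overlap must be >= 1")
    counts = overlap_map(masks).grid
    restrict = None
    if analysis_mask is not None:
        am = analysis_mask.grid if isinstance(analysis_mask, LesionMask) else np.asarray(analysis_mask)
        if am.shape != counts.shape:
            raise CohortGeometryError("analysis mask is not on the cohort grid")
        restrict = am.astype(bool)
    if restrict is not None and mask_before_overlap:
        include = (np.where(restrict, counts, 0) >= min_overlap)
    else:
        include = counts >= min_overlap
        if restrict is not None:
            include &= restrict
    if not include.any():
        raise EmptyMatrixError(
            f"no voxel is lesioned in at least {min_overlap} participants"
        )
    voxel_index = np.argwhere(include)
    i, j, k = voxel_index.T
    X = np.stack([m.grid[i, j, k] for m in masks]).astype(np.uint8)
    return LesionMatrix(
        X=X,
        voxel_index=voxel_index,
        inclusion_mask=include,
        affine=masks[0].affine.copy(),
        participant_ids=[m.participant_id for m in masks],
        min_overlap=min_overlap,
    )
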