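"""Volume and affine-transform data model shared by every pipeline stage.

Conventions
-----------
* World space is RAS+ millimetres; voxel indices are 0-based.
* Affines are homogeneous 4x4 matrices acting on column vectors, so a
  chain ``B after A`` is the matrix product ``B @ A``.
* NaN marks masked voxels in scalar volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "AffineTransform",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_affine",
    "write_affine",
    "resample_labels",
]


@dataclass
class Volume3D:
    """A 3D scalar image with its voxel-to-world affine.

    Parameters
    ----------
    data
        3D floating-point array; NaN marks masked voxels.
    voxel_to_mm
        4x4 homogeneous affine mapping 0-based voxel indices to RAS+ mm.
    """

    data: np.ndarray
    voxel_to_mm: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D image: got {self.data.ndim} dimensions")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.voxel_to_mm = np.asarray(self.voxel_to_mm, dtype=np.float64)
        if self.voxel_to_mm.shape != (4, 4):
            raise ValueError("voxel_to_mm must be 4x4")
        if abs(np.linalg.det(self.voxel_to_mm[:3, :3])) < 1e-12:
            raise ValueError("voxel_to_mm linear part is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.voxel_to_mm[:3, :3], axis=0)

    def same_grid(self, other: "Volume3D | LabelVolume", atol: float = 1e-6) -> bool:
        other_shape = other.data.shape if isinstance(other, Volume3D) else other.labels.shape
        return self.data.shape == other_shape and np.allclose(
            self.voxel_to_mm, other.voxel_to_mm, atol=atol
        )


@dataclass
class AffineTransform:
    """Homogeneous 4x4 spatial transform between two named spaces."""

    matrix: np.ndarray
    from_space: str = ""
    to_space: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of affine must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine linear part is singular")

    def inverse(self) -> "AffineTransform":
        return AffineTransform(
            np.linalg.inv(self.matrix), from_space=self.to_space, to_space=self.from_space
        )

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of mm coordinates through the transform."""
        pts = np.atleast_2d(points_mm)
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out.reshape(np.shape(points_mm))


@dataclass
class LabelVolume:
    """Integer-labelled ROI volume; 0 is background."""

    labels: np.ndarray
    voxel_to_mm: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"non-3D image: got {self.labels.ndim} dimensions")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int32)
        self.voxel_to_mm = np.asarray(self.voxel_to_mm, dtype=np.float64)
        present = set(np.unique(self.labels)) - {0}
        if self.label_names:
            missing = present - set(self.label_names)
            if missing:
                raise ValueError(f"labels without names: {sorted(missing)}")

    def counts(self) -> dict[int, int]:
        vals, cts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), cts.tolist()))


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 scalar volume, promoting data to floating point."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    return Volume3D(data.astype(np.float64), np.asarray(img.affine))


def write_volume(v: Volume3D, path: str | Path) -> Path:
    """Write a Volume3D as NIfTI-1; returns the path written."""
    path = Path(path)
    img = nib.Nifti1Image(v.data.astype(np.float64), v.voxel_to_mm)
    nib.save(img, str(path))
    return path


def read_labels(path: str | Path, label_names: dict[int, str] | None = None) -> LabelVolume:
    """Read an integer label volume from NIfTI-1."""
    v = read_volume(path)
    return LabelVolume(np.rint(v.data).astype(np.int32), v.voxel_to_mm, label_names or {})


def write_labels(lv: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(lv.labels.astype(np.int16), lv.voxel_to_mm)
    nib.save(img, str(path))
    return path


def read_affine(path: str | Path, from_space: str = "", to_space: str = "") -> AffineTransform:
    """Read a plain-text 4x4 affine (4 lines of 4 numbers, row-major)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(tok) for tok in line.split()])
    arr = np.array(rows, dtype=np.float64)
    if arr.shape != (4, 4):
        raise ValueError(f"affine file {path} has shape {arr.shape}, expected (4, 4)")
    return AffineTransform(arr, from_space=from_space, to_space=to_space)


def write_affine(t: AffineTransform, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, t.matrix, fmt="%.17g")
    return path


def resample_labels(
    lv: LabelVolume, t: AffineTransform, target: Volume3D
) -> LabelVolume:
    """Pull a label volume onto the grid of ``target`` by nearest neighbour.

    ``t`` maps target-space mm to label-space mm (the pull direction).
    Labels are categorical, so only nearest-neighbour sampling is offered;
    voxels that land outside the source extent become background (0).
    """
    # voxel(target) -> mm(target) -> mm(labels) -> voxel(labels)
    vox2vox = np.linalg.inv(lv.voxel_to_mm) @ t.matrix @ target.voxel_to_mm
    ii, jj, kk = np.meshgrid(
        *(np.arange(s, dtype=np.float64) for s in target.data.shape), indexing="ij"
    )
    coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=0)
    src = vox2vox[:3, :3] @ coords + vox2vox[:3, 3:4]
    out = ndimage.map_coordinates(
        lv.labels, src, order=0, mode="constant", cval=0, prefilter=False
    )
    return LabelVolume(
        out.reshape(target.data.shape).astype(lv.labels.dtype),
        target.voxel_to_mm.copy(),
        dict(lv.label_names),
    )
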