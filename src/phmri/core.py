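"""Core data containers shared across the pipeline.

The coordinate conventions used throughout:

* voxel indices are 0-based ``(x, y, z)``;
* world coordinates are in millimetres measured from the volume corner,
  ``world = index * voxel_size``;
* affine transforms act on world coordinates and map *subject* (moving)
  space into *atlas* (reference) space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AtlasVolume", "BoldScan", "AffineTransform"]


@dataclass
class AtlasVolume:
    """A 3D integer parcellation of the brain into named regions.

    ``labels`` holds 0 for background and ``1..R`` for regions; every group
    result in the pipeline lives in this coordinate frame.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive lengths (mm)")
        present = np.unique(self.labels)
        if present.min() < 0:
            raise ValueError("negative region labels are not allowed")
        ids = present[present > 0]
        if ids.size and not np.array_equal(ids, np.arange(1, ids.max() + 1)):
            raise ValueError("region ids must form a contiguous range 1..R")
        if not self.region_names:
            self.region_names = {int(i): f"region_{int(i):03d}" for i in ids}

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @property
    def region_ids(self) -> np.ndarray:
        return np.arange(1, self.n_regions + 1)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_voxel_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_regions + 1)
        return {int(i): int(counts[i]) for i in self.region_ids}

    def empty_regions(self) -> list[int]:
        """Region ids named in the lookup but absent from the label image."""
        counts = self.region_voxel_counts()
        return [i for i in self.region_names if counts.get(i, 0) == 0]


@dataclass
class BoldScan:
    """One subject's 4D BOLD time series plus acquisition metadata."""

    data: np.ndarray  # (x, y, z, t), arbitrary units
    tr_seconds: float
    mask: np.ndarray  # 3D boolean brain mask
    motion_params: np.ndarray | None = None  # (t, 6): mm translations, rad rotations
    outlier_flags: np.ndarray | None = None  # (t,) boolean
    tissue_means: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.n_acquisitions < 2:
            raise ValueError("a scan needs at least two acquisitions")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial shape of the data")
        if self.outlier_flags is None:
            self.outlier_flags = np.zeros(self.n_acquisitions, dtype=bool)
        else:
            self.outlier_flags = np.asarray(self.outlier_flags, dtype=bool)
            if self.outlier_flags.shape != (self.n_acquisitions,):
                raise ValueError("outlier_flags must have one entry per acquisition")
        if self.motion_params is not None:
            self.motion_params = np.asarray(self.motion_params, dtype=float)
            if self.motion_params.shape != (self.n_acquisitions, 6):
                raise ValueError("motion_params must be (t, 6)")

    @property
    def n_acquisitions(self) -> int:
        return int(self.data.shape[3])

    def masked_series(self) -> np.ndarray:
        """In-mask voxel time courses as a (n_voxels, t) array."""
        return self.data[self.mask]


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class AffineTransform:
    """A 9-parameter (translation, rotation, per-axis scale) world transform.

    Composed as translation @ rotation @ scale; no shear term, matching a
    rigid-plus-scaling registration family.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4 homogeneous")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(
        cls,
        translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
        rotation_rad: tuple[float, float, float] = (0.0, 0.0, 0.0),
        scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> "AffineTransform":
        M = np.eye(4)
        M[:3, :3] = _rotation_matrix(*rotation_rad) @ np.diag(scale)
        M[:3, 3] = translation_mm
        return cls(M)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform applying ``other`` first, then ``self``."""
        return AffineTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of world coordinates through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out if np.asarray(points).ndim > 1 else out[0]

    def decompose(self) -> dict[str, np.ndarray]:
        """Recover translation, rotation matrix and per-axis scales.

        Valid for shear-free transforms only: scales are the column norms of
        the linear part.
        """
        A = self.matrix[:3, :3]
        scales = np.linalg.norm(A, axis=0)
        R = A / scales
        return {
            "translation": self.matrix[:3, 3].copy(),
            "rotation": R,
            "scale": scales,
        }
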