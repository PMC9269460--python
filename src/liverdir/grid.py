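"""Image and displacement-field containers on axis-aligned voxel grids.

Conventions used throughout the package:

* axis order is ``(x, y, z)`` = (left-right, anterior-posterior,
  superior-inferior);
* voxel indices are 0-based and ``world_mm = origin + index * spacing``
  (axis-aligned grids only, no oblique orientation);
* displacement fields store millimetre 3-vectors per voxel of the grid
  they are *anchored* to, and act as point maps
  ``x -> x + u(x)`` from the anchor phase to the target phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


@dataclass
class ImageVolume:
    """A 3D scalar volume with physical geometry (HU-like intensities)."""

    data: np.ndarray
    spacing: np.ndarray  # mm per voxel, shape (3,)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | DisplacementField") -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounding box (low, high) of voxel centers in mm."""
        hi = self.origin + (np.asarray(self.shape) - 1) * self.spacing
        return self.origin.copy(), hi

    def index_grid_mm(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        return index_grid_mm(self.shape, self.spacing, self.origin)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class DisplacementField:
    """Per-voxel displacement (mm) anchored on ``from_phase``'s grid.

    As a point map this sends a point ``x`` in ``from_phase`` world
    coordinates to ``x + u(x)`` in ``to_phase`` coordinates.  The same
    field is the pull-back used to resample the ``to_phase`` image onto
    the anchor grid.
    """

    data: np.ndarray  # (*shape, 3) mm
    spacing: np.ndarray
    origin: np.ndarray
    from_phase: int | str = "?"
    to_phase: int | str = "?"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(f"expected (*shape, 3) field, got {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @classmethod
    def zeros_like(
        cls,
        vol: "ImageVolume",
        from_phase: int | str = "?",
        to_phase: int | str = "?",
    ) -> "DisplacementField":
        return cls(
            np.zeros((*vol.shape, 3)),
            vol.spacing.copy(),
            vol.origin.copy(),
            from_phase,
            to_phase,
        )

    def magnitude_mm(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)

    def magnitude_voxels(self) -> np.ndarray:
        return np.linalg.norm(self.data / self.spacing, axis=-1)


def index_grid_mm(shape, spacing, origin) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def sample_at_points(
    vol: ImageVolume,
    points_mm: np.ndarray,
    order: int = 1,
    background: float | None = None,
) -> np.ndarray:
    """Interpolate ``vol`` at world points.

    ``background=None`` clamps to the edge (used for field lookup);
    otherwise out-of-bounds samples take the given value.
    """
    pts = np.asarray(points_mm, dtype=np.float64)
    idx = (pts - vol.origin) / vol.spacing
    coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
    if background is None:
        out = ndimage.map_coordinates(vol.data, coords, order=order, mode="nearest")
    else:
        out = ndimage.map_coordinates(
            vol.data, coords, order=order, mode="constant", cval=background
        )
    return out.reshape(pts.shape[:-1])


def sample_field_at_points(
    fld: DisplacementField, points_mm: np.ndarray, order: int = 1
) -> np.ndarray:
    """Interpolate a displacement field at world points (clamp-to-edge)."""
    pts = np.asarray(points_mm, dtype=np.float64)
    idx = (pts - fld.origin) / fld.spacing
    coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
    out = np.empty((coords.shape[1], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            fld.data[..., c], coords, order=order, mode="nearest"
        )
    return out.reshape(pts.shape)


# ---------------------------------------------------------------------------
# NIfTI I/O.  Axis-aligned affine: diag(spacing) with origin translation.
# ---------------------------------------------------------------------------


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def save_field(fld: DisplacementField, path) -> None:
    """Write a field as a 4D NIfTI plus a JSON sidecar with direction tags."""
    img = nib.Nifti1Image(
        fld.data.astype(np.float32), _affine(fld.spacing, fld.origin)
    )
    nib.save(img, str(path))
    sidecar = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {"from_phase": fld.from_phase, "to_phase": fld.to_phase, "units": "mm"},
            fh,
        )


def load_field(path) -> DisplacementField:
    img = nib.load(str(path))
    aff = img.affine
    sidecar = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    tags = {"from_phase": "?", "to_phase": "?"}
    try:
        with open(sidecar) as fh:
            tags.update(json.load(fh))
    except FileNotFoundError:
        pass
    return DisplacementField(
        np.asarray(img.dataobj, dtype=np.float64),
        np.abs(np.diag(aff)[:3]),
        aff[:3, 3],
        tags["from_phase"],
        tags["to_phase"],
    )
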