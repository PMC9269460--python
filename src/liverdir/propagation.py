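"""Mid-ventilation selection and DIR-based contour propagation.

The mid-ventilation phase — where the tumor surrogate (markers' COM)
is closest to its time-averaged position — carries the planning
delineations.  Liver and GTV masks are propagated from it to every
other phase through the registration point maps, and summarized by
center of mass, volume, and the volume coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import compose_fields, warp_image
from .grid import DisplacementField, ImageVolume
from .markers import MarkerSet


class EmptyMaskError(ValueError):
    pass


@dataclass
class StructureTrajectory:
    """Per-phase COM and volume summaries of the propagated structures."""

    gtv_com_mm: np.ndarray  # (n_phases, 3)
    liver_com_mm: np.ndarray
    gtv_volume_cm3: np.ndarray
    liver_volume_cm3: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.gtv_volume_cm3)
        return pd.DataFrame(
            {
                "phase_index": np.arange(n),
                "gtv_com_x": self.gtv_com_mm[:, 0],
                "gtv_com_y": self.gtv_com_mm[:, 1],
                "gtv_com_z": self.gtv_com_mm[:, 2],
                "liver_com_x": self.liver_com_mm[:, 0],
                "liver_com_y": self.liver_com_mm[:, 1],
                "liver_com_z": self.liver_com_mm[:, 2],
                "gtv_cm3": self.gtv_volume_cm3,
                "liver_cm3": self.liver_volume_cm3,
            }
        )


def select_mid_ventilation(markers: MarkerSet) -> int:
    """Phase whose markers-COM is nearest the time-averaged markers-COM.

    Ties break toward the lower phase index.
    """
    if markers.n_phases < 2:
        raise ValueError("need at least 2 phases")
    coms = markers.com_trajectory()
    mean_com = coms.mean(axis=0)
    dist = np.linalg.norm(coms - mean_com, axis=1)
    return int(np.argmin(dist))  # argmin takes the first (lowest) index on ties


def propagate_labels(
    mask: ImageVolume,
    transforms: dict[tuple[int, int], DisplacementField] | dict,
    source_phase: int,
    target_phase: int,
    path: list[tuple[int, int]],
) -> ImageVolume:
    """Pull a label mask from the source (mid-ventilation) phase onto a
    target phase's grid.

    ``path`` lists the adjacent links source→target; the pull-back uses
    the composed point map target→source (linear interpolation then
    0.5 threshold).  ``transforms[(a, b)]`` must map a-coordinates to
    b-coordinates for each link (either orientation may be stored).
    """
    if source_phase == target_phase or not path:
        return mask.with_data((mask.data >= 0.5).astype(float))
    # build target -> source by walking the path backwards
    fld = None
    for a, b in reversed(path):
        step = _link_field(transforms, b, a)
        fld = step if fld is None else compose_fields(fld, step, check_tags=False)
    return warp_image(mask, fld, interpolation="mask", background=0.0)


def _link_field(transforms, a, b) -> DisplacementField:
    if (a, b) in transforms:
        return transforms[(a, b)]
    raise KeyError(
        f"missing registration link {a}->{b}; available: {sorted(transforms)}"
    )


def mask_com(mask: ImageVolume) -> np.ndarray:
    """Voxel centroid of a binary mask in world mm."""
    m = mask.data >= 0.5
    if not m.any():
        raise EmptyMaskError("mask is empty")
    idx = np.argwhere(m)
    return idx.mean(axis=0) * mask.spacing + mask.origin


def mask_volume(mask: ImageVolume) -> float:
    """Voxel count times voxel volume, in cm³."""
    m = mask.data >= 0.5
    if not m.any():
        raise EmptyMaskError("mask is empty")
    return float(m.sum() * np.prod(mask.spacing) / 1000.0)


def volume_cv(volumes) -> float:
    """Coefficient of variation 100·(sample sd / mean), in percent."""
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 phases")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean volume")
    return float(100.0 * v.std(ddof=1) / mean)


def propagate_structures(
    liver_mask: ImageVolume,
    gtv_mask: ImageVolume,
    pair_fields: dict[tuple[int, int], DisplacementField],
    mid_ventilation: int,
    n_phases: int,
    cyclic: bool = True,
) -> StructureTrajectory:
    """Propagate liver and GTV masks from mid-ventilation to all phases
    along minimal-composition sequential paths and summarize them."""
    from .strategies import propagation_path

    gtv_com = np.empty((n_phases, 3))
    liver_com = np.empty((n_phases, 3))
    gtv_vol = np.empty(n_phases)
    liver_vol = np.empty(n_phases)
    for j in range(n_phases):
        path = propagation_path(mid_ventilation, j, n_phases, cyclic=cyclic)
        g = propagate_labels(gtv_mask, pair_fields, mid_ventilation, j, path)
        l = propagate_labels(liver_mask, pair_fields, mid_ventilation, j, path)
        gtv_com[j] = mask_com(g)
        liver_com[j] = mask_com(l)
        gtv_vol[j] = mask_volume(g)
        liver_vol[j] = mask_volume(l)
    return StructureTrajectory(gtv_com, liver_com, gtv_vol, liver_vol)
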