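"""Automatic fiducial-marker localization and tracking.

Implanted gold fiducials are radio-opaque (well above 500 HU) against
soft tissue, so a fixed HU threshold followed by connected-component
analysis localizes them in every respiratory phase.  The centroid of
each component (unweighted, over voxel centers) is the measured marker
position; the arithmetic mean of the three centroids is the markers'
center of mass (COM), a more stable surrogate of tumor position than
any single marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .grid import ImageVolume

HU_THRESHOLD = 500.0
MIN_COMPONENT_VOXELS = 3


class NoMarkersFound(RuntimeError):
    """The thresholded volume contains no component of sufficient size."""


class MarkerCountMismatch(RuntimeError):
    pass


@dataclass
class MarkerSet:
    """Identity-labelled marker centroids (mm) per phase."""

    centroids_mm: np.ndarray  # (n_phases, n_markers, 3)
    reference_index: int

    @property
    def n_phases(self) -> int:
        return self.centroids_mm.shape[0]

    @property
    def n_markers(self) -> int:
        return self.centroids_mm.shape[1]

    def com(self, phase: int) -> np.ndarray:
        """Markers' center of mass: component-wise mean of the centroids."""
        return markers_com(self, phase)

    def com_trajectory(self) -> np.ndarray:
        return self.centroids_mm.mean(axis=1)


def segment_markers(
    vol: ImageVolume,
    hu_threshold: float = HU_THRESHOLD,
    min_voxels: int = MIN_COMPONENT_VOXELS,
) -> tuple[np.ndarray, int]:
    """Label voxels strictly above the HU threshold by 26-connectivity.

    Components smaller than ``min_voxels`` are discarded (noise spikes).
    Returns (label volume, number of components); raises
    :class:`NoMarkersFound` if none survive.
    """
    mask = vol.data > hu_threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n and min_voxels > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_voxels)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
            labels, n = ndimage.label(labels > 0, structure=structure)
    if n == 0:
        raise NoMarkersFound(
            f"no connected component above {hu_threshold} HU with "
            f">= {min_voxels} voxels"
        )
    return labels, int(n)


def marker_centroids(
    labels: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Unweighted centroid of each labelled component in world mm."""
    n = int(labels.max())
    if n == 0:
        raise NoMarkersFound("label volume contains no components")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    cents = ndimage.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    return np.asarray(cents, dtype=float) * spacing + origin


def detect_markers(
    vol: ImageVolume,
    hu_threshold: float = HU_THRESHOLD,
    min_voxels: int = MIN_COMPONENT_VOXELS,
) -> np.ndarray:
    """Threshold-segment then centroid one phase volume."""
    labels, _ = segment_markers(vol, hu_threshold, min_voxels)
    return marker_centroids(labels, vol.spacing, vol.origin)


def track_markers(
    per_phase_centroids: list[np.ndarray], reference_index: int
) -> MarkerSet:
    """Assign marker identities across phases.

    Correspondence with the reference phase is solved by minimum-total-
    distance (Hungarian) matching — exact for the three-marker case and
    robust to arbitrary input ordering.  Inter-marker distances far
    exceed breathing displacements, so the assignment is unambiguous.
    """
    counts = {len(c) for c in per_phase_centroids}
    if len(counts) != 1:
        bad = [
            f"phase {k}: {len(c)}" for k, c in enumerate(per_phase_centroids)
        ]
        raise MarkerCountMismatch(
            "marker count differs across phases (" + ", ".join(bad) + ")"
        )
    ref = np.asarray(per_phase_centroids[reference_index], dtype=float)
    out = np.empty((len(per_phase_centroids), len(ref), 3))
    for k, cents in enumerate(per_phase_centroids):
        cents = np.asarray(cents, dtype=float)
        cost = np.linalg.norm(ref[:, None, :] - cents[None, :, :], axis=-1)
        rows, cols = linear_sum_assignment(cost)
        out[k, rows] = cents[cols]
    return MarkerSet(out, reference_index)


def detect_and_track(
    volumes: list[ImageVolume],
    reference_index: int,
    hu_threshold: float = HU_THRESHOLD,
    min_voxels: int = MIN_COMPONENT_VOXELS,
) -> MarkerSet:
    cents = [detect_markers(v, hu_threshold, min_voxels) for v in volumes]
    return track_markers(cents, reference_index)


def markers_com(markers: MarkerSet, phase: int) -> np.ndarray:
    if not (0 <= phase < markers.n_phases):
        raise IndexError(f"phase {phase} not in 0..{markers.n_phases - 1}")
    return markers.centroids_mm[phase].mean(axis=0)
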