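"""Marker segmentation, centroids, tracking and COM."""

import numpy as np
import pytest

from liverdir.grid import ImageVolume
from liverdir.markers import (
    MarkerCountMismatch,
    NoMarkersFound,
    detect_and_track,
    detect_markers,
    marker_centroids,
    markers_com,
    segment_markers,
    track_markers,
)
from liverdir.phantom import build_anatomy

from conftest import small_spec
from oracles import exhaustive_marker_matching


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, float), spacing)


class TestSegmentMarkers:
    def test_below_threshold_signals_no_markers(self):
        vol = _vol(np.full((8, 8, 8), 499.0))
        with pytest.raises(NoMarkersFound):
            segment_markers(vol)

    def test_threshold_is_strict(self):
        data = np.zeros((8, 8, 8))
        data[4, 4, 4] = 500.0  # exactly at threshold: excluded
        with pytest.raises(NoMarkersFound):
            segment_markers(_vol(data), min_voxels=1)
        data[4, 4, 4] = 501.0
        labels, n = segment_markers(_vol(data), min_voxels=1)
        assert n == 1 and labels[4, 4, 4] == 1

    def test_phantom_has_three_components(self):
        vol, *_ = build_anatomy(small_spec())
        _, n = segment_markers(vol)
        assert n == 3

    def test_small_components_discarded(self):
        data = np.zeros((10, 10, 10))
        data[2, 2, 2] = 600.0  # single-voxel spike
        data[6:8, 6:8, 6] = 600.0  # 4-voxel blob
        _, n = segment_markers(_vol(data), min_voxels=3)
        assert n == 1

    def test_detection_idempotent(self):
        vol, *_ = build_anatomy(small_spec())
        labels, n = segment_markers(vol)
        masked = vol.with_data(np.where(labels > 0, vol.data, 0.0))
        labels2, n2 = segment_markers(masked)
        assert n2 == n
        assert np.array_equal(labels > 0, labels2 > 0)


class TestCentroids:
    def test_two_voxel_midpoint(self):
        data = np.zeros((5, 5, 5))
        data[0, 0, 0] = data[2, 0, 0] = 600.0
        labels, _ = segment_markers(_vol(data), min_voxels=1)
        # the two voxels are 26-disconnected? they are 2 apart -> separate
        # components; use a contiguous pair instead
        data = np.zeros((5, 5, 5))
        data[0, 0, 0] = data[1, 0, 0] = data[2, 0, 0] = 600.0
        labels, _ = segment_markers(_vol(data), min_voxels=1)
        c = marker_centroids(labels, (1.0, 1.0, 1.0))
        assert np.allclose(c, [[1.0, 0.0, 0.0]])

    def test_flip_symmetry(self, rng):
        data = np.zeros((11, 11, 11))
        ii, jj, kk = np.mgrid[:11, :11, :11]
        ball = (ii - 5) ** 2 + (jj - 5) ** 2 + (kk - 5) ** 2 <= 9
        data[ball] = 700.0
        labels, _ = segment_markers(_vol(data))
        c = marker_centroids(labels, (1.0, 1.0, 1.0))
        flipped, _ = segment_markers(_vol(data[::-1, ::-1, ::-1]))
        cf = marker_centroids(flipped, (1.0, 1.0, 1.0))
        assert np.allclose(c, 10.0 - cf)

    def test_phantom_centroids_subvoxel_accurate(self):
        # stamped blobs with sub-voxel offsets must localize to better
        # than half the largest voxel dimension per axis
        offsets = [(0.3, -0.2, 0.7), (-0.4, 0.4, -0.9)]
        base = small_spec()
        for off in offsets:
            pos = tuple(
                tuple(np.asarray(p) + off) for p in base.marker_positions_mm
            )
            spec = small_spec(marker_positions_mm=pos)
            vol, _, _, true_pos = build_anatomy(spec)
            cents = detect_markers(vol)
            matched = exhaustive_marker_matching(true_pos, cents)
            assert np.abs(matched - true_pos).max() < 0.5 * max(spec.spacing_mm)


class TestTracking:
    def test_identity_assignment(self):
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        ms = track_markers([pts, pts, pts], reference_index=1)
        assert np.allclose(ms.centroids_mm, np.stack([pts] * 3))

    def test_restores_swapped_ordering(self):
        ref = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        moved = ref + [0.0, 0.0, 2.0]
        shuffled = moved[[2, 0, 1]]
        ms = track_markers([ref, shuffled], reference_index=0)
        assert np.allclose(ms.centroids_mm[1], moved)
        assert np.allclose(ms.centroids_mm[1], exhaustive_marker_matching(ref, shuffled))

    def test_matches_exhaustive_for_random_shuffles(self, rng):
        # breathing displacements are far smaller than inter-marker
        # distances, so min-sum matching must equal brute force
        ref = np.array([[0.0, 0, 0], [15, 5, 0], [5, 20, 10]])
        for _ in range(20):
            moved = ref + rng.uniform(-3, 3, size=(3, 3))
            perm = rng.permutation(3)
            ms = track_markers([ref, moved[perm]], reference_index=0)
            assert np.allclose(ms.centroids_mm[1], exhaustive_marker_matching(ref, moved[perm]))

    def test_unequal_counts_fail_loudly(self):
        a = np.zeros((3, 3))
        b = np.zeros((2, 3))
        with pytest.raises(MarkerCountMismatch, match="phase 1: 2"):
            track_markers([a, b], reference_index=0)


class TestMarkersCom:
    def test_mean_of_three(self):
        pts = np.array([[0.0, 0, 0], [3, 0, 0], [6, 0, 0]])
        ms = track_markers([pts], reference_index=0)
        assert np.allclose(markers_com(ms, 0), [3.0, 0.0, 0.0])

    def test_single_marker_degenerate(self):
        pts = np.array([[1.0, 2, 3]])
        ms = track_markers([pts], reference_index=0)
        assert np.allclose(markers_com(ms, 0), [1.0, 2.0, 3.0])

    def test_phase_out_of_range(self):
        ms = track_markers([np.zeros((3, 3))], reference_index=0)
        with pytest.raises(IndexError):
            markers_com(ms, 5)


class TestOnPhantomSeries:
    def test_com_error_not_worse_than_worst_marker(self, series, truth):
        ms = detect_and_track(series.volumes, series.reference_index)
        err = np.linalg.norm(
            ms.centroids_mm - truth.marker_trajectories_mm, axis=-1
        )  # (phases, markers)
        com_err = np.linalg.norm(
            ms.com_trajectory() - truth.marker_trajectories_mm.mean(axis=1), axis=-1
        )
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert rms(com_err) <= max(rms(err[:, m]) for m in range(err.shape[1]))

    def test_centroid_accuracy_on_series(self, series, truth):
        # detection order is scan order, not the generator's marker
        # order: align identities at the reference phase first
        ms = detect_and_track(series.volumes, series.reference_index)
        ref = series.reference_index
        cost = np.linalg.norm(
            truth.marker_trajectories_mm[ref][:, None]
            - ms.centroids_mm[ref][None],
            axis=-1,
        )
        perm = np.argmin(cost, axis=1)
        assert len(set(perm)) == ms.n_markers
        err = np.abs(ms.centroids_mm[:, perm] - truth.marker_trajectories_mm)
        assert err.max() < 0.5 * 2.0  # half the largest voxel dimension
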