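"""Distance metrics, KS statistics, and report arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from liverdir.fields import transform_points
from liverdir.grid import DisplacementField, ImageVolume
from liverdir.metrics import (
    displacement_3d,
    error_table,
    ks_two_sample,
    peak_to_peak_displacement,
    registration_error,
    relative_distance,
    round_half_away,
    summarize_errors,
)

from oracles import ecdf_ks_statistic, permutation_ks_pvalue


def _translation_field(vec, shape=(12, 12, 10), spacing=(1, 1, 2)):
    vol = ImageVolume(np.zeros(shape), spacing)
    f = DisplacementField.zeros_like(vol, from_phase="ref", to_phase="j")
    f.data[...] = vec
    return f


class TestRegistrationError:
    def test_identity_zero(self):
        f = _translation_field([0.0, 0.0, 0.0])
        p = np.array([3.0, 3.0, 3.0])
        assert registration_error(p, p, f) == pytest.approx(0.0)

    def test_hand_worked_translation(self):
        # marker measured at (0,0,10), transform carries the reference
        # marker (0,0,0) to (0,0,8): error is 2 mm
        f = _translation_field([0.0, 0.0, 8.0])
        err = registration_error(
            np.array([0.0, 0.0, 10.0]), np.array([0.0, 0.0, 0.0]), f
        )
        assert err == pytest.approx(2.0)

    def test_true_map_gives_zero_on_phantom(self, truth):
        # the analytic map is its own gold standard
        ref = len(truth.fields_ref_to_phase) // 2
        for j, fld in enumerate(truth.fields_ref_to_phase):
            errs = registration_error(
                truth.marker_trajectories_mm[j],
                truth.marker_trajectories_mm[fld.from_phase],
                fld,
            )
            assert np.max(errs) < 1e-6


class TestRelativeDistance:
    def test_rigid_translation_zero(self, rng):
        pts = rng.normal(size=(4, 3))
        t = np.array([2.0, -1.0, 5.0])
        for i in range(3):
            d = relative_distance(pts[i] + t, pts[i + 1] + t, pts[i], pts[i + 1])
            assert d == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_example(self):
        d = relative_distance(
            [0, 0, 0], [13.0, 0, 0], [0, 0, 0], [12.0, 0, 0]
        )
        assert d == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=9, max_size=9))
    def test_invariant_under_shared_translation(self, vals):
        p1 = np.array(vals[0:3])
        p2 = np.array(vals[3:6])
        t = np.array(vals[6:9])
        d = relative_distance(p1 + t, p2 + t, p1, p2)
        assert abs(d) < 1e-9 * max(1.0, np.abs(vals).max())


class TestDisplacement3D:
    @pytest.mark.parametrize(
        "lr, ap, si, printed",
        [(1.2, 1.3, 5.1, 5.4), (2.5, 3.3, 12.6, 13.3), (0.0, 0.0, 0.0, 0.0)],
    )
    def test_published_cohort_rows(self, lr, ap, si, printed):
        assert round_half_away(displacement_3d(lr, ap, si)) == pytest.approx(printed)

    def test_peak_to_peak_of_trajectory(self):
        traj = np.array([[0, 0, 0], [1.2, 0.4, 5.1], [0.6, 1.3, 2.0], [0, 0, 0.0]])
        d = peak_to_peak_displacement(traj)
        assert d["LR"] == pytest.approx(1.2)
        assert d["AP"] == pytest.approx(1.3)
        assert d["SI"] == pytest.approx(5.1)
        assert d["3D"] == pytest.approx(displacement_3d(1.2, 1.3, 5.1))

    def test_extreme_phase_convention(self):
        from liverdir.metrics import extreme_phase_displacement

        traj = np.array([[0, 0, 0], [1.2, 0.4, 5.1], [0.6, 1.3, 2.0], [0, 0, 0.0]])
        d = extreme_phase_displacement(traj, 0, 1)
        assert d["3D"] == pytest.approx(displacement_3d(1.2, 0.4, 5.1))


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d, p = ks_two_sample(x, x)
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0, 1, 2, 3], [10, 11, 12, 13])
        assert d == pytest.approx(1.0)

    def test_statistic_matches_ecdf_sweep(self, rng):
        for _ in range(5):
            x = rng.normal(size=20)
            y = rng.normal(0.3, 1.2, size=20)
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(ecdf_ks_statistic(x, y), abs=1e-12)

    def test_pvalue_near_permutation_estimate(self, rng):
        # the asymptotic Kolmogorov p-value approaches the exact
        # permutation distribution as the samples grow
        x = rng.normal(size=80)
        y = rng.normal(0.3, 1.0, size=80)
        _, p = ks_two_sample(x, y)
        p_perm = permutation_ks_pvalue(x, y, n_perm=3000, seed=1)
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestTables:
    def test_summary_matches_row_level_recomputation(self, rng):
        rows = [
            {
                "strategy": s,
                "phase_index": p,
                "marker_id": m,
                "r_error_mm": float(rng.uniform(0, 3)),
            }
            for s in ("reference", "sequential")
            for p in range(4)
            for m in range(3)
        ]
        df = error_table(rows)
        summary = summarize_errors(df)
        for _, row in summary.iterrows():
            sub = df[
                (df.strategy == row.strategy) & (df.phase_index == row.phase_index)
            ]["r_error_mm"]
            assert row["mean"] == pytest.approx(sub.mean())
            assert row["median"] == pytest.approx(sub.median())
            assert row["sd"] == pytest.approx(sub.std())
            assert row["max"] == pytest.approx(sub.max())

    def test_negative_error_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            error_table(
                [
                    {
                        "strategy": "reference",
                        "phase_index": 0,
                        "marker_id": 0,
                        "r_error_mm": -1.0,
                    }
                ]
            )


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(1.25, 1.3), (-1.25, -1.3), (1.24, 1.2), (0.05, 0.1), (-0.05, -0.1)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == pytest.approx(expected)
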