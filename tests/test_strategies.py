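"""Reference vs sequential strategy plumbing and cyclic path logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liverdir.phantom import generate_series
from liverdir.registration import RegistrationParams
from liverdir.strategies import (
    link_fields,
    make_cache,
    propagation_path,
    reference_registration,
    sequential_registration,
)

from conftest import small_spec


class TestPropagationPath:
    def test_source_equals_target(self):
        assert propagation_path(3, 3, 10) == []

    def test_two_steps_forward(self):
        assert propagation_path(5, 7, 10) == [(5, 6), (6, 7)]

    def test_wraparound_shorter(self):
        assert propagation_path(9, 1, 10) == [(9, 0), (0, 1)]

    def test_backward_path(self):
        assert propagation_path(5, 3, 10) == [(5, 4), (4, 3)]

    def test_diametric_tie_breaks_forward(self):
        # 50% -> 0% in 10 phases: both directions need 5 links; the tie
        # goes toward increasing phase index (via 60...90)
        path = propagation_path(5, 0, 10)
        assert path == [(5, 6), (6, 7), (7, 8), (8, 9), (9, 0)]

    def test_non_cyclic_chain(self):
        assert propagation_path(0, 3, 10, cyclic=False) == [(0, 1), (1, 2), (2, 3)]

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            propagation_path(0, 10, 10)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 11), st.integers(0, 11))
    def test_path_properties(self, n, s, t):
        s, t = s % n, t % n
        path = propagation_path(s, t, n)
        assert len(path) <= n // 2 + (n % 2 == 0)  # never longer than half the cycle
        if path:
            assert path[0][0] == s and path[-1][1] == t
            for (a, b), (c, _) in zip(path, path[1:]):
                assert b == c
            for a, b in path:
                assert (b - a) % n in (1, n - 1)  # adjacent links only


@pytest.fixture(scope="module")
def static_series():
    """Zero-amplitude series: every registration converges immediately."""
    spec = small_spec(amplitude_mm=(0.0, 0.0, 0.0), n_phases=4, noise_sigma_hu=0.0)
    series, _ = generate_series(spec)
    return series


@pytest.fixture(scope="module")
def light_params():
    return RegistrationParams(iterations=(5, 5, 5))


class TestReferenceStrategy:
    def test_registration_count_and_identity(self, static_series, light_params):
        results = reference_registration(static_series, light_params)
        assert set(results) == {0, 1, 2, 3}
        ref = static_series.reference_index
        assert np.allclose(results[ref].phi_ab.data, 0.0)

    def test_identity_series_fields_tiny(self, static_series, light_params):
        results = reference_registration(static_series, light_params)
        for j, r in results.items():
            assert r.phi_ab.magnitude_voxels().max() < 0.1

    def test_bad_reference_index(self, static_series, light_params):
        with pytest.raises(IndexError):
            reference_registration(static_series, light_params, ref_index=9)


class TestSequentialStrategy:
    def test_cyclic_pairs_and_composition_counts(self, static_series, light_params):
        pairs, composed, counts = sequential_registration(
            static_series, light_params
        )
        n = static_series.n_phases
        assert set(pairs) == {(k, (k + 1) % n) for k in range(n)}
        ref = static_series.reference_index
        assert counts[ref] == 0
        assert max(counts.values()) == n // 2
        assert set(composed) == set(range(n))

    def test_adjacent_phase_equals_pairwise_field(self, static_series, light_params):
        pairs, composed, _ = sequential_registration(static_series, light_params)
        ref = static_series.reference_index
        nxt = (ref + 1) % static_series.n_phases
        assert np.array_equal(composed[nxt].data, pairs[(ref, nxt)].phi_ab.data)

    def test_identity_series_composed_fields_tiny(self, static_series, light_params):
        _, composed, _ = sequential_registration(static_series, light_params)
        for fld in composed.values():
            assert np.linalg.norm(fld.data, axis=-1).max() < 0.2  # mm

    def test_link_fields_has_both_directions(self, static_series, light_params):
        pairs, _, _ = sequential_registration(static_series, light_params)
        links = link_fields(pairs)
        for (a, b) in pairs:
            assert (a, b) in links and (b, a) in links


class TestPointHopVsComposedField:
    def test_routes_agree_on_smooth_fields(self, rng):
        """Carrying marker points link-by-link equals transforming them
        once through the composed field (up to interpolation)."""
        from liverdir.fields import compose_fields, transform_points
        from liverdir.grid import DisplacementField, ImageVolume, index_grid_mm
        from liverdir.strategies import transform_points_via_links

        shape, spacing = (24, 24, 20), np.array([1.0, 1.0, 2.0])
        pts_grid = index_grid_mm(shape, spacing, np.zeros(3))

        def smooth_field(phase_a, phase_b, k):
            u = 1.5 * np.stack(
                [
                    np.sin(2 * np.pi * pts_grid[..., (c + k) % 3] / 40.0)
                    for c in range(3)
                ],
                axis=-1,
            )
            return DisplacementField(u, spacing, np.zeros(3), phase_a, phase_b)

        links = {(0, 1): smooth_field(0, 1, 0), (1, 2): smooth_field(1, 2, 1)}
        path = [(0, 1), (1, 2)]
        composed = compose_fields(links[(0, 1)], links[(1, 2)])
        pts = rng.uniform(6, 14, size=(10, 3)) * [1, 1, 2]
        via_links = transform_points_via_links(pts, links, path)
        via_composed = transform_points(pts, composed)
        assert np.abs(via_links - via_composed).max() < 0.05


class TestCache:
    def test_pairs_shared_between_strategies(self, static_series, light_params):
        cache = make_cache(light_params)
        sequential_registration(static_series, light_params, cache=cache)
        n_before = len(cache.mem)
        reference_registration(static_series, light_params, cache=cache)
        # reference needs (ref, j): (ref, ref+1) is reused as stored,
        # (ref-1, ref) is reused flipped, only the diametric pair is new
        new = len(cache.mem) - n_before
        assert new == 2

    def test_disk_cache_roundtrip(self, static_series, light_params, tmp_path):
        cache = make_cache(light_params, cache_dir=tmp_path)
        r1 = cache.get(static_series, 0, 1)
        cache2 = make_cache(light_params, cache_dir=tmp_path)
        r2 = cache2.get(static_series, 0, 1)
        assert np.allclose(r1.phi_ab.data, r2.phi_ab.data)
        assert len(list(tmp_path.glob("*.nii.gz"))) == 2
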