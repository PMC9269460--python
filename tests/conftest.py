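import numpy as np
import pytest

from liverdir.phantom import PhantomSpec, generate_series


def small_spec(**overrides) -> PhantomSpec:
    """A desk-scale phantom used throughout the unit tests."""
    kwargs = dict(
        grid_shape=(48, 48, 32),
        spacing_mm=(1.0, 1.0, 2.0),
        liver_center_mm=(24.0, 24.0, 32.0),
        liver_axes_mm=(18.0, 16.0, 22.0),
        tumor_center_mm=(26.0, 24.0, 34.0),
        tumor_radius_mm=5.0,
        marker_positions_mm=((20.0, 20.0, 28.0), (30.0, 28.0, 32.0), (25.0, 29.0, 40.0)),
        amplitude_mm=(1.0, 1.2, 5.0),
        n_phases=4,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def spec():
    return small_spec()


@pytest.fixture(scope="session")
def series_and_truth(spec):
    return generate_series(spec)


@pytest.fixture(scope="session")
def series(series_and_truth):
    return series_and_truth[0]


@pytest.fixture(scope="session")
def truth(series_and_truth):
    return series_and_truth[1]


@pytest.fixture(scope="session")
def registered_pair(series):
    """Reference↔0% registration of the small phantom (shared: it is the
    most expensive fixture in the unit suite)."""
    from liverdir.registration import RegistrationParams, register_pair

    ref = series.reference_index
    params = RegistrationParams(iterations=(100, 80, 40))
    return register_pair(
        series.volumes[ref], series.volumes[0], params, tag_a=ref, tag_b=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
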