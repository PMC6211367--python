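import numpy as np
import pytest

from leafmorph.canvas import GeometryParams, build_initial_canvas, build_rectangle_canvas


COARSE = dict(n_across=14, n_along=25)


@pytest.fixture(scope="session")
def default_canvas():
    return build_initial_canvas()


@pytest.fixture()
def coarse_geometry():
    return GeometryParams(**COARSE)


@pytest.fixture()
def rect_canvas():
    return build_rectangle_canvas(100.0, 200.0, n_across=10, n_along=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def coarse_config(variant, seed=1, **kw):
    """Scaled-down simulation config shared by the slower preset tests."""
    from leafmorph.factors import ModelVariant
    from leafmorph.presets import SimulationConfig

    return SimulationConfig(
        variant=ModelVariant(variant) if isinstance(variant, str) else variant,
        seed=seed,
        geometry=GeometryParams(**COARSE),
        mean_initial_cell_area=110.0,
        **kw,
    )
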