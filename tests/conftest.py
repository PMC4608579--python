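import numpy as np
import pytest

import rosettepiv as rp
from rosettepiv.pipeline import analyze_rosette


def small_config(preset: str, seed: int, **overrides) -> rp.SimulationConfig:
    """A compact rosette configuration used throughout the suite."""
    kwargs = dict(n_frames=25, rosette_radius_px=45.0, image_size_px=160,
                  center_px=(80.0, 80.0), lumen_radius_px=10.0, n_nuclei=200)
    kwargs.update(overrides)
    return rp.perturbation_preset(preset, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def erg_movie():
    return rp.generate_rosette_movie(small_config("e_rg", seed=7))


@pytest.fixture(scope="session")
def erg_result(erg_movie):
    stack, annotation, _ = erg_movie
    return analyze_rosette(stack, annotation)


@pytest.fixture()
def textured_frame():
    rng = np.random.default_rng(0)
    return rng.integers(0, 256, size=(64, 64)).astype(float)
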