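import numpy as np
import pytest

import laminafluct as lf


@pytest.fixture(scope="session")
def noiseless_uniform():
    """A clean nucleus whose test channel equals the reference pattern."""
    spec = lf.uniform_spec(noise=lf.NoiseModel.none(), seed=0)
    stack, truth = lf.generate_nucleus_image(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noiseless_punctate_spaced():
    """A clean, strongly punctate nucleus with equally spaced foci."""
    spec = lf.punctate_spec(
        noise=lf.NoiseModel.none(), focus_placement="spaced", n_foci=4,
        baseline_fraction=0.3, orientation=0.0, seed=0,
    )
    stack, truth = lf.generate_nucleus_image(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def default_noise_uniform():
    spec = lf.uniform_spec(seed=1)
    stack, truth = lf.generate_nucleus_image(spec)
    return spec, stack, truth
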