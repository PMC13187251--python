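import numpy as np
import pytest

from histostack import (
    PhantomSpec,
    build_processed_stack,
    generate_phantom,
    make_phantom_stack,
)
from histostack.synthetic import slice_volume


@pytest.fixture(scope="session")
def case0():
    """Default phantom case (seed 0): perturbed stack, ground truth, spec."""
    return make_phantom_stack(seed=0)


@pytest.fixture(scope="session")
def processed0(case0):
    stack, _, _ = case0
    return build_processed_stack(stack)


@pytest.fixture(scope="session")
def base_phantom():
    """One unperturbed phantom volume shared across perturbation-seed sweeps."""
    spec = PhantomSpec(seed=0)
    volume, fiducials = generate_phantom(spec)
    stack, gt = slice_volume(volume, spec, fiducials)
    return spec, volume, fiducials, stack, gt


@pytest.fixture(scope="session")
def phantom_cases():
    """Twenty default phantom cases with planted 0-360° rotations."""
    return [make_phantom_stack(seed=seed) for seed in range(20)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
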