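import numpy as np
import pytest

from sparsedce.phantom import PhantomSpec, make_phantom, run_pipeline


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Zero-noise phantom + pipeline output (shared; generation is cheap
    but the voxelwise fit is the slow part)."""
    spec = PhantomSpec(
        map_noise_sd=0.0, dynamic_noise_sd=0.0, pre_noise_sd=0.0, seed=11
    )
    ds = make_phantom(spec)
    ki, vp, plasma = run_pipeline(ds)
    return ds, ki, vp, plasma


@pytest.fixture(scope="session")
def default_phantom():
    """Default-noise phantom at the full 32^3 grid (>= 1000 voxels/class)."""
    ds = make_phantom(PhantomSpec(seed=7))
    ki, vp, plasma = run_pipeline(ds)
    return ds, ki, vp, plasma


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
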