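import numpy as np
import pytest

import mtlmorph as m


@pytest.fixture(scope="session")
def tiny_slab_spec():
    """Noiseless axis-aligned slab: 5 mm cortex, one MTL blob, no jitter."""
    return m.PhantomSpec(
        shape=(24, 24, 24),
        cortex=m.SlabCortex(axis=2, start_mm=10.0, thickness_mm=5.0),
        mtl_blobs=(m.Blob((12.0, 12.0, 12.5), (6.0, 6.0, 6.0)),),
        noise_sd=0.0,
        thickness_jitter_sd_mm=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study():
    """A reduced end-to-end phantom study shared by module-level tests."""
    return m.run_phantom_study(
        seed=5,
        shape=(40, 40, 40),
        n_per_group={"AD": 5, "MCI": 5, "NC": 6, "NCDB": 8},
    )


@pytest.fixture(scope="session")
def full_study():
    """The full study conditions: 64^3 grid, graded AD > MCI > NC effects,
    paper-sized groups (15 AD, 23 MCI, 26 NC, 25 NCDB controls)."""
    return m.run_phantom_study(seed=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
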