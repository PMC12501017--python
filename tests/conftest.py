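import numpy as np
import pytest

from octavasc import generate_phantom, run_pipeline
from octavasc.phantom import PhantomSpec, default_study_spec, parallel_tube_spec


@pytest.fixture(scope="session")
def iso_phantom():
    """Four parallel tubes (20/30/50/80 um) on a 5 um isotropic grid."""
    spec = parallel_tube_spec((20.0, 30.0, 50.0, 80.0), noise_seed=7)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def iso_result(iso_phantom):
    _, volume, _ = iso_phantom
    return run_pipeline(volume)


@pytest.fixture(scope="session")
def resolution_phantom():
    """Tubes of 10/20/40 um diameter bracketing the 15 um resolution floor."""
    spec = parallel_tube_spec((10.0, 20.0, 40.0), noise_seed=11)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def resolution_result(resolution_phantom):
    _, volume, _ = resolution_phantom
    return run_pipeline(volume)


@pytest.fixture(scope="session")
def default_phantom():
    """The default anisotropic (8, 4, 4) um study phantom."""
    spec = default_study_spec(noise_seed=5)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def default_result(default_phantom):
    _, volume, _ = default_phantom
    return run_pipeline(volume)


@pytest.fixture(scope="session")
def empty_phantom():
    """A phantom with no tubes: static speckle only."""
    spec = PhantomSpec(grid_shape=(16, 32, 32), voxel_size=(5.0, 5.0, 5.0),
                       n_frames=8, tubes=[], noise_seed=3)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth
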