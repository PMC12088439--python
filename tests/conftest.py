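import numpy as np
import pytest

from catm.orientation import euler_to_rotation
from catm.simulate import ImagingModel, degrade
from catm.templates import (build_dna_template, build_nucleosome_template,
                            build_steric_mask, rotate_volume)
from catm.volume import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def nuc_template():
    return build_nucleosome_template(voxel_size=1.0)


@pytest.fixture(scope="session")
def dna_template():
    return build_dna_template(voxel_size=1.0)


@pytest.fixture(scope="session")
def nuc_mask(nuc_template):
    return build_steric_mask(nuc_template, 0.5)


@pytest.fixture(scope="session")
def imaging():
    """Noise-free imaging model (wedge + CTF only)."""
    return ImagingModel(snr=np.inf)


@pytest.fixture(scope="session")
def single_particle_scene(nuc_template, imaging):
    """One clean degraded nucleosome at a known pose in a 48^3 box.

    Returns (volume, position_nm (x,y,z), rotation).
    """
    rot = euler_to_rotation(25.0, 40.0, 0.0)
    rt = rotate_volume(nuc_template, rot)
    box = np.zeros((48, 48, 48), dtype=np.float32)
    box[15:32, 14:31, 16:33] = rt.data  # center voxel (z,y,x) = (23, 22, 24)
    vol = degrade(Volume(box, 1.0), imaging)
    return vol, np.array([24.0, 22.0, 23.0]), rot
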