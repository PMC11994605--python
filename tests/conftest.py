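import numpy as np
import pytest

from scapstab.landmarks import template_configuration
from scapstab.synthgen import BoneParams, generate_bone_geometry


@pytest.fixture(scope="session")
def template_cfg():
    return template_configuration()


@pytest.fixture(scope="session")
def default_bones():
    return generate_bone_geometry(BoneParams())


@pytest.fixture(scope="session")
def anteverted_bones():
    return generate_bone_geometry(BoneParams(version_deg=6.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
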