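import numpy as np
import pytest

from protmod import fixtures
from protmod.backbone import backbone_from_torsions
from protmod.sidechain import load_mini_library


@pytest.fixture(scope="session")
def mini_lib():
    return load_mini_library()


@pytest.fixture(scope="session")
def helix10():
    return fixtures.make_ideal_helix(10)


@pytest.fixture(scope="session")
def toy_protein(mini_lib):
    return fixtures.make_toy_protein(20, seed=1, lib=mini_lib)


@pytest.fixture(scope="session")
def hlh24():
    return fixtures.helix_loop_helix(24, seed=3)


@pytest.fixture(scope="session")
def slack_coil_template():
    """Helix–coil–helix with a compressible linker (used by the deletion
    tests; the coil has enough slack to absorb a one-residue deletion)."""
    phi = [-57.0] * 8 + [-70, -90, -70, -100, -80, -70, -90, -80] + [-57.0] * 8
    psi = [-47.0] * 8 + [-20, 0, -30, 20, -10, -25, 10, -15] + [-47.0] * 8
    return backbone_from_torsions("A" * 24, np.deg2rad(phi), np.deg2rad(psi))
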