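import numpy as np
import pytest

from twobead import Frame, build_topology, chain_template, default_forcefield


@pytest.fixture(scope="session")
def ff():
    """Mid-range scan parameters: sigma_SS = 0.41 nm, r0_BS = 0.55 nm."""
    return default_forcefield(0.41, 0.55)


@pytest.fixture(scope="session")
def r8_topology():
    return build_topology(8, 1)


@pytest.fixture()
def r8_frame(ff):
    """Single straight R8 chain at the bonded-energy minimum."""
    return Frame(chain_template(8, ff) + 10.0, box=35.0)


@pytest.fixture()
def perturbed_r8(r8_frame):
    rng = np.random.default_rng(42)
    out = r8_frame.copy()
    out.positions = out.positions + rng.normal(scale=0.03, size=out.positions.shape)
    return out
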