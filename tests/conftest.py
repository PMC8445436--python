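import pytest

from vistrain import observer_sim as obs
from vistrain import visual_field as vf


@pytest.fixture(scope="session")
def blind_spot_field():
    """Right-eye field with the default anatomical blind spot, 0.75 deg grid."""
    return vf.make_field([vf.default_blind_spot()], pitch=0.75, extent=20.0)


@pytest.fixture(scope="session")
def hemianopia_field():
    """Right half-field defect (boundary at fixation), 1 deg grid."""
    return vf.make_field([vf.halfplane(0.0, "right")], pitch=1.0, extent=10.0)


@pytest.fixture()
def ideal_observer(blind_spot_field):
    return obs.SimulatedObserver(obs.ObserverParams(), blind_spot_field)
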