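import numpy as np
import pytest

from billmech import fem, geometry as geo


@pytest.fixture(scope="session")
def default_spec():
    return geo.BillSpec()


@pytest.fixture(scope="session")
def coarse_bill(default_spec):
    """Default bill at a coarse test resolution, tagged."""
    return geo.make_bill_mesh(default_spec, n_axial=12, n_circumferential=8)


@pytest.fixture(scope="session")
def composite():
    return fem.material_assignment("composite")


@pytest.fixture(scope="session")
def all_keratin():
    return fem.material_assignment("all_keratin")


@pytest.fixture(scope="session")
def prism_uniaxial():
    """0.01 x 0.01 x 0.05 m prism with node sets, for statically determinate oracles."""
    return geo.make_prism_mesh(0.01, 0.01, 0.05, 4, 4, 21)


def rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
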