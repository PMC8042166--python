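import numpy as np
import pytest

from protofil.surface import SasaParams
from protofil.synth import SubunitTemplate, TrajectorySpec, build_filament


@pytest.fixture(scope="session")
def trimer():
    """Default straight trimer (structure, model)."""
    return build_filament(SubunitTemplate(), 3)


@pytest.fixture(scope="session")
def sasa_params():
    """SASA config matching the synthetic bead radius."""
    return SasaParams(uniform_radius=SubunitTemplate().bead_radius)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_spec(**kw) -> TrajectorySpec:
    defaults = dict(mode="GTP", n_frames=40, seed=7)
    defaults.update(kw)
    return TrajectorySpec(**defaults)
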