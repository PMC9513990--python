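import numpy as np
import pytest

from ulbench.kinematics import ArmGeometry
from ulbench.protocol import build_target_layout
from ulbench.synthetic import ImpairmentParams, synth_trial


@pytest.fixture(scope="session")
def geom():
    return ArmGeometry(0.30, 0.25)


@pytest.fixture(scope="session")
def layout(geom):
    return build_target_layout(geom, 0.30, "rest_height")


@pytest.fixture(scope="session")
def clean_trial(geom, layout):
    """Zero-impairment anterior reaching trial (shared, read-only)."""
    trial, truth = synth_trial("anterior_reaching_rest_height", layout, geom,
                               ImpairmentParams(seed=11))
    return trial, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
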