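import numpy as np
import pytest

from magscan import (
    ContextResponse,
    ScanningParams,
    annotate,
    build_construct,
    make_leader_fixture,
)
from magscan.simulate import CONSTRUCT_PRESETS, GEOMETRY_PRESETS


@pytest.fixture(scope="session")
def trpm7_leader():
    return make_leader_fixture(GEOMETRY_PRESETS["trpm7-mouse-like"], seed=11)


@pytest.fixture(scope="session")
def trpm7_annotation(trpm7_leader):
    return annotate(trpm7_leader)


@pytest.fixture(scope="session")
def constructs():
    return {name: build_construct(name) for name in CONSTRUCT_PRESETS}


@pytest.fixture(scope="session")
def simple_params():
    """Hand-set parameters with easily checked probabilities."""
    return ScanningParams(
        loading_amp=100.0,
        loading_center=(0.8, 1.0 / 300.0),
        loading_width=0.25,
        contexts={
            "strong": ContextResponse(0.5, 0.5, 0.8, 1.0),
            "adequate": ContextResponse(0.05, 0.95, 0.8, 0.1),
            "weak": ContextResponse(0.02, 0.5, 1.0, 0.15),
        },
        reinit_prob=0.2,
    )


@pytest.fixture(scope="session")
def paper_params():
    from magscan import load_params_preset

    return load_params_preset("paper2014")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
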