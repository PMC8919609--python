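import numpy as np
import pytest

from echospace.localize import analyze_pulse
from echospace.scene import EarGeometry
from echospace.synthetic import (
    geometric_echo_oracle,
    one_plate_fixture,
    scaled_localize_config,
)


@pytest.fixture(scope="session")
def one_plate_run():
    """Full simulate/detect/localize chain on the one-plate desk fixture.

    Expensive (a few FDTD runs), so computed once per session and shared
    by every test that checks the chain against the geometric oracle.
    """
    scene, pulse = one_plate_fixture()
    ears = EarGeometry(pulse)
    oracle = geometric_echo_oracle(scene, pulse, ears)
    config = scaled_localize_config()
    out = analyze_pulse(scene, pulse, config)
    return {
        "scene": scene,
        "pulse": pulse,
        "ears": ears,
        "oracle": oracle,
        "config": config,
        **out,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
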