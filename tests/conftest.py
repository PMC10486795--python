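import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from perirad.phantom import PhantomConfig, make_phantom
from perirad.voi import ImageVolume, make_margin


@pytest.fixture(scope="session")
def textured_phantom():
    """A medium lesion phantom with texture and noise, plus its VoiPair."""
    cfg = PhantomConfig(seed=7)
    volume, tumor = make_phantom(cfg)
    pair = make_margin(tumor, volume)
    return volume, pair


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def constant_volume(shape=(6, 6, 6), value=80.0, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.full(shape, float(value)), spacing)
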