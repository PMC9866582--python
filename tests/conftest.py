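import numpy as np
import pytest

from pulsekit.synth import NoiseSpec, draw_params
from pulsekit.waveform import PulseParams


@pytest.fixture
def normal_params() -> PulseParams:
    """A representative normal-pulse parameter set."""
    return PulseParams(Ym=100.0, Ym1=9.0, Ym2=8.0, T=1.0, ts=0.15, b=0.27,
                       ts1=0.37, T1=0.49, ts2=0.59, c=0.35)


@pytest.fixture
def slippery_params() -> PulseParams:
    """A representative slippery-pulse parameter set (no dicrotic wave)."""
    return PulseParams(Ym=100.0, Ym1=9.0, Ym2=0.0, T=1.0, ts=0.21, b=0.33,
                       ts1=0.43, T1=0.55, ts2=0.75, c=0.35)


@pytest.fixture
def default_noise() -> NoiseSpec:
    return NoiseSpec()


def random_params(seed: int, label: str = "normal") -> PulseParams:
    return draw_params(label, np.random.default_rng(seed))
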