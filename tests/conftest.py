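import numpy as np
import pytest

from scstim import (
    ControlConfig,
    EncodingConfig,
    NoiseConfig,
    ObjectSpec,
    get_preset,
    simulate_session,
)
from scstim.config import config_for_preset


@pytest.fixture
def medium_sphere():
    return ObjectSpec("sphere", "M", "medium", 45.0, 0.15)


def simulate_preset(name: str, seed: int):
    """Simulate one full session of a built-in preset at its default
    study conditions."""
    cfg = config_for_preset(name, seed)
    preset = get_preset(name)
    schedule = preset.schedule(seed)
    return simulate_session(
        schedule,
        cfg.control.to_dataclass(),
        cfg.noise.to_dataclass(),
        cfg.encoding.to_dataclass(),
        master_seed=seed,
    )


def tone_gain(filter_fn, freq: float, fs: float = 50.0, duration: float = 8.0) -> float:
    """Steady-state amplitude gain of a causal filter on a pure tone,
    measured by quadrature demodulation over the last 2 s."""
    t = np.arange(int(duration * fs)) / fs
    y = filter_fn(np.sin(2 * np.pi * freq * t))
    n_tail = int(2.0 * fs)
    tt = t[-n_tail:]
    yy = y[-n_tail:]
    z = yy * np.exp(-2j * np.pi * freq * tt)
    return 2.0 * abs(z.mean())
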