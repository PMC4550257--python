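import numpy as np
import pytest

from catransient import ParameterSet, Signal


@pytest.fixture
def rs1():
    return ParameterSet.preset("rs1")


@pytest.fixture
def rs2():
    return ParameterSet.preset("rs2")


@pytest.fixture
def rng():
    return np.random.default_rng(20150826)


def make_signal(y, fs=10.0, id="test"):
    """Build a Signal from raw values, padding to the 8-sample minimum."""
    y = list(y)
    while len(y) < 8:
        y.append(y[-1])
    return Signal.from_values(id, np.asarray(y, dtype=float), fs)


def random_trace(rng, n, kind=None):
    """A random test trace: random walk, noisy sine, or pulse train."""
    kind = kind if kind is not None else rng.integers(0, 3)
    x = np.arange(n)
    if kind == 0:
        return np.cumsum(rng.normal(0.0, 1.0, n))
    if kind == 1:
        return np.sin(2 * np.pi * x / rng.uniform(5, 50)) + rng.normal(0, 0.3, n)
    base = np.abs(np.sin(2 * np.pi * x / rng.uniform(10, 40))) ** 3
    return base + rng.normal(0, 0.05, n)
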