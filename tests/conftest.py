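import numpy as np
import pytest

from hrvstream import PreprocessConfig, SpectralConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def pre_config():
    return PreprocessConfig()


@pytest.fixture
def spec_config():
    return SpectralConfig()


# ---------------------------------------------------------------------------
# Independent brute-force oracles, shared across test modules.  Plain loops
# on purpose: no numpy vectorization, no code shared with the implementation.


def oracle_rmssd(x):
    n = len(x)
    acc = 0.0
    for i in range(n - 1):
        d = x[i + 1] - x[i]
        acc += d * d
    return (acc / (n - 1)) ** 0.5


def oracle_sdnn(x):
    n = len(x)
    m = sum(x) / n
    acc = 0.0
    for v in x:
        acc += (v - m) ** 2
    return (acc / (n - 1)) ** 0.5


def oracle_pnn50(x):
    n = len(x)
    count = 0
    for i in range(n - 1):
        if abs(x[i + 1] - x[i]) > 50.0:
            count += 1
    return 100.0 * count / (n - 1)


def oracle_percentile(x, q):
    """Linear-interpolation percentile, written from the definition."""
    s = sorted(x)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * q / 100.0
    lo = int(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def oracle_trapezoid(y, x):
    acc = 0.0
    for i in range(len(x) - 1):
        acc += 0.5 * (y[i] + y[i + 1]) * (x[i + 1] - x[i])
    return acc
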