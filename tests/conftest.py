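import numpy as np
import pytest

from polyethism import EnvironmentParams, RunConfig


@pytest.fixture
def env10():
    """Default abundant environment: b=20, r=1, age-symmetric costs, games of 10."""
    return EnvironmentParams(b=20.0, r=1.0, beta=0.0, n=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_config(model="srt", b=20.0, beta=0.0, alpha=0.5, T=200, N=100, seed=1, **extra):
    data = {
        "environment": {"b": b, "beta": beta},
        "learning": {"alpha": alpha},
        "run": {"model": model, "T": T, "N": N},
        "seed": seed,
    }
    for block, kw in extra.items():
        data.setdefault(block, {}).update(kw)
    return RunConfig.from_dict(data)
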