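"""Shared fixtures and hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_panel_csv(tmp_path):
    """3-person, 9-item, 2-wave ordinal CSV in the default wide layout."""
    header = ["id"] + [f"pg{i}_w{w}" for w in (1, 2) for i in range(1, 10)]
    rows = [
        [1] + [0] * 9 + [0] * 9,
        [2] + [1, 0, 2, 0, 0, 0, 0, 0, 0] + [0, 1, 0, 0, 0, 0, 0, 0, 0],
        [3] + [3] * 9 + [2] * 9,
    ]
    path = tmp_path / "toy.csv"
    lines = [",".join(header)] + [",".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def random_small_weights(rng, p, density=0.5, signed=True):
    """Random symmetric zero-diagonal weight matrix for oracle tests."""
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                w = rng.uniform(0.2, 2.0)
                if signed and rng.random() < 0.4:
                    w = -w
                W[i, j] = W[j, i] = w
    return W
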