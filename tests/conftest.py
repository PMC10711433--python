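import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance, used as an oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def tiny_run():
    """A small but complete simulated selection: 3 rounds, planted family."""
    from selexg4.simulate import g2_study_config, run_selex

    config = g2_study_config(
        seed=7, pool_size=4000, reads_per_round=4000, rounds=3
    )
    return run_selex(config)
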