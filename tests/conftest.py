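import dataclasses

import numpy as np
import pytest

from ahpgroup import datasets, synthetic_data


def scenario(groups, *, seed, sigma, discretize):
    """Default reference scenario restricted to the given (group, n) pairs."""
    cfg = synthetic_data.default_config(seed=seed, noise_sigma=sigma,
                                        discretize=discretize)
    return dataclasses.replace(cfg, groups=tuple(groups))


@pytest.fixture(scope="session")
def hierarchy():
    return datasets.hospital_it_hierarchy()


@pytest.fixture(scope="session")
def small_study():
    """A small noisy discretized study: two groups, quick to derive."""
    cfg = scenario([("patients", 8), ("policy makers", 6)],
                   seed=42, sigma=0.3, discretize=True)
    return synthetic_data.simulate_study(cfg)


@pytest.fixture(scope="session")
def noise_free_study():
    """Zero-noise, non-discretized study: every respondent states the truth."""
    cfg = scenario([("patients", 3), ("nurses", 2), ("policy makers", 2)],
                   seed=0, sigma=0.0, discretize=False)
    return synthetic_data.simulate_study(cfg)


def random_reciprocal(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random reciprocal matrix with upper entries from the 1-9 scale."""
    scale = np.concatenate([1.0 / np.arange(2, 10), np.arange(1, 10)])
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = rng.choice(scale)
            a[j, i] = 1.0 / a[i, j]
    return a
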