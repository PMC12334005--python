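import numpy as np
import pytest

from apcbayes import APCGrid, EffectSet, SamplerConfig, centered_index


@pytest.fixture(scope="session")
def grid10() -> APCGrid:
    return APCGrid(10, 10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250920)


def random_effectset(rng: np.random.Generator, grid: APCGrid, scale: float = 0.5) -> EffectSet:
    """A random sum-to-zero effect set on ``grid``."""
    blocks = []
    for M in (grid.I, grid.J, grid.K):
        b = rng.normal(0.0, scale, M)
        blocks.append(b - b.mean())
    return EffectSet(rng.normal(), *blocks)


@pytest.fixture(scope="session")
def fast_config() -> SamplerConfig:
    """Reduced sampler settings for unit tests of the machinery (not used
    for any result that is compared against reference values)."""
    return SamplerConfig(chains=2, iterations=300, warmup=100, thin=2, seed=3)


def slopes_of(e: EffectSet) -> tuple[float, float, float]:
    out = []
    for b in (e.bA, e.bP, e.bC):
        v = centered_index(b.size)
        out.append(float(v @ b) / float(v @ v))
    return tuple(out)
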