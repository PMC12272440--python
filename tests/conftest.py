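"""Shared fixtures: phantoms and pipeline runs reused across test modules.

Everything is generated programmatically at test time; expensive end-to-end
runs are session-scoped so parameter-recovery and delineation checks share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from dermapa.core_io import PipelineConfig
from dermapa.phantom import PhantomSpec, generate_sample
from dermapa.pipeline import run_all


def tiny_spec(**overrides) -> PhantomSpec:
    """A small, fast phantom spec for unit tests."""
    defaults = dict(shape=(4, 40, 64),
                    tumor_half_axes_mm=(0.8, 0.5, 1.0),
                    seed=7)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def noiseless_sample():
    return generate_sample(tiny_spec(noise_sigma=0.0, additive_floor=0.0, rim_mm=0.0))


@pytest.fixture(scope="session")
def noisy_sample():
    return generate_sample(tiny_spec())


@pytest.fixture(scope="session")
def noiseless_run(noiseless_sample):
    return run_all(noiseless_sample, PipelineConfig(rng_seed=1))


@pytest.fixture(scope="session")
def noisy_run(noisy_sample):
    return run_all(noisy_sample, PipelineConfig(rng_seed=1))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
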