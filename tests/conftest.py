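import warnings

import numpy as np
import pytest

from maximindesign import CostStructure, ICCRectangle


@pytest.fixture
def subject_costs() -> CostStructure:
    """Budget counts subjects: c_sp = c_s2p = 1, all other costs 0."""
    return CostStructure.subject_count()


@pytest.fixture
def copd_rect() -> ICCRectangle:
    """ICC ranges of the COPD bronchodilator planning example."""
    return ICCRectangle(0.10, 0.70, 0.30, 0.90)


def random_costs(rng: np.random.Generator) -> CostStructure:
    """A valid random cost structure (soft-check warnings suppressed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CostStructure(
            c_A=float(rng.exponential(2.0)),
            c_B=float(rng.exponential(2.0)),
            c_t=float(rng.exponential(0.5)),
            c_sp=float(rng.exponential(1.0)) + 0.01,
            c_s2p=float(rng.exponential(2.0)) + 0.01,
            c_ts=float(rng.exponential(1.0)),
        )


def random_rect(rng: np.random.Generator) -> ICCRectangle:
    a = np.sort(rng.uniform(0.01, 1.0, 2))
    b = np.sort(rng.uniform(0.01, 1.0, 2))
    return ICCRectangle(float(a[0]), float(a[1]), float(b[0]), float(b[1]))
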