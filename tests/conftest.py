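import numpy as np
import pytest

import countdesign as cd
from countdesign.generators import CountMatrix


@pytest.fixture(scope="session")
def powerlaw_1000():
    return cd.make_powerlaw_profile(1000, 1.0, seed=1)


@pytest.fixture(scope="session")
def null_pair_small():
    profile = cd.make_powerlaw_profile(200, 1.0, seed=3)
    return cd.apply_perturbation(profile, cd.PerturbationSpec(0.0, 0.0), seed=4)


@pytest.fixture
def cm_factory():
    """Build a CountMatrix from a raw array and a condition vector."""

    def build(counts, condition=None, truth=None):
        counts = np.asarray(counts)
        n_e, n_s = counts.shape
        if condition is None:
            condition = np.array([1] * (n_s // 2) + [2] * (n_s - n_s // 2))
        return CountMatrix(
            counts=counts,
            entity_ids=[f"G{i}" for i in range(n_e)],
            sample_ids=[f"S{j}" for j in range(n_s)],
            condition=np.asarray(condition),
            truth=truth,
        )

    return build
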