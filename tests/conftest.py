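import numpy as np
import pytest

from breedlip import FeatureMatrix, SyntheticConfig


def tiny_matrix(values, mz=None, rt=None, sample_ids=None, names=None):
    """Build a FeatureMatrix from a plain (samples x features) array."""
    values = np.asarray(values, dtype=float)
    n_s, n_f = values.shape
    mz = list(mz) if mz is not None else [100.0 + 10 * j for j in range(n_f)]
    rt = list(rt) if rt is not None else [60.0 + 5 * j for j in range(n_f)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_s)]
    return FeatureMatrix.from_arrays(values, sample_ids, mz, rt, names)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def small_config(**overrides) -> SyntheticConfig:
    """Scaled-down synthetic cohort for fast unit tests (same 9 breeds)."""
    base = dict(
        n_features=240,
        n_base_metabolites=190,
        n_diet_features=8,
        n_metaclass1_features=6,
        n_metaclass2_features=3,
        n_shared_features=8,
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
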