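import numpy as np
import pandas as pd
import pytest

from neurocoex.io import ExpressionDataset
from neurocoex.synth import SynthSpec, generate_developmental


def make_dataset(values, genes=None, samples=None, metadata=None):
    """Build an ExpressionDataset from a bare array for unit tests."""
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    samples = samples or [f"s{j}" for j in range(n_s)]
    if metadata is None:
        metadata = pd.DataFrame(index=pd.Index(samples, name="sample"))
    return ExpressionDataset(list(genes), list(samples), values, metadata)


@pytest.fixture(scope="session")
def tiny_spec():
    """Reduced-size study: 8 planted modules of 50 genes in 600."""
    return SynthSpec(seed=1, n_genes=600, module_size=50)


@pytest.fixture(scope="session")
def dev_default():
    """Full-size developmental dataset with planted modules (seed 1)."""
    return generate_developmental(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def dev_tiny(tiny_spec):
    return generate_developmental(tiny_spec)
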