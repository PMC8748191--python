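import numpy as np
import pytest

from gutbraincov.compositional import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_table(rng, n_samples=30, n_taxa=8, prefix="t"):
    """Strictly positive lognormal abundance table."""
    vals = np.exp(rng.normal(0.0, 1.0, (n_samples, n_taxa)))
    return AbundanceTable(
        [f"s{i:03d}" for i in range(n_samples)],
        [f"{prefix}{j:02d}" for j in range(n_taxa)],
        vals,
    )


@pytest.fixture
def table_factory():
    return random_table
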