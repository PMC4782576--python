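import warnings

import numpy as np
import pandas as pd
import pytest

from methcan.synthetic import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale configuration used across integration-style tests."""
    return SyntheticConfig(
        n_genes=300,
        n_cgis=150,
        n_tissues=3,
        samples_per_phenotype=6,
        n_fetal_tissues=3,
        fetal_samples_per_tissue=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_all(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000):
    from methcan.genome import GenomicInterval

    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 500))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out
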