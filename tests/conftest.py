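import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from coexmark import simulate


@pytest.fixture
def small_dataset():
    """2-module planted dataset small enough for exact checks."""
    cfg = simulate.SyntheticConfig(
        n_genes=120,
        n_samples_case=20,
        n_samples_control=12,
        n_modules=2,
        module_sizes=(40, 40),
        factor_loading=0.9,
        noise_sd=0.5,
        n_discriminative=10,
        trait_linked_modules=(0,),
        seed=11,
    )
    return simulate.generate_expression(cfg)


@pytest.fixture
def two_group_phenotypes():
    def make(n_case: int, n_ctrl: int) -> pd.DataFrame:
        samples = [f"S{i:03d}" for i in range(n_case + n_ctrl)]
        return pd.DataFrame(
            {"group": ["AS"] * n_case + ["HC"] * n_ctrl},
            index=pd.Index(samples, name="sample_id"),
        )

    return make


@pytest.fixture
def random_matrix():
    def make(n_genes: int, n_samples: int, seed: int = 0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(8, 1, (n_genes, n_samples)),
            index=pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene"),
            columns=[f"S{i:03d}" for i in range(n_samples)],
        )

    return make
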