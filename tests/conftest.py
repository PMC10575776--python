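import numpy as np
import pandas as pd
import pytest

from triocog.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-trio cohort, small enough for exhaustive recount oracles."""
    cfg = SynthConfig(
        n_trios=60,
        n_snps=120,
        n_genes_lofi=40,
        n_genes_dd=10,
        n_genes_background=20,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-scale cohort (656 trios)."""
    return generate_cohort(SynthConfig(seed=11))


@pytest.fixture
def simple_trios():
    n = 10
    fids = [f"F{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "fid": fids,
            "proband": [f + "-P" for f in fids],
            "father": [f + "-F" for f in fids],
            "mother": [f + "-M" for f in fids],
            "sex": 1,
            "phenotype": [0, 1] * (n // 2),
        }
    )
    for j in range(1, 11):
        df[f"PC{j}"] = 0.0
    return df


def rng(seed=0):
    return np.random.default_rng(seed)
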