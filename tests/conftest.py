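import warnings

import numpy as np
import pandas as pd
import pytest

from phyllotraj import (
    OtuTable,
    SimulationConfig,
    flag_contaminants,
    simulate,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 20 genotypes x 5 dates, 40 OTUs, 50 SNPs."""
    return SimulationConfig(n_genotypes=20, n_otus=40, n_snps=50, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    table, panel, truth = simulate(small_config)
    return table, panel, truth


@pytest.fixture(scope="session")
def clean_table(small_study):
    """Decontaminated, controls removed."""
    table, _, _ = small_study
    return flag_contaminants(table).pruned(table).real_samples()


def toy_table(counts, groups=None, timepoints=None, infected=None,
              controls=None):
    """Build a minimal OtuTable around a counts array."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    ids = [f"s{i + 1}" for i in range(n)]
    meta = pd.DataFrame({
        "genotype": [f"g{i + 1}" for i in range(n)],
        "subpopulation": groups if groups is not None else ["a"] * n,
        "site": "site1",
        "timepoint": timepoints if timepoints is not None else [1] * n,
        "doy": 150,
        "infected": infected if infected is not None else [False] * n,
        "is_control": controls if controls is not None else [False] * n,
    }, index=ids)
    cols = [f"o{j + 1}" for j in range(counts.shape[1])]
    return OtuTable(pd.DataFrame(counts, index=ids, columns=cols), meta)
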