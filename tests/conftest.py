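import numpy as np
import pandas as pd
import pytest

from subfieldseq.core import CountMatrix
from subfieldseq.simulate import SimConfig, simulate_behavior, simulate_counts


def make_count_matrix(values, platform="A", gene_ids=None, sample_ids=None):
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        platform,
    )


def make_sheet(n1, n2, factor="age_group", levels=("young", "aged"), platform="A"):
    """Minimal valid sample sheet for a two-group contrast on one platform."""
    n = n1 + n2
    return pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n)],
            "animal_id": [f"a{j}" for j in range(n)],
            "region": "CA1",
            "age_group": [levels[0]] * n1 + [levels[1]] * n2
            if factor == "age_group"
            else "young",
            "cognitive_class": "unassigned",
            "platform": platform,
            "site": "X",
        }
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study shared across tests."""
    config = SimConfig(
        n_genes=500,
        n_young=5,
        n_aged_unimpaired=5,
        n_aged_impaired=5,
        rng_seed=42,
    )
    counts_a, counts_b, sheet, truth = simulate_counts(config)
    behavior = simulate_behavior(config, sheet)
    return {
        "config": config,
        "counts_a": counts_a,
        "counts_b": counts_b,
        "sheet": sheet,
        "truth": truth,
        "behavior": behavior,
    }
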