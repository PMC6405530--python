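import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from invadepop import GenotypeMatrix, SimConfig, simulate_dataset


def random_genotype_matrix(rng, n_ind=12, n_loci=8, missing_rate=0.1):
    """Random matrix where every locus shows both alleles (round-trippable)."""
    while True:
        calls = rng.integers(0, 3, size=(n_ind, n_loci)).astype(np.int8)
        mask = rng.uniform(size=calls.shape) < missing_rate
        calls[mask] = -1
        obs_ok = True
        for j in range(n_loci):
            col = calls[:, j][calls[:, j] >= 0]
            if col.size == 0 or (1 not in col and not (0 in col and 2 in col)):
                obs_ok = False
                break
        if obs_ok:
            break
    ids = [f"ind{i + 1}" for i in range(n_ind)]
    loci = [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(ids, loci, calls)


def toy_metadata(gm, populations, range_of=None, source="natural"):
    """Metadata table assigning gm's individuals to the given populations."""
    range_of = range_of or {}
    rows = []
    for ind, pop in zip(gm.individual_ids, populations):
        rows.append(
            {
                "individual_id": ind,
                "population": pop,
                "range_label": range_of.get(pop, "native"),
                "longitude": 10.0 + hash(pop) % 50 / 10,
                "latitude": 45.0 + hash(pop) % 30 / 10,
                "source_type": source,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic two-range dataset with known ground truth."""
    cfg = SimConfig(
        n_native_demes=4,
        n_invasive_pops=4,
        pop_size=(8, 12),
        n_loci_full=80,
        n_loci_ascertained=40,
        founder_demes=(0, 1),
        n_common_garden=1,
        seed=42,
    )
    return simulate_dataset(cfg)
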