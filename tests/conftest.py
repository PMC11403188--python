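import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from deerload import GenotypeMatrix, ScenarioConfig, simulate_scenario


def make_gm(genotypes, positions=None, chrom="chr1", populations=None, **site_cols):
    """Hand-build a GenotypeMatrix from a (sites, samples) genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    samples = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else list(chrom),
            "pos": positions,
            "ref": site_cols.get("ref", ["A"] * n_sites),
            "alt": site_cols.get("alt", ["G"] * n_sites),
            "qual": site_cols.get("qual", [100.0] * n_sites),
            "info": site_cols.get("info", [{} for _ in range(n_sites)]),
        }
    )
    return GenotypeMatrix(
        sites=sites,
        genotypes=g,
        samples=samples,
        populations=populations or {s: "P" for s in samples},
    )


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Small two-population simulation shared by structure-level tests."""
    cfg = ScenarioConfig(
        n_chrom=4,
        chrom_length_bp=250_000,
        mu=6e-7,
        rec_rate=8.0,
        ne_ancestral=100,
        split_gen=60,
        ne_pops={"A": 100, "B": 50},
        migration_epoch=(60, 59, 0.0, 0.0),
        sample_sizes={"A": 10, "B": 10},
        seed=11,
    )
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def panmictic_dataset():
    """One panmictic population, neutral classes only relevant for nulls."""
    cfg = ScenarioConfig(
        n_chrom=4,
        chrom_length_bp=250_000,
        mu=8e-7,
        rec_rate=8.0,
        ne_ancestral=100,
        split_gen=5,
        ne_pops={"A": 100},
        migration_epoch=(5, 4, 0.0, 0.0),
        sample_sizes={"A": 20},
        seed=5,
    )
    return simulate_scenario(cfg)
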