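import numpy as np
import pandas as pd
import pytest

from ricegs import SimulationConfig, simulate_genotypes, simulate_phenotypes
from ricegs.sim import TraitSpec


@pytest.fixture(scope="session")
def two_trait_config():
    return SimulationConfig(
        n_accessions=150, n_snps=400, n_founder_haplotypes=12,
        maf_min=0.05, recomb_rate=0.02,
        traits=[TraitSpec("BR3", 0.5, 60, "higher"),
                TraitSpec("PH", 0.8, 60, "lower")],
        season_genetic_correlation=0.7, seed=42)


@pytest.fixture(scope="session")
def panel(two_trait_config):
    return simulate_genotypes(two_trait_config)


@pytest.fixture(scope="session")
def phenotypes(two_trait_config, panel):
    return simulate_phenotypes(panel, two_trait_config)


@pytest.fixture(scope="session")
def br3_es(phenotypes):
    """BR3 early-season phenotype vector aligned to panel sample order."""
    table, _ = phenotypes
    sub = table.query("trait == 'BR3' and season == 'ES'")
    return sub.set_index("accession")["value"]
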