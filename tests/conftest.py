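import numpy as np
import pandas as pd
import pytest

from limbphylo import synth

TREE = "(((bat,pig),mouse),opossum);"
SPECIES = ["bat", "pig", "mouse", "opossum"]


@pytest.fixture(scope="session")
def tree_newick() -> str:
    return TREE


@pytest.fixture(scope="session")
def small_config() -> synth.SimConfig:
    return synth.SimConfig(
        species_tree=TREE,
        n_core_orthologs=100,
        n_specific_per_species=10,
        n_specific_per_clade=5,
        stage_divergence_sd={"ridge": 0.1, "bud": 0.4, "paddle": 0.8},
        limb_effect_genes=5,
        limb_effect_size=5.0,
        tai_shape="hourglass",
        tai_effect_size=1.0,
        noise_sd=0.05,
        n_replicates=2,
        seq_depth=300_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> synth.SimDataset:
    return synth.generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def toy_profiles(n_genes: int, n_profiles: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.lognormal(1.0, 1.0, size=(n_genes, n_profiles)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"p{j}" for j in range(n_profiles)],
    )
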