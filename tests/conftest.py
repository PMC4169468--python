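import numpy as np
import pandas as pd
import pytest

from symbiocomp import phylo, simulate


def star_tree(n: int) -> phylo.Phylogeny:
    return phylo.read_newick("(" + ",".join(f"s{i:03d}:1" for i in range(n)) + ");")


@pytest.fixture(scope="session")
def star19():
    return star_tree(19)


@pytest.fixture(scope="session")
def coalescent19():
    return simulate.simulate_tree(19, seed=11)


def replicate_trait_table(effects: pd.DataFrame, n_rep: int, resid_sd: float,
                          seed: int) -> pd.DataFrame:
    """Long trait table: strain effects plus i.i.d. replicate noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in effects.index:
        for t in effects.columns:
            for _ in range(n_rep):
                rows.append((s, t, effects.loc[s, t] + rng.normal(0.0, resid_sd)))
    return pd.DataFrame(rows, columns=["strain", "trait", "value"])


@pytest.fixture(scope="session")
def small_study():
    """A compact full synthetic study reused across tests."""
    cfg = simulate.SimulationConfig(
        n_strains=6, n_vials_per_strain_per_treatment=4, flies_per_vial=12,
        trait_names=("protection_DCV", "protection_FHV"),
    )
    return simulate.simulate_study(cfg)
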