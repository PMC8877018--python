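import pandas as pd
import pytest

import traitassembly as ta


@pytest.fixture(scope="session")
def balanced_tree() -> ta.Phylogeny:
    return ta.Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture(scope="session")
def star_tree_8() -> ta.Phylogeny:
    tips = ",".join(f"t{i}:1" for i in range(8))
    return ta.Phylogeny.from_newick(f"({tips}):0;")


@pytest.fixture(scope="session")
def small_dataset() -> ta.SyntheticDataset:
    """Unfiltered 12-species, 4-site dataset reused by several modules."""
    cfg = ta.SimulationConfig(
        n_species=12, n_sites=4, n_individuals_per_site=15, seed=3
    )
    return ta.generate_dataset(cfg)


@pytest.fixture()
def two_pop_table() -> ta.TraitTable:
    """One community of two species with hand-checkable variances."""
    rows = []
    for sp, vals in (("spA", [1.0, 3.0]), ("spB", [5.0, 7.0])):
        for i, v in enumerate(vals):
            rows.append({"site": "c1", "habitat": "SEF", "species": sp,
                         "individual": f"{sp}{i}", "x": v})
    return ta.TraitTable(pd.DataFrame(rows))
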