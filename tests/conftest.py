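import pandas as pd
import pytest

from empdcc.fixtures import dataset_table, testing_sets
from empdcc.synthetic import default_specs_from_table5, generate_population


@pytest.fixture(scope="session")
def table5_pops():
    """Synthetic analogues of the 24 reference datasets (n=2000, fixed seeds)."""
    specs = default_specs_from_table5(n=2000, base_seed=100)
    return {s.name: generate_population(s) for s in specs}


@pytest.fixture(scope="session")
def testing_pools(table5_pops):
    """Pooled synthetic testing-set particles: (asbestiform, non-asbestiform)."""
    t = testing_sets()
    asb = pd.concat(
        [table5_pops[d] for d in t.loc[t["habit_apriori"] == "asbestiform", "dataset"]],
        ignore_index=True,
    )
    non = pd.concat(
        [table5_pops[d] for d in t.loc[t["habit_apriori"] == "non_asbestiform", "dataset"]],
        ignore_index=True,
    )
    return asb, non
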