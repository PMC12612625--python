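import warnings

import numpy as np
import pandas as pd
import pytest

from traitplast import SimulationConfig, TraitTable, simulate_trait_table
from traitplast.simulate import (default_site_effect_signs,
                                 default_trait_profiles,
                                 default_variance_fractions)


def make_table(df: pd.DataFrame, *args, **kwargs) -> TraitTable:
    """Construct a TraitTable silencing the tree-count advisory warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return TraitTable(df, *args, **kwargs)


def small_config(traits=("LMA", "LDMC", "AS_AL"), fractions=None, **kwargs):
    """SimulationConfig restricted to a few traits for fast replicated runs."""
    profiles = {t: default_trait_profiles()[t] for t in traits}
    base = default_variance_fractions()
    if fractions is not None:
        base = {t: fractions for t in traits}
    return SimulationConfig(
        trait_profiles=profiles,
        variance_fractions={t: base[t] for t in traits},
        site_effect_sign={t: default_site_effect_signs()[t] for t in traits},
        **kwargs,
    )


@pytest.fixture
def toy_table() -> TraitTable:
    """2 sites x 3 varieties (1 shared) x 2 trees x 2 traits."""
    rows = []
    values = iter(range(1, 100))
    for site, varieties in [("A", ["shared", "onlyA1", "onlyA2"]),
                            ("B", ["shared", "onlyB1", "onlyB2"])]:
        for v in varieties:
            for tree in ["t1", "t2"]:
                rows.append({"site": site, "variety": v, "tree": tree,
                             "LMA": float(next(values)) * 10,
                             "LDMC": float(next(values)) * 5})
    return TraitTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic garden (17 common + 33 distinct per site)."""
    table, truth = simulate_trait_table(SimulationConfig(seed=2024))
    return table, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
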