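import numpy as np
import pandas as pd
import pytest

from wheatstab.synthetic import SimConfig, simulate_trial, simulate_yield_components
from wheatstab.trial_io import DesignSpec, KEY_COLUMNS


def make_table(rows):
    """Build a tidy trial table from (year, block, n, at, sd, geno, trait, value) tuples."""
    return pd.DataFrame(rows, columns=[*KEY_COLUMNS[:-1], "trait", "value"])


@pytest.fixture(scope="session")
def design() -> DesignSpec:
    return DesignSpec()


@pytest.fixture(scope="session")
def sim_table():
    """Default-condition simulated study (seed 0), shared read-only."""
    table, truth = simulate_trial(SimConfig(seed=0))
    return table, truth


@pytest.fixture(scope="session")
def yield_table():
    table, truth = simulate_yield_components(SimConfig(seed=0))
    return table, truth


@pytest.fixture
def tiny_table():
    """2 genotypes x 2 environments (1 year x 2 managements) x 3 blocks, one trait."""
    rows = []
    for mi, (nl, at, sd) in enumerate([("optimal", "split", "early"),
                                       ("optimal", "split", "late")]):
        for gi, geno in enumerate(["Capone", "Esket"]):
            for b in (1, 2, 3):
                rows.append((2020, b, nl, at, sd, geno, "GY",
                             5.0 + gi + 2 * mi + 0.1 * b))
    return make_table(rows)
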