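import numpy as np
import pandas as pd
import pytest

from spellmsm import GeneratorConfig, MultiStateModel, generate_cohort, simulate_trajectories
from spellmsm.synthetic import DEFAULT_EXCLUSION_FRACTIONS

NO_EXCLUSIONS = {k: 0.0 for k in DEFAULT_EXCLUSION_FRACTIONS}


def make_counting_table(rows):
    """Counting-process table from (person, from, to, entry, exit, status) rows."""
    frame = pd.DataFrame(
        rows, columns=["person_id", "from_state", "to_state", "entry", "exit", "status"]
    )
    frame["weight"] = 1.0
    return frame


@pytest.fixture(scope="session")
def clean_config():
    """Small cohort with no gaps/overlaps/exclusions: latent path == spells."""
    return GeneratorConfig(
        n_individuals=800,
        seed=20240915,
        gap_rate=0.0,
        overlap_rate=0.0,
        exclusion_fractions=NO_EXCLUSIONS,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def clean_spells(clean_config, clean_cohort):
    return simulate_trajectories(clean_cohort, clean_config)


@pytest.fixture(scope="session")
def clean_model(clean_spells, clean_cohort):
    return MultiStateModel.from_spells(clean_spells, clean_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort under the full default study conditions (gaps, overlaps, flags)."""
    config = GeneratorConfig(n_individuals=600, seed=77)
    cohort = generate_cohort(config)
    spells = simulate_trajectories(cohort, config)
    return config, cohort, spells


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
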