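import warnings

import numpy as np
import pandas as pd
import pytest

import trialvar as tv
from trialvar.melsm import MELSM


@pytest.fixture(scope="session")
def small_table() -> pd.DataFrame:
    """Moderate synthetic table with real random effects on both portions."""
    cfg = tv.GeneratorConfig(n_per_group=15, trials_per_condition=12, seed=101)
    return tv.simulate_trial_table(cfg)


@pytest.fixture(scope="session")
def small_fit(small_table):
    """One location-scale fit shared across posterior-summary tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MELSM(small_table).fit(draws=300, warmup=300, chains=2, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_table(cells: dict[tuple[str, str, str], int]) -> pd.DataFrame:
    """Build a trial table with given per-(participant, group, event) counts."""
    rows = []
    for (pid, group, event), n in cells.items():
        for t in range(1, n + 1):
            rows.append((pid, group, event, t, float(t)))
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "event", "trial", "amplitude"]
    )
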