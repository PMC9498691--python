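import numpy as np
import pandas as pd
import pytest

from asymtraj import synth


@pytest.fixture(scope="session")
def mirrored_pair():
    """A perfectly mirrored region pair: no size, shape or pose asymmetry."""
    return synth.make_paired_volume(synth.ShapeSpec(seed=101))


@pytest.fixture(scope="session")
def default_cohort():
    """A medium synthetic cohort under the default study conditions."""
    return synth.simulate_cohort(n_subjects=120, seed=42)


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    from asymtraj.io import filter_cohort

    kept, log = filter_cohort(default_cohort.visits)
    return kept, log, default_cohort


def true_adjusted(sim) -> pd.DataFrame:
    """Visits with ground-truth adjusted times from the generator answer key."""
    offset = sim.subjects.set_index("rid")["conversion_offset_months"]
    df = sim.visits.copy()
    df["adjusted_months"] = df["viscode_months"] - df["rid"].map(offset)
    return df


@pytest.fixture(scope="session")
def adjusted_cohort(default_cohort):
    return true_adjusted(default_cohort)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
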