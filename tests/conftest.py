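import pytest

import cordtol as ct
from cordtol.datasets import group_cohorts


@pytest.fixture(scope="session")
def rat_datasets():
    return ct.load_rat_table()


@pytest.fixture(scope="session")
def cohorts():
    return ct.load_cohort_table()


@pytest.fixture(scope="session")
def rim_fits(cohorts):
    """Default (logit) fits with profile CIs for groups B, C, D."""
    return {g: ct.fit_rim(group_cohorts(cohorts, g), group=g) for g in "BCD"}


@pytest.fixture(scope="session")
def normalized_published(rat_datasets):
    """Rat datasets normalized to the published single-fraction reference."""
    return ct.normalize(rat_datasets, reference=ct.published_reference(rat_datasets))
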