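import numpy as np
import pytest

from facendo import shapeprep as prep
from facendo import synthdata as syn


@pytest.fixture(scope="session")
def template():
    return syn.make_template(p=100, seed=1)


@pytest.fixture(scope="session")
def small_cohort(template):
    """60 individuals, 20 'parents' shifted along a planted direction."""
    direction = syn.localized_direction(template, seed=5)
    spec = syn.CohortSpec(
        n_individuals=60,
        n_group1=20,
        effect_direction=direction,
        effect_size=1.5,
        noise_sd=0.02,
        seed=11,
    )
    configs, covs, group = syn.simulate_cohort(template, spec)
    return {
        "configs": configs,
        "covariates": covs,
        "group": group,
        "direction": direction,
        "template": template,
    }


@pytest.fixture(scope="session")
def aligned_sample(small_cohort):
    return prep.gpa(small_cohort["configs"], remove_scale=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
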