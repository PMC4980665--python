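"""Shared fixtures: synthetic datasets and (expensive) fitted models.

Heavy MCMC fits are session-scoped so the recovery checks in the unit tests
and the acceptance suite share one fit per model.  Seeds are fixed
conventionally (1 for datasets, distinct odd offsets for samplers).
"""

import numpy as np
import pytest

from paimem.bayes.accuracy import fit_accuracy
from paimem.bayes.logistic import fit_logistic
from paimem.bayes.rt import fit_rt
from paimem.bayes.sampler import MCMCConfig
from paimem.generate import default_config, generate
from paimem.task import Triplet, build_schedule

#: test-scale MCMC: enough draws for stable posterior means at a fraction of
#: the published run lengths
TEST_MCMC = dict(chains=4, draws=4000, burn_in=1500, adapt_steps=800)
SMALL_MCMC = dict(chains=4, draws=1200, burn_in=600, adapt_steps=400)


def make_triplets(n):
    return [Triplet(t, f"A{t}", f"B{t}", f"C{t}") for t in range(1, n + 1)]


@pytest.fixture(scope="session")
def exp1_schedule():
    return build_schedule(1, seed=7)


@pytest.fixture(scope="session")
def exp1_data():
    """Experiment-1 synthetic dataset at the reported group summaries."""
    config = default_config(1, seed=1)
    dataset, truth = generate(config, return_truth=True)
    return config, dataset, truth


@pytest.fixture(scope="session")
def exp1_accuracy_fit(exp1_data):
    _, dataset, _ = exp1_data
    return fit_accuracy(dataset, MCMCConfig(seed=43, **TEST_MCMC))


@pytest.fixture(scope="session")
def exp1_rt_fit(exp1_data):
    _, dataset, _ = exp1_data
    return fit_rt(
        dataset,
        MCMCConfig(seed=45, chains=4, draws=2500, burn_in=1000, adapt_steps=600),
        phase="choice",
    )


@pytest.fixture(scope="session")
def logistic_data():
    """Larger sample for the regression recovery (coefficients need more
    subjects than accuracy summaries do)."""
    config = default_config(1, n_subjects=300, seed=1)
    dataset, truth = generate(config, return_truth=True)
    return config, dataset, truth


@pytest.fixture(scope="session")
def logistic_fit(logistic_data):
    _, dataset, _ = logistic_data
    return fit_logistic(
        dataset,
        MCMCConfig(seed=47, chains=4, draws=2500, burn_in=1000, adapt_steps=600),
    )


@pytest.fixture(scope="session")
def exp2_data():
    config = default_config(2, seed=1)
    dataset, truth = generate(config, return_truth=True)
    return config, dataset, truth


@pytest.fixture(scope="session")
def exp2_accuracy_fit(exp2_data):
    _, dataset, _ = exp2_data
    return fit_accuracy(dataset, MCMCConfig(seed=49, **TEST_MCMC))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
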