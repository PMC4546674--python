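import numpy as np
import pandas as pd
import pytest

import ettmachine as em
from ettmachine.preprocess import expand_missingness


@pytest.fixture(scope="session")
def toy():
    """Discrete toy cohort (binary W, S, Y) with closed-form truth."""
    return em.make_discrete_toy(1000, seed=3)


@pytest.fixture(scope="session")
def toy_frames(toy):
    coh = toy.cohort
    X = pd.DataFrame({"w": coh.df["w"]})
    return X, coh.site, coh.df["y"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def default_cohort():
    return em.generate_cohort(em.default_config(), seed=7)


@pytest.fixture(scope="session")
def default_design(default_cohort):
    return expand_missingness(default_cohort)


@pytest.fixture(scope="session")
def mortality_truth():
    """High-precision Monte-Carlo truth for overall mortality under the
    default mechanism (shared across tests; seeds differ from any cohort
    seed used in estimation)."""
    return em.true_ett(em.default_config(), "overall_mortality",
                       n_mc=1_000_000, seed=11)


def saturated_toy_fits(X, S, y):
    """Saturated outcome and propensity fits on the one-binary-covariate toy:
    logistic with the site-by-W interaction is exactly saturated."""
    qfit = em.fit_outcome_model(X, S, y, method="regression", site_interactions=["w"])
    gfit = em.fit_propensity(X, S, method="regression", delta=0.0)
    return qfit, gfit
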