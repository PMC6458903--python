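"""Shared fixtures: synthetic cohorts and their inversions.

The expensive objects (inverted cohorts) are session-scoped and shared
between the recovery, model-comparison and acceptance tests.
"""

import numpy as np
import pytest

from specdcm import cmc, cohorts
from specdcm.inversion import (InversionConfig, default_prior_covariance,
                               variational_laplace)

COHORT_SEED = 33          # construct-validity cohort
SMALL_SEED = 21
NULL_SEED0 = 1000


@pytest.fixture(scope="session")
def network():
    return cmc.default_network()


@pytest.fixture(scope="session")
def base_params():
    return cmc.alpha_prior_parameters()


@pytest.fixture(scope="session")
def prior_cov():
    return default_prior_covariance()


def invert_cohort(csds, base, net, prior_cov, m, max_iterations=64):
    cfg = InversionConfig(n_eigenmodes=m, max_iterations=max_iterations)
    return [variational_laplace(d, base, prior_cov, net, cfg) for d in csds]


@pytest.fixture(scope="session")
def cohort36(network, base_params, prior_cov):
    """36-subject construct-validity cohort, inverted (8 eigenmodes)."""
    m = 8
    models, csds, cov, z, net, base = cohorts.construct_validity_cohort(
        seed=COHORT_SEED, n_subjects=36, n_eigenmodes=m,
        freqs=cmc.default_freqs())
    posts = invert_cohort(csds, base_params, network, prior_cov, m)
    return {"models": models, "csds": csds, "cov": cov, "z": z,
            "posteriors": posts}


@pytest.fixture(scope="session")
def cohort12(network, base_params, prior_cov):
    """12-subject scaled-down cohort, inverted (4 eigenmodes)."""
    m = 4
    models, csds, cov, z, net, base = cohorts.construct_validity_cohort(
        seed=SMALL_SEED, n_subjects=12, n_eigenmodes=m,
        freqs=cmc.default_freqs())
    posts = invert_cohort(csds, base_params, network, prior_cov, m,
                          max_iterations=48)
    return {"models": models, "csds": csds, "cov": cov, "z": z,
            "posteriors": posts}


@pytest.fixture(scope="session")
def null_cohorts(network, base_params, prior_cov):
    """20 null cohorts (no between-subject effect), inverted."""
    m = 4
    out = []
    for rep in range(20):
        models, csds, cov, z, net, base = cohorts.construct_validity_cohort(
            seed=NULL_SEED0 + rep, n_subjects=12, n_eigenmodes=m,
            freqs=cmc.default_freqs(), effect_size=0.0)
        posts = invert_cohort(csds, base_params, network, prior_cov, m,
                              max_iterations=48)
        out.append({"cov": cov, "z": z, "posteriors": posts})
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
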