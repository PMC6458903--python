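"""Tests for the between-subject (PEB) level and Bayesian model reduction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from specdcm import cmc
from specdcm.inversion import SubjectPosterior, default_prior_covariance
from specdcm.peb import (DesignMatrix, ModelSpace, PEBResult,
                         bayesian_model_reduction, build_design_matrix,
                         compare_model_space, exhaustive_bmr_search,
                         extract_effects, orthogonalize_age, peb_fit)


# ---------------------------------------------------------------------------
# Orthogonalization and design
# ---------------------------------------------------------------------------


def test_orthogonalize_age_perfect_fit_gives_zero():
    k = np.array([10.0, 20.0, 30.0, 40.0])
    age = 2.0 * k + 5.0
    assert np.abs(orthogonalize_age(k, age)).max() < 1e-10


def test_orthogonalize_age_uncorrelated_returns_centred_age(rng):
    k = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    age = np.array([30.0, 30.0, 40.0, 40.0, 50.0, 50.0])  # corr(k, age) = 0
    out = orthogonalize_age(k, age)
    assert np.allclose(out, age - age.mean(), atol=1e-10)


def test_orthogonalize_age_matches_normal_equations():
    k = np.array([10.0, 20.0, 30.0])
    age = np.array([20.0, 25.0, 36.0])
    X = np.column_stack([np.ones(3), k])
    beta = np.linalg.solve(X.T @ X, X.T @ age)  # explicit OLS oracle
    expect = age - X @ beta
    out = orthogonalize_age(k, age)
    assert np.allclose(out, expect, atol=1e-10)
    assert abs(out @ k) < 1e-8
    assert abs(out.mean()) < 1e-10


def test_orthogonalize_age_rejects_constant_score():
    with pytest.raises(ValueError):
        orthogonalize_age(np.ones(5), np.arange(5.0))


def test_design_matrix_properties(rng):
    n = 24
    cov = pd.DataFrame({
        "kbit_raw": rng.normal(55, 20, n),
        "age": rng.uniform(16, 56, n),
        "order": rng.permutation(n) + 1,
        "protocol": rng.integers(0, 2, n),
    })
    d = build_design_matrix(cov)
    assert d.X.shape == (n, 6)
    assert np.linalg.matrix_rank(d.X) == 6
    kbit = d.column("kbit")
    age_o = d.column("age_orth")
    assert abs(np.corrcoef(kbit, age_o)[0, 1]) < 1e-10
    for name in ("kbit", "age_orth", "kbit_x_age", "order_nuisance",
                 "protocol_nuisance"):
        assert abs(d.column(name).mean()) < 1e-10


def test_design_matrix_rejects_rank_deficiency():
    X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
    with pytest.raises(ValueError):
        DesignMatrix(X=X, columns=["intercept", "a", "b"], effect_columns=())


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------


def _linear_evidence(y, A, b, h, mu0, S0):
    return multivariate_normal.logpdf(
        y, mean=A @ mu0 + b, cov=A @ S0 @ A.T + np.eye(len(y)) / h)


def test_bmr_identity_when_prior_unchanged(rng):
    p = 4
    S0 = np.diag(rng.uniform(0.2, 1.0, p))
    mu = rng.standard_normal(p)
    S = 0.5 * S0
    dF, mr, Sr = bayesian_model_reduction(np.zeros(p), S0, mu, S,
                                          np.zeros(p), S0)
    assert dF == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(mr, mu)
    assert np.allclose(Sr, S)


def test_bmr_matches_reinversion_on_linear_gaussian(rng):
    """Closed-form evidence change equals explicit re-inversion for 10
    random reduced priors of a linear-Gaussian model."""
    p, n, h = 5, 30, 10.0
    A = rng.standard_normal((n, p))
    b = rng.standard_normal(n)
    y = A @ rng.standard_normal(p) + b + rng.standard_normal(n) / np.sqrt(h)
    mu0 = np.zeros(p)
    S0 = np.diag(np.full(p, 0.5))
    P = h * A.T @ A + np.linalg.inv(S0)
    S = np.linalg.inv(P)
    mu = S @ (h * A.T @ (y - b))
    F_full = _linear_evidence(y, A, b, h, mu0, S0)
    for _ in range(10):
        nu = 0.3 * rng.standard_normal(p)
        Sr0 = np.diag(rng.uniform(1e-6, 0.6, p))
        dF, mr, Sr = bayesian_model_reduction(mu0, S0, mu, S, nu, Sr0)
        F_red = _linear_evidence(y, A, b, h, nu, Sr0)
        assert dF == pytest.approx(F_red - F_full, abs=1e-6)
        # reduced posterior matches direct conjugate update under the new prior
        P_direct = h * A.T @ A + np.linalg.inv(Sr0)
        mu_direct = np.linalg.solve(
            P_direct, h * A.T @ (y - b) + np.linalg.solve(Sr0, nu))
        assert np.allclose(mr, mu_direct, atol=1e-8)


def test_bmr_irrelevant_parameter_costs_little(rng):
    """Switching off a parameter the data do not inform changes F by < 0.5
    nats."""
    p, n, h = 4, 40, 20.0
    A = rng.standard_normal((n, p))
    A[:, 2] = 0.0  # parameter 2 is irrelevant
    y = A @ rng.standard_normal(p) + rng.standard_normal(n) / np.sqrt(h)
    mu0 = np.zeros(p)
    S0 = np.diag(np.full(p, 0.5))
    P = h * A.T @ A + np.linalg.inv(S0)
    S = np.linalg.inv(P)
    mu = S @ (h * A.T @ y)
    Sr0 = S0.copy()
    Sr0[2, 2] = 1e-10
    dF, _, _ = bayesian_model_reduction(mu0, S0, mu, S, mu0, Sr0)
    assert abs(dF) < 0.5


def test_bmr_rejects_indefinite_reduction(rng):
    p = 3
    S0 = np.eye(p) * 0.1           # tight full prior
    S = np.eye(p) * 0.2            # posterior looser than the prior
    Sr0 = np.eye(p) * 10.0         # much looser reduced prior
    with pytest.raises(ValueError):
        bayesian_model_reduction(np.zeros(p), S0, np.zeros(p), S,
                                 np.zeros(p), Sr0)


# ---------------------------------------------------------------------------
# PEB fitting
# ---------------------------------------------------------------------------


def _toy_posterior(mean_vec, var=0.005):
    return SubjectPosterior(mean=mean_vec, covariance=np.eye(len(mean_vec)) * var,
                            free_energy=0.0)


def test_peb_degenerate_pooling_recovers_shared_mean(base_params, prior_cov):
    """Identical, confident subject posteriors with an intercept-only design:
    the group intercept effect reproduces the shared posterior mean."""
    shared = base_params.to_vector().copy()
    names = cmc.CMCParameters.names()
    shared[names.index("g1_lV1")] += 0.3
    shared[names.index("a_fwd_lV1->lSPL")] -= 0.2
    posts = [_toy_posterior(shared) for _ in range(8)]
    X = np.ones((8, 1))
    d = DesignMatrix(X=X, columns=["intercept"], effect_columns=())
    peb = peb_fit(posts, d, base_params, prior_cov)
    group_mean = peb.prior_mean_sel + peb.beta_block("intercept")[0]
    idx = peb.param_indices
    assert np.allclose(group_mean, shared[idx], atol=0.05)


def test_peb_exchangeability_under_subject_permutation(cohort12, base_params,
                                                       prior_cov):
    posts = cohort12["posteriors"]
    z = cohort12["z"]
    X = np.column_stack([np.ones_like(z), z])
    d = DesignMatrix(X=X, columns=["intercept", "kbit"],
                     effect_columns=("kbit",))
    peb1 = peb_fit(posts, d, base_params, prior_cov)
    perm = np.random.default_rng(3).permutation(len(posts))
    d2 = DesignMatrix(X=X[perm], columns=["intercept", "kbit"],
                      effect_columns=("kbit",))
    peb2 = peb_fit([posts[i] for i in perm], d2, base_params, prior_cov)
    assert np.allclose(peb1.beta_mean, peb2.beta_mean, atol=1e-8)
    assert peb1.free_energy == pytest.approx(peb2.free_energy, abs=1e-6)


def test_peb_rejects_bad_inputs(base_params, prior_cov):
    posts = [_toy_posterior(base_params.to_vector()) for _ in range(4)]
    X = np.column_stack([np.ones(4), np.ones(4)])
    with pytest.raises(ValueError):
        DesignMatrix(X=X, columns=["intercept", "dup"], effect_columns=())
    good = DesignMatrix(X=np.ones((3, 1)), columns=["intercept"],
                        effect_columns=())
    with pytest.raises(ValueError):
        peb_fit(posts, good, base_params, prior_cov)  # row mismatch
    bad = _toy_posterior(base_params.to_vector())
    bad.names = list(bad.names)[::-1]
    d4 = DesignMatrix(X=np.ones((4, 1)), columns=["intercept"],
                      effect_columns=())
    with pytest.raises(ValueError):
        peb_fit(posts[:3] + [bad], d4, base_params, prior_cov)


# ---------------------------------------------------------------------------
# Model space and comparison
# ---------------------------------------------------------------------------


def test_model_space_has_seven_distinct_candidates():
    space = ModelSpace()
    assert len(space.candidates) == 7
    assert "i" in space.labels
    with pytest.raises(ValueError):
        ModelSpace(candidates=[("forward",)] * 7)


def _flat_peb(base_params, prior_cov):
    """A PEB result whose effect posterior equals its prior (no evidence)."""
    from specdcm.peb import _selected_indices
    idx, names = _selected_indices(("forward", "backward", "intrinsic"))
    z = np.zeros(len(names))
    X = np.column_stack([np.ones(6), np.linspace(-1, 1, 6)])
    d = DesignMatrix(X=X, columns=["intercept", "kbit"],
                     effect_columns=("kbit",))
    Sb = np.diag(np.full(2 * len(names), 1.0 / 16))
    return PEBResult(
        beta_mean=np.zeros(2 * len(names)), beta_covariance=Sb.copy(),
        free_energy=0.0, design=d, param_names=names, param_indices=idx,
        classes=("forward", "backward", "intrinsic"), beta_prior_cov=Sb,
        gamma=0.0, psi=np.eye(len(names)),
        prior_mean_sel=base_params.to_vector()[idx],
        subject_means=np.zeros((6, len(names))),
        subject_fitted=np.zeros((6, len(names))))


def test_equal_evidence_gives_uniform_probabilities(base_params, prior_cov):
    peb = compare_model_space(_flat_peb(base_params, prior_cov))
    probs = [v["probability"] for v in peb.model_posteriors.values()]
    assert np.allclose(probs, 1.0 / 7.0, atol=1e-10)
    assert sum(probs) == pytest.approx(1.0, abs=1e-10)


def test_bayes_factor_is_exp_of_free_energy_difference(cohort12, base_params,
                                                       prior_cov):
    d = build_design_matrix(cohort12["cov"])
    peb = compare_model_space(peb_fit(cohort12["posteriors"], d, base_params,
                                      prior_cov))
    f = peb.model_free_energies
    p = {k: v["probability"] for k, v in peb.model_posteriors.items()}
    bf = p["i"] / p["fb"]
    assert bf == pytest.approx(np.exp(f["i"] - f["fb"]), rel=1e-9)
    assert sum(p.values()) == pytest.approx(1.0, abs=1e-10)


def test_exhaustive_search_ranks_and_guards(base_params, prior_cov):
    peb = _flat_peb(base_params, prior_cov)
    res = exhaustive_bmr_search(peb, entries=[14, 15, 16])
    assert len(res) == 8
    assert all(r["delta_F"] == pytest.approx(0.0, abs=1e-9) for r in res)
    with pytest.raises(ValueError):
        exhaustive_bmr_search(peb, entries=list(range(20)))


def test_extract_effects_requires_known_column(cohort12, base_params,
                                               prior_cov):
    d = build_design_matrix(cohort12["cov"])
    peb = peb_fit(cohort12["posteriors"], d, base_params, prior_cov)
    with pytest.raises(ValueError):
        extract_effects(peb, "not_a_column")
    eff = extract_effects(peb, "kbit")
    assert list(eff["effects"]["node"]) == list(cmc.NODES)
    assert np.all(eff["effects"]["ci_low"] <= eff["effects"]["effect"])
    assert np.all(eff["effects"]["effect"] <= eff["effects"]["ci_high"])


def test_recovered_effect_sign_and_magnitude(cohort12):
    """Intrinsic deviations generated as 0.4 per regressor SD: the recovered
    score effect has the right sign and is within 50% at low noise."""
    from specdcm.inversion import default_prior_covariance
    base = cmc.alpha_prior_parameters()
    d = build_design_matrix(cohort12["cov"])
    peb = peb_fit(cohort12["posteriors"], d, base, default_prior_covariance())
    eff = extract_effects(peb, "kbit")
    mean_eff = eff["effects"]["effect"].mean()
    assert mean_eff > 0
    assert abs(mean_eff - 0.4) < 0.2
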