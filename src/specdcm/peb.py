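"""Parametric empirical Bayes (PEB) and Bayesian model reduction (BMR).

Second level of the hierarchical analysis: subject-level Gaussian posteriors
over CMC parameters are explained by a between-subject linear model
theta_i = prior_mean + B' x_i + eps_i, where x_i is the i-th row of a design
matrix (cognitive score, orthogonalized age, their interaction and two
nuisance regressors, plus an intercept) and eps_i are random effects.
Candidate hypotheses about *which* connection classes (forward, backward,
intrinsic self-inhibition) carry between-subject effects are scored without
refitting via Bayesian model reduction over the group-level effect
posterior: switching a class off amounts to shrinking the prior variance of
its effect entries to zero, for which the change in free energy and the
reduced posterior are available in closed form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmc import CMCParameters, NODES
from .inversion import SubjectPosterior

__all__ = [
    "DesignMatrix",
    "ModelSpace",
    "PEBResult",
    "orthogonalize_age",
    "build_design_matrix",
    "peb_fit",
    "bayesian_model_reduction",
    "compare_model_space",
    "extract_effects",
    "exhaustive_bmr_search",
]

EFFECT_COLUMNS_DEFAULT = ("kbit", "age_orth", "kbit_x_age")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def orthogonalize_age(kbit: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Residuals of age regressed on the cognitive score (with intercept).

    The returned component is exactly orthogonal to the score and mean-zero,
    so the score keeps all shared variance (it is the outcome of interest)
    and age only explains what the score cannot.
    """
    k = np.asarray(kbit, dtype=float)
    a = np.asarray(age, dtype=float)
    if len(k) != len(a) or len(k) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(k) == 0:
        raise ValueError("constant score: orthogonalization slope undefined")
    X = np.column_stack([np.ones_like(k), k])
    beta, *_ = np.linalg.lstsq(X, a, rcond=None)
    return a - X @ beta


@dataclass
class DesignMatrix:
    """Between-subject design with named columns.

    ``effect_columns`` are the regressors of interest whose effects are
    switched on/off during model comparison; the intercept and nuisance
    columns are retained in every candidate model.
    """

    X: np.ndarray
    columns: list
    effect_columns: tuple = EFFECT_COLUMNS_DEFAULT

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape does not match column names")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        missing = [c for c in self.effect_columns if c not in self.columns]
        if missing:
            raise ValueError(f"effect columns not in design: {missing}")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]


def build_design_matrix(covariates: pd.DataFrame) -> DesignMatrix:
    """Six-column design from a covariate table.

    Columns: intercept; mean-centred standardized score; age orthogonalized
    to the score; their interaction; counterbalancing-order rank and a
    split/whole-block indicator as mean-centred nuisance regressors.
    Continuous columns are scaled to unit standard deviation (effects are
    per SD).
    """
    need = {"kbit_raw", "age", "order", "protocol"}
    if not need.issubset(covariates.columns):
        raise ValueError(f"covariates need columns {sorted(need)}")
    k = covariates["kbit_raw"].to_numpy(dtype=float)
    a = covariates["age"].to_numpy(dtype=float)

    def z(v):
        v = v - v.mean()
        sd = v.std()
        return v / sd if sd > 0 else v

    kc = z(k)
    ao = orthogonalize_age(k, a)
    ao = z(ao) if ao.std() > 0 else ao
    inter = z(kc * ao) if (kc * ao).std() > 0 else kc * ao
    order = z(covariates["order"].to_numpy(dtype=float))
    proto = covariates["protocol"].to_numpy(dtype=float)
    proto = proto - proto.mean()
    X = np.column_stack([np.ones_like(kc), kc, ao, inter, order, proto])
    cols = ["intercept", "kbit", "age_orth", "kbit_x_age",
            "order_nuisance", "protocol_nuisance"]
    return DesignMatrix(X=X, columns=cols)


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------


def bayesian_model_reduction(prior_mean, prior_cov, post_mean, post_cov,
                             red_mean, red_cov):
    """Evidence change and posterior under a replaced (reduced) prior.

    For Gaussian prior/posterior and any replacement prior over the same
    parameters, the change in log evidence and the implied posterior are
    available in closed form.  Returns (delta_F, reduced_mean, reduced_cov).

    Raises ValueError if the implied reduced posterior precision is not
    positive definite (the replacement prior is incompatible with the
    posterior), with the offending eigenvalue in the message.
    """
    mu0 = np.asarray(prior_mean, float)
    mu = np.asarray(post_mean, float)
    nu = np.asarray(red_mean, float)
    Pi0 = np.linalg.inv(np.asarray(prior_cov, float))
    P = np.linalg.inv(np.asarray(post_cov, float))
    Pir = np.linalg.inv(np.asarray(red_cov, float))

    Pr = P + Pir - Pi0
    evals = np.linalg.eigvalsh(0.5 * (Pr + Pr.T))
    if evals.min() <= 0:
        raise ValueError(
            "reduced posterior precision is indefinite "
            f"(min eigenvalue {evals.min():.3g}); the reduced prior is "
            "incompatible with the full posterior")
    mr = np.linalg.solve(Pr, P @ mu + Pir @ nu - Pi0 @ mu0)

    def _ld(M):
        sign, ld = np.linalg.slogdet(M)
        if sign <= 0:
            raise ValueError("non-positive-definite matrix in BMR")
        return ld

    dF = 0.5 * (_ld(Pir) - _ld(Pi0) + _ld(P) - _ld(Pr)) + 0.5 * (
        mr @ Pr @ mr - mu @ P @ mu + mu0 @ Pi0 @ mu0 - nu @ Pir @ nu)
    return float(dF), mr, np.linalg.inv(Pr)


# ---------------------------------------------------------------------------
# Model space
# ---------------------------------------------------------------------------

CONNECTION_CLASSES = ("forward", "backward", "intrinsic")


@dataclass
class ModelSpace:
    """Seven candidate models: non-empty subsets of {F, B, I}.

    Each candidate allows between-subject effects of the regressors of
    interest only on the listed connection classes; the intrinsic-only
    candidate is labelled "i".
    """

    candidates: list = field(default_factory=lambda: [
        ("forward",),
        ("backward",),
        ("forward", "backward"),
        ("intrinsic",),
        ("forward", "intrinsic"),
        ("backward", "intrinsic"),
        ("forward", "backward", "intrinsic"),
    ])

    def __post_init__(self):
        if len(self.candidates) != 7:
            raise ValueError("the model space has exactly 7 candidates")
        seen = set()
        for c in self.candidates:
            s = frozenset(c)
            if not s or not s.issubset(CONNECTION_CLASSES) or s in seen:
                raise ValueError("candidates must be distinct non-empty "
                                 "subsets of {forward, backward, intrinsic}")
            seen.add(s)

    @staticmethod
    def label(classes) -> str:
        short = {"forward": "f", "backward": "b", "intrinsic": "i"}
        return "".join(short[c] for c in CONNECTION_CLASSES if c in classes)

    @property
    def labels(self) -> list:
        return [self.label(c) for c in self.candidates]


# ---------------------------------------------------------------------------
# PEB fit
# ---------------------------------------------------------------------------


def _selected_indices(classes) -> tuple[np.ndarray, list]:
    names = CMCParameters.names()
    idx = [i for i, nm in enumerate(names)
           if CMCParameters.parameter_class(nm) in classes]
    if not idx:
        raise ValueError(f"no parameters belong to classes {classes!r}")
    return np.array(idx), [names[i] for i in idx]


@dataclass
class PEBResult:
    """Group-level effect posterior and model-comparison bookkeeping.

    ``beta_mean``/``beta_covariance`` are over the stacked effect vector
    (one block of selected parameters per design column, column-major in
    design order); ``free_energy`` is the group free energy of the full
    model.  Candidate free energies and posterior probabilities are filled
    by :func:`compare_model_space`.
    """

    beta_mean: np.ndarray
    beta_covariance: np.ndarray
    free_energy: float
    design: DesignMatrix
    param_names: list
    param_indices: np.ndarray
    classes: tuple
    beta_prior_cov: np.ndarray
    gamma: float
    psi: np.ndarray
    prior_mean_sel: np.ndarray
    subject_means: np.ndarray
    subject_fitted: np.ndarray
    model_free_energies: dict = field(default_factory=dict)
    model_posteriors: dict = field(default_factory=dict)

    def beta_block(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        """(mean, covariance) of the effect block for one design column."""
        j = self.design.columns.index(column)
        s = len(self.param_names)
        sl = slice(j * s, (j + 1) * s)
        return self.beta_mean[sl], self.beta_covariance[sl, sl]


def _peb_quadratics(mus, Ps, Pi0s, mu0s, Pir):
    """Per-subject quadratic coefficients of the BMR evidence in nu."""
    A, gvec, const = [], [], 0.0
    ld_Pir = np.linalg.slogdet(Pir)[1]
    ld_Pi0 = np.linalg.slogdet(Pi0s)[1]
    for mu_i, P_i in zip(mus, Ps):
        Pir_full = P_i + Pir - Pi0s
        evals = np.linalg.eigvalsh(0.5 * (Pir_full + Pir_full.T))
        if evals.min() <= 0:
            raise ValueError("indefinite implied precision in PEB")
        b = P_i @ mu_i - Pi0s @ mu0s
        Minv = np.linalg.inv(Pir_full)
        A.append(Pir @ Minv @ Pir - Pir)
        gvec.append(Pir @ (Minv @ b))
        const += 0.5 * (ld_Pir - ld_Pi0
                        + np.linalg.slogdet(P_i)[1]
                        - np.linalg.slogdet(Pir_full)[1]
                        + b @ Minv @ b
                        - mu_i @ P_i @ mu_i + mu0s @ Pi0s @ mu0s)
    return A, gvec, const


def _peb_free_energy(X, A, gvec, const, mu0s, Sb_inv):
    """Maximize the quadratic group objective; return (F, beta, Pbeta)."""
    n, c = X.shape
    s = A[0].shape[0]
    H = np.zeros((c * s, c * s))
    grad = np.zeros(c * s)
    for i in range(n):
        xi = X[i]
        nu0 = mu0s  # offset: nu_i = mu0s + B' x_i
        Gi = gvec[i] + A[i] @ nu0
        H += np.kron(np.outer(xi, xi), A[i])
        for j in range(c):
            grad[j * s:(j + 1) * s] += xi[j] * Gi
        const += 0.5 * nu0 @ A[i] @ nu0 + gvec[i] @ nu0
    Pb = Sb_inv - H
    beta = np.linalg.solve(Pb, grad)
    sign, ld_Pb = np.linalg.slogdet(Pb)
    if sign <= 0:
        raise ValueError("group-level posterior precision not PD")
    _, ld_Sb_inv = np.linalg.slogdet(Sb_inv)
    F = const + 0.5 * beta @ grad + 0.5 * ld_Sb_inv - 0.5 * ld_Pb
    return float(F), beta, Pb


def peb_fit(posteriors: list[SubjectPosterior], design: DesignMatrix,
            prior_mean: CMCParameters, prior_cov: np.ndarray,
            classes: tuple = CONNECTION_CLASSES,
            gamma_grid: np.ndarray | None = None,
            gamma_prior_var: float = 1.0,
            beta_prior_var: float = 1.0 / 16.0) -> PEBResult:
    """Fit the between-subject model over the selected connection classes.

    The subject-level marginal posteriors over the selected parameters are
    combined with the group model nu_i = prior + B' x_i and random-effect
    covariance Psi = exp(-gamma) * prior/16; gamma (a scalar log-precision)
    is optimized on a grid by free-energy ascent with a Gaussian hyperprior.
    Deterministic; the group free energy is exact for this linear-Gaussian
    level (no iteration needed beyond the gamma line search).
    """
    if len(posteriors) < 3:
        raise ValueError("need at least 3 subjects")
    if design.n_subjects != len(posteriors):
        raise ValueError("design rows must match the number of subjects")
    names0 = posteriors[0].names
    for p in posteriors:
        if p.names != names0:
            raise ValueError("subject posteriors have mismatched "
                             "parameter layouts")
    idx, sel_names = _selected_indices(classes)
    mu0s = prior_mean.to_vector()[idx]
    S0s = np.asarray(prior_cov)[np.ix_(idx, idx)]
    Pi0s = np.linalg.inv(S0s)
    mus = [p.mean[idx] for p in posteriors]
    Ps = [np.linalg.inv(p.covariance[np.ix_(idx, idx)]) for p in posteriors]

    s = len(idx)
    c = len(design.columns)
    # group-effect prior: zero mean with one shared variance for every
    # (column, parameter) entry, so model comparison over connection classes
    # is not biased by unequal first-level prior widths
    Sb = np.diag(np.full(c * s, beta_prior_var))
    Sb_inv = np.linalg.inv(Sb)

    if gamma_grid is None:
        gamma_grid = np.linspace(-3.0, 5.0, 17)
    best = None
    for gamma in gamma_grid:
        Psi = S0s / 16.0 * np.exp(-gamma)
        Pir = np.linalg.inv(Psi)
        try:
            A, gvec, const = _peb_quadratics(mus, Ps, Pi0s, mu0s, Pir)
            F, beta, Pb = _peb_free_energy(design.X, A, gvec, const, mu0s,
                                           Sb_inv)
        except (ValueError, np.linalg.LinAlgError):
            continue
        F -= 0.5 * gamma ** 2 / gamma_prior_var
        if best is None or F > best[0]:
            best = (F, float(gamma), beta, Pb, Psi)
    if best is None:
        raise ValueError("no admissible between-subject precision found")
    F, gamma, beta, Pb, Psi = best
    Sigma_b = np.linalg.inv(Pb)
    Sigma_b = 0.5 * (Sigma_b + Sigma_b.T)

    # empirical-Bayes subject estimates under the fitted group model
    B = beta.reshape(c, s)
    Pir = np.linalg.inv(Psi)
    fitted = design.X @ B + mu0s  # group prediction per subject
    subj = []
    for mu_i, P_i, nu_i in zip(mus, Ps, fitted):
        Pr_i = P_i + Pir - Pi0s
        subj.append(np.linalg.solve(
            Pr_i, P_i @ mu_i + Pir @ nu_i - Pi0s @ mu0s))
    return PEBResult(
        beta_mean=beta, beta_covariance=Sigma_b, free_energy=F,
        design=design, param_names=sel_names, param_indices=idx,
        classes=tuple(classes), beta_prior_cov=Sb, gamma=gamma, psi=Psi,
        prior_mean_sel=mu0s, subject_means=np.array(mus),
        subject_fitted=np.array(subj))


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

_OFF_VARIANCE = 1e-8


def _reduced_beta_prior(peb: PEBResult, keep_classes) -> np.ndarray:
    """Shrink effect-of-interest priors for classes outside the candidate.

    The intercept and nuisance columns keep their priors in every candidate;
    only the regressors of interest are switched off, and only on the
    parameters of the excluded connection classes.
    """
    s = len(peb.param_names)
    Sb_r = peb.beta_prior_cov.copy()
    keep = set(keep_classes)
    for j, col in enumerate(peb.design.columns):
        if col not in peb.design.effect_columns:
            continue
        for k, pname in enumerate(peb.param_names):
            if CMCParameters.parameter_class(pname) not in keep:
                ent = j * s + k
                Sb_r[ent, :] = 0.0
                Sb_r[:, ent] = 0.0
                Sb_r[ent, ent] = _OFF_VARIANCE
    return Sb_r


def compare_model_space(peb: PEBResult, space: ModelSpace | None = None
                        ) -> PEBResult:
    """Score every candidate by BMR on the group-effect posterior.

    Adds per-candidate free energies (relative to the weakest candidate)
    and softmax posterior probabilities to the PEB result; the Bayes factor
    between two candidates is exp of their free-energy difference.
    """
    space = space or ModelSpace()
    if not space.candidates:
        raise ValueError("empty model space")
    zeros = np.zeros_like(peb.beta_mean)
    dFs = {}
    posts = {}
    for cand in space.candidates:
        label = space.label(cand)
        Sb_r = _reduced_beta_prior(peb, cand)
        dF, mr, Sr = bayesian_model_reduction(
            zeros, peb.beta_prior_cov, peb.beta_mean, peb.beta_covariance,
            zeros, Sb_r)
        dFs[label] = peb.free_energy + dF
        posts[label] = (mr, Sr)
    fvals = np.array([dFs[lb] for lb in space.labels])
    p = np.exp(fvals - fvals.max())
    p /= p.sum()
    peb.model_free_energies = dict(zip(space.labels, fvals))
    peb.model_posteriors = {
        lb: {"mean": posts[lb][0], "cov": posts[lb][1], "probability": pi}
        for lb, pi in zip(space.labels, p)}
    return peb


def exhaustive_bmr_search(peb: PEBResult, entries: list[int],
                          max_entries: int = 14) -> list[dict]:
    """Score all on/off combinations of individual effect entries by BMR.

    Provided for completeness (greedy pruning over arbitrary subsets); the
    headline comparison uses the neurobiologically motivated seven-model
    space instead.
    """
    if len(entries) > max_entries:
        raise ValueError(f"refusing exhaustive search over {len(entries)} "
                         f"entries (> {max_entries})")
    zeros = np.zeros_like(peb.beta_mean)
    out = []
    for mask in itertools.product([False, True], repeat=len(entries)):
        Sb_r = peb.beta_prior_cov.copy()
        for on, ent in zip(mask, entries):
            if not on:
                Sb_r[ent, :] = 0.0
                Sb_r[:, ent] = 0.0
                Sb_r[ent, ent] = _OFF_VARIANCE
        dF, _, _ = bayesian_model_reduction(
            zeros, peb.beta_prior_cov, peb.beta_mean, peb.beta_covariance,
            zeros, Sb_r)
        out.append({"mask": mask, "delta_F": dF})
    return sorted(out, key=lambda d: -d["delta_F"])


# ---------------------------------------------------------------------------
# Effect extraction
# ---------------------------------------------------------------------------


def extract_effects(peb: PEBResult, column: str, nodes=NODES,
                    ci: float = 0.90) -> dict:
    """Per-node intrinsic self-inhibition effects of one design column.

    Returns the posterior effect mean and central Bayesian credible
    interval per node, and the per-subject empirical-Bayes estimates of the
    intrinsic parameters for scatter plots against the covariate.
    """
    if column not in peb.design.columns:
        raise ValueError(f"column {column!r} not in design "
                         f"{peb.design.columns}")
    from scipy.stats import norm
    zq = norm.ppf(0.5 + ci / 2.0)
    bm, bc = peb.beta_block(column)
    rows = []
    for node in nodes:
        pname = f"g1_{node}"
        if pname not in peb.param_names:
            raise ValueError(f"intrinsic parameter {pname} not in PEB "
                             "selection; include 'intrinsic' in classes")
        k = peb.param_names.index(pname)
        se = float(np.sqrt(max(bc[k, k], 0.0)))
        rows.append({"node": node, "effect": float(bm[k]),
                     "ci_low": float(bm[k] - zq * se),
                     "ci_high": float(bm[k] + zq * se)})
    g1_cols = [peb.param_names.index(f"g1_{n}") for n in nodes]
    per_subject = peb.subject_fitted[:, g1_cols]
    return {"column": column, "ci": ci, "effects": pd.DataFrame(rows),
            "per_subject_g1": per_subject,
            "covariate": peb.design.column(column)}
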