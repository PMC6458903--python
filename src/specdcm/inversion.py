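"""Subject-level model inversion: CSD features and variational Laplace.

The complex cross-spectral density of multichannel EEG is summarized in a
reduced basis of principal spatial eigenmodes and explained by the
linearized CMC network model.  Fitting uses Gauss-Newton ascent on a
variational free energy under the Laplace approximation, with
Levenberg-style damping, an observation-precision hyperparameter updated
each outer iteration, and a Gaussian prior over the log-scaling parameter
deviations.  The free energy (accuracy minus complexity) approximates the
log model evidence and is the currency of all model comparisons downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cmc import (
    CMCParameters,
    CrossSpectralData,
    NetworkModel,
    assemble_system,
    default_freqs,
    predict_csd,
)
from .errors import SubjectExcludedError, UnstableModelError

__all__ = [
    "InversionConfig",
    "SubjectPosterior",
    "default_prior_covariance",
    "extract_csd_features",
    "variational_laplace",
    "free_energy",
    "csd_to_vector",
]

MIN_EPOCHS = 12  # inclusion rule: subjects need at least 12 clean 2-s epochs


@dataclass
class InversionConfig:
    """Settings for feature extraction and variational Laplace."""

    n_eigenmodes: int = 8
    fmin: float = 1.0
    fmax: float = 30.0
    df: float = 0.5
    max_iterations: int = 64
    tol: float = 0.01          # nats; |dF| < tol for 3 iterations => converged
    update_precision: bool = True
    lambda_prior_var: float = 16.0   # log-normal hyperprior width on precision
    lambda_step_max: float = 1.0     # max log-precision change per iteration
    fd_step: float = 1e-3            # finite-difference step for the Jacobian

    def __post_init__(self):
        if self.n_eigenmodes < 1:
            raise ValueError("n_eigenmodes must be >= 1")
        if self.tol <= 0:
            raise ValueError("convergence tolerance must be > 0")

    def freqs(self) -> np.ndarray:
        return default_freqs(self.fmin, self.fmax, self.df)


@dataclass
class SubjectPosterior:
    """Gaussian posterior over flattened parameters, plus free energy."""

    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    fit_diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    names: list = field(default_factory=CMCParameters.names)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.isfinite(self.mean).all():
            raise ValueError("posterior mean must be finite")
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")
        asym = np.linalg.norm(self.covariance - self.covariance.T)
        if asym > 1e-8 * max(np.linalg.norm(self.covariance), 1e-300):
            raise ValueError("posterior covariance must be symmetric")

    def parameters(self) -> CMCParameters:
        return CMCParameters.from_vector(self.mean)


def default_prior_covariance() -> np.ndarray:
    """Diagonal prior covariance over parameter deviations.

    1/16 on rate constants, intrinsic gains and the sigmoid slope; 1/8 on
    extrinsic gains and noise amplitudes; tighter 1/64 on lead-field gains
    and noise spectral exponents, which are nuisance quantities whose
    looseness would otherwise absorb genuine gain effects.
    """
    var = []
    for name in CMCParameters.names():
        cls = CMCParameters.parameter_class(name)
        if cls in ("forward", "backward", "lateral"):
            var.append(1.0 / 8.0)
        elif cls == "noise":
            var.append(1.0 / 64.0 if "beta" in name else 1.0 / 8.0)
        elif cls == "leadfield":
            var.append(1.0 / 64.0)
        else:
            var.append(1.0 / 16.0)
    return np.diag(var)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def extract_csd_features(epochs: np.ndarray, cfg: InversionConfig,
                         fs: float = 250.0) -> CrossSpectralData:
    """Complex CSD of epoched sensor data in a principal-eigenmode basis.

    Parameters
    ----------
    epochs : array (n_epochs, n_channels, n_times)
        Clean 2-s epochs.
    cfg : InversionConfig
        Number of eigenmodes and frequency grid.
    fs : float
        Sampling frequency in Hz.

    Returns
    -------
    CrossSpectralData
        Hermitian m-by-m cross-spectra on the configured grid, where m is
        ``cfg.n_eigenmodes`` (or fewer if the sensor covariance is
        rank-deficient, with a warning).

    Raises
    ------
    SubjectExcludedError
        If fewer than 12 epochs are supplied (the study inclusion rule).
    """
    X = np.asarray(epochs, dtype=float)
    if X.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_channels, n_times)")
    n_epochs, n_ch, _ = X.shape
    if n_epochs < MIN_EPOCHS:
        raise SubjectExcludedError(
            f"subject excluded: {n_epochs} epochs < required {MIN_EPOCHS}")
    if cfg.n_eigenmodes > n_ch:
        raise ValueError("n_eigenmodes cannot exceed the channel count")

    flat = X.transpose(1, 0, 2).reshape(n_ch, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    cov = flat @ flat.T / flat.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > 1e-12 * max(evals[0], 1e-300)))
    m = min(cfg.n_eigenmodes, rank)
    if m < cfg.n_eigenmodes:
        warnings.warn(
            f"sensor covariance rank {rank} < requested {cfg.n_eigenmodes} "
            f"eigenmodes; returning {m}", RuntimeWarning)
    U = evecs[:, :m]
    # deterministic sign: largest-magnitude loading positive
    for k in range(m):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]

    proj = np.einsum("cm,ect->emt", U, X)

    from mne.time_frequency import csd_array_multitaper
    csd = csd_array_multitaper(
        proj, sfreq=fs, fmin=max(cfg.fmin - 0.25, 0.25), fmax=cfg.fmax + 0.25,
        bandwidth=3.0, verbose="error")
    cf = np.asarray(csd.frequencies, dtype=float)
    want = cfg.freqs()
    mats, freqs = [], []
    for f0 in want:
        k = int(np.argmin(np.abs(cf - f0)))
        if abs(cf[k] - f0) < cfg.df / 2:
            G = csd.get_data(index=k)
            mats.append(0.5 * (G + G.conj().T))
            freqs.append(cf[k])
    return CrossSpectralData(freqs=np.array(freqs), csd=np.array(mats),
                             n_eigenmodes=m)


# ---------------------------------------------------------------------------
# Data vectorization
# ---------------------------------------------------------------------------


def csd_to_vector(csd: np.ndarray) -> np.ndarray:
    """Stack upper-triangular CSD entries as a real vector.

    Layout per frequency: real parts of all i <= j entries, then imaginary
    parts of all i < j entries (the diagonal is real for Hermitian input).
    """
    G = np.asarray(csd)
    m = G.shape[-1]
    iu, ju = np.triu_indices(m)
    io, jo = np.triu_indices(m, k=1)
    re = G[..., iu, ju].real
    im = G[..., io, jo].imag
    return np.concatenate([re.ravel(), im.ravel()])


# ---------------------------------------------------------------------------
# Generic Gauss-Newton variational Laplace engine
# ---------------------------------------------------------------------------


def _finite_diff_jacobian(g: Callable[[np.ndarray], np.ndarray],
                          mu: np.ndarray, g0: np.ndarray,
                          step: float) -> np.ndarray:
    p = len(mu)
    J = np.zeros((len(g0), p))
    for i in range(p):
        d = np.zeros(p)
        d[i] = step
        try:
            gi = g(mu + d)
            J[:, i] = (gi - g0) / step
            continue
        except UnstableModelError:
            pass
        try:
            gi = g(mu - d)
            J[:, i] = (g0 - gi) / step
        except UnstableModelError:
            J[:, i] = 0.0  # parameter direction blocked by stability boundary
    return J


def _free_energy_terms(y, g_mu, J, Sigma, mu, mu0, Pi0, lam, lam0, lam_var):
    n_d = len(y)
    r = y - g_mu
    h = np.exp(lam)
    acc = (-0.5 * h * (r @ r + np.einsum("ij,jk,ik->", J, Sigma, J))
           + 0.5 * n_d * (lam - np.log(2.0 * np.pi)))
    dmu = mu - mu0
    sign, logdet_S = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf
    _, logdet_S0 = np.linalg.slogdet(np.linalg.inv(Pi0))
    kl_theta = 0.5 * (np.trace(Pi0 @ Sigma) + dmu @ Pi0 @ dmu
                      - len(mu) + logdet_S0 - logdet_S)
    kl_lambda = 0.5 * (lam - lam0) ** 2 / lam_var
    return acc - kl_theta - kl_lambda


def _update_lambda(lam, lam0, lam_var, n_d, sq_term):
    """Newton steps on dF/dlam = n_d/2 - exp(lam)/2 * sq - (lam-lam0)/var."""
    for _ in range(8):
        h = np.exp(lam)
        grad = 0.5 * n_d - 0.5 * h * sq_term - (lam - lam0) / lam_var
        hess = -0.5 * h * sq_term - 1.0 / lam_var
        step = grad / hess
        lam = lam - np.clip(step, -4.0, 4.0)
    return float(lam)


def gauss_newton_vl(y: np.ndarray, g: Callable[[np.ndarray], np.ndarray],
                    mu0: np.ndarray, Sigma0: np.ndarray,
                    cfg: InversionConfig,
                    jacobian: Callable[[np.ndarray], np.ndarray] | None = None,
                    fixed_lambda: float | None = None) -> SubjectPosterior:
    """Variational Laplace for y = g(theta) + e, e ~ N(0, exp(-lam) I).

    Gauss-Newton ascent on the free energy with Levenberg damping: steps
    that do not increase F are rejected and the damping increased.  Returns
    the Gaussian posterior, the converged free energy and a diagnostics
    dict including the trajectory of accepted free energies.
    """
    y = np.asarray(y, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    n_d, p = len(y), len(mu0)
    Pi0 = np.linalg.inv(Sigma0)
    sign0, _ = np.linalg.slogdet(Sigma0)
    if sign0 <= 0:
        raise ValueError("prior covariance must be positive definite")

    mu = mu0.copy()
    g_mu = g(mu)
    r = y - g_mu
    if fixed_lambda is not None:
        lam = lam0 = float(fixed_lambda)
        lam_var = np.inf
    else:
        lam = lam0 = float(np.log(n_d / max(r @ r, 1e-12 * n_d)))
        lam_var = cfg.lambda_prior_var

    jac = jacobian if jacobian is not None else (
        lambda m_: _finite_diff_jacobian(g, m_, g(m_), cfg.fd_step))

    def posterior_cov(J, lam_):
        P = np.exp(lam_) * (J.T @ J) + Pi0
        return np.linalg.inv(P), P

    J = jac(mu)
    Sigma, P = posterior_cov(J, lam)
    F = _free_energy_terms(y, g_mu, J, Sigma, mu, mu0, Pi0, lam, lam0, lam_var)
    trajectory = [F]
    damping = 1e-4
    n_small = 0
    converged = False

    for _ in range(cfg.max_iterations):
        if fixed_lambda is None and cfg.update_precision:
            sq = r @ r + np.einsum("ij,jk,ik->", J, Sigma, J)
            lam_new = _update_lambda(lam, lam0, lam_var, n_d, sq)
            # clamp hyperparameter moves: prevents the precision racing ahead
            # of the parameter estimates early in the ascent
            lam = float(np.clip(lam_new, lam - cfg.lambda_step_max,
                                lam + cfg.lambda_step_max))
            Sigma, P = posterior_cov(J, lam)
            F = _free_energy_terms(y, g_mu, J, Sigma, mu, mu0, Pi0,
                                   lam, lam0, lam_var)

        h = np.exp(lam)
        grad = h * (J.T @ r) - Pi0 @ (mu - mu0)
        accepted = False
        for _inner in range(16):
            H = P + damping * np.diag(np.diag(P))
            try:
                delta = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                damping *= 8.0
                continue
            mu_c = mu + delta
            try:
                g_c = g(mu_c)
            except UnstableModelError:
                damping *= 8.0
                continue
            Sigma_c, P_c = posterior_cov(J, lam)
            F_c = _free_energy_terms(y, g_c, J, Sigma_c, mu_c, mu0, Pi0,
                                     lam, lam0, lam_var)
            if F_c > trajectory[-1]:
                accepted = True
                break
            damping *= 8.0
        if not accepted:
            break

        dF = F_c - trajectory[-1]
        mu, g_mu = mu_c, g_c
        r = y - g_mu
        damping = max(damping / 8.0, 1e-6)
        J = jac(mu)
        Sigma, P = posterior_cov(J, lam)
        trajectory.append(F_c)
        F = F_c
        if abs(dF) < cfg.tol:
            n_small += 1
            if n_small >= 3:
                converged = True
                break
        else:
            n_small = 0

    # final consistent evaluation at the posterior mean
    F_final = _free_energy_terms(y, g_mu, J, Sigma, mu, mu0, Pi0,
                                 lam, lam0, lam_var)
    Sigma = 0.5 * (Sigma + Sigma.T)
    diagnostics = {
        "f_trajectory": np.array(trajectory),
        "lambda": lam,
        "lambda_prior_mean": lam0,
        "lambda_prior_var": lam_var,
        "n_data": n_d,
        "residual_rss": float(r @ r),
        "predicted": g_mu.copy(),
        "observed": y.copy(),
    }
    return SubjectPosterior(mean=mu, covariance=Sigma, free_energy=float(F_final),
                            fit_diagnostics=diagnostics, converged=converged)


# ---------------------------------------------------------------------------
# CMC-specific wrappers
# ---------------------------------------------------------------------------


def _frequency_weights(data: CrossSpectralData) -> np.ndarray:
    """Per-frequency variance-stabilizing weights for the stacked data vector.

    Cross-spectral sampling noise is multiplicative (relative to the local
    power), whereas the likelihood assumes homoscedastic residuals; weighting
    each frequency by the inverse of its mean observed power makes the two
    consistent and stops the spectral peak from dominating the fit.  The
    weights are fixed functions of the data, so this is ordinary weighted
    least squares inside the free energy.
    """
    m = data.csd.shape[1]
    mean_diag = np.einsum("fii->f", data.csd).real / m
    if np.any(mean_diag <= 0):
        raise ValueError("data CSD has non-positive mean power at some frequency")
    wf = 1.0 / mean_diag
    n_re = m * (m + 1) // 2
    n_im = m * (m - 1) // 2
    return np.concatenate([np.repeat(wf, n_re), np.repeat(wf, n_im)])


def _make_predictor(net: NetworkModel, freqs: np.ndarray, m: int,
                    weights: np.ndarray):
    def g(vec: np.ndarray) -> np.ndarray:
        params = CMCParameters.from_vector(vec)
        sys = assemble_system(params, net, n_outputs=m)
        pred = predict_csd(sys, params, freqs)
        return csd_to_vector(pred.csd) * weights
    return g


def variational_laplace(data: CrossSpectralData,
                        prior_mean: CMCParameters,
                        prior_cov: np.ndarray,
                        net: NetworkModel,
                        cfg: InversionConfig) -> SubjectPosterior:
    """Invert the CMC network model for one subject's cross-spectral data.

    The stacked complex cross-spectra are fitted under per-frequency
    variance-stabilizing weights (EEG units are arbitrary and CSD sampling
    noise is relative, so each frequency is normalized by its mean observed
    power).  Deterministic given its inputs.
    """
    freqs = np.asarray(data.freqs, dtype=float)
    m = data.csd.shape[1]
    mu0 = prior_mean.to_vector()

    w = _frequency_weights(data)
    g = _make_predictor(net, freqs, m, w)
    y = csd_to_vector(data.csd) * w

    post = gauss_newton_vl(y, g, mu0, prior_cov, cfg)
    post.fit_diagnostics["freqs"] = freqs
    return post


def free_energy(posterior: SubjectPosterior, data: CrossSpectralData,
                prior_mean: CMCParameters, prior_cov: np.ndarray,
                net: NetworkModel, cfg: InversionConfig) -> float:
    """Recompute the variational free energy at a stored posterior.

    Uses the same linearization and hyperparameter bookkeeping as
    :func:`variational_laplace`; at the final iterate of an inversion it
    reproduces the stored ``free_energy``.
    """
    sign, _ = np.linalg.slogdet(posterior.covariance)
    if sign <= 0:
        raise ValueError("posterior covariance must be positive definite")
    freqs = np.asarray(data.freqs, dtype=float)
    m = data.csd.shape[1]
    mu0 = prior_mean.to_vector()
    Pi0 = np.linalg.inv(prior_cov)

    w = _frequency_weights(data)
    g = _make_predictor(net, freqs, m, w)
    y = csd_to_vector(data.csd) * w
    mu = posterior.mean
    g_mu = g(mu)
    J = _finite_diff_jacobian(g, mu, g_mu, cfg.fd_step)
    lam = posterior.fit_diagnostics.get("lambda", 0.0)
    lam0 = posterior.fit_diagnostics.get("lambda_prior_mean", lam)
    lam_var = posterior.fit_diagnostics.get("lambda_prior_var",
                                            cfg.lambda_prior_var)
    h = np.exp(lam)
    Sigma = np.linalg.inv(h * (J.T @ J) + Pi0)
    return float(_free_energy_terms(y, g_mu, J, Sigma, mu, mu0, Pi0,
                                    lam, lam0, lam_var))
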