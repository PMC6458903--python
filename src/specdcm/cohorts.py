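"""Synthetic cohorts for construct-validity simulation and sensor analysis.

Two kinds of data are generated, mirroring the statistical structure the
analysis assumes:

* model-space cohorts: a baseline six-node CMC parameterization is combined
  with a standard-normal between-subject regressor that modulates a chosen
  connection class (intrinsic self-inhibition by default), plus small
  random-effect jitter on all parameters; per-subject cross-spectral
  densities are predicted from each model and perturbed by a
  Hermitian-preserving (complex-Wishart-style) sampling noise;

* sensor cohorts: epoched multichannel EEG built from stochastic ~10 Hz and
  ~5 Hz oscillators with posterior-alpha / frontal-theta topographies over a
  1/f background, where the theta-alpha oscillator amplitude is linear in a
  per-subject cognitive score.

All generators are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .cmc import (
    CMCParameters,
    CrossSpectralData,
    NetworkModel,
    assemble_system,
    default_network,
    predict_csd,
    alpha_prior_parameters,
)
from .errors import UnstableModelError
from . import spectral

__all__ = [
    "CohortSpec",
    "generate_cohort_models",
    "generate_cohort_csds",
    "generate_covariate_table",
    "generate_sensor_cohort",
]

#: cohort descriptives echoed from the study population (score mean/SD and
#: range, age range in years)
KBIT_MEAN, KBIT_SD = 54.84, 19.64
KBIT_RANGE = (10.0, 102.0)
AGE_RANGE = (16.0, 56.0)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_subjects: int = 36
    target_classes: tuple = ("intrinsic",)
    effect_size: float = 0.4        # deviation units per regressor SD
    jitter_sd: float = 0.1          # random-effect SD on all parameters
    noise_level: float = 0.05       # relative CSD sampling noise (1/sqrt(dof))
    score_mean: float = KBIT_MEAN
    score_sd: float = KBIT_SD
    age_range: tuple = AGE_RANGE

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")
        if not self.target_classes:
            raise ValueError("target connection class must be non-empty")


def _class_indices(classes) -> np.ndarray:
    names = CMCParameters.names()
    idx = [i for i, nm in enumerate(names)
           if CMCParameters.parameter_class(nm) in classes]
    if not idx:
        raise ValueError(f"no parameters in classes {classes!r}")
    return np.array(idx)


def generate_cohort_models(base: CMCParameters, spec: CohortSpec, seed: int,
                           net: NetworkModel | None = None):
    """Per-subject models whose targeted parameters track a regressor.

    Subject i's targeted parameters equal base + effect_size * z_i plus
    N(0, jitter_sd^2) random effects on every parameter.  Unstable draws are
    resampled (new jitter) up to 10 times; persistent instability is
    reported with the offending subject index.

    Returns (models, regressor) with the standard-normal regressor z.
    """
    net = net or default_network()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(spec.n_subjects)
    z = (z - z.mean()) / max(z.std(), 1e-12)
    tgt = _class_indices(spec.target_classes)
    base_vec = base.to_vector()
    # the baseline itself must be admissible
    assemble_system(base, net)

    models = []
    for i in range(spec.n_subjects):
        ok = False
        for _attempt in range(10):
            vec = base_vec.copy()
            if spec.jitter_sd > 0:
                vec = vec + rng.normal(0.0, spec.jitter_sd, size=len(vec))
            vec[tgt] += spec.effect_size * z[i]
            params = CMCParameters.from_vector(vec)
            try:
                assemble_system(params, net)
            except UnstableModelError:
                continue
            ok = True
            break
        if not ok:
            raise UnstableModelError(
                f"subject {i}: no stable model in 10 jitter resamples")
        models.append(params)
    return models, z


def _wishart_perturb(G: np.ndarray, dof: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Sample mean of dof complex-Wishart draws with expectation G."""
    m = G.shape[0]
    evals, evecs = np.linalg.eigh(G)
    evals = np.clip(evals, 0.0, None)
    root = evecs * np.sqrt(evals)
    z = (rng.normal(size=(dof, m)) + 1j * rng.normal(size=(dof, m))) / np.sqrt(2)
    zs = z @ root.conj().T
    S = zs.conj().T @ zs / dof
    return 0.5 * (S + S.conj().T)


def generate_cohort_csds(models, net: NetworkModel, freqs: np.ndarray,
                         noise_level: float, seed: int,
                         n_eigenmodes: int = 8) -> list[CrossSpectralData]:
    """Predicted CSDs per subject with Hermitian-preserving sampling noise.

    ``noise_level`` is the relative fluctuation scale: each frequency's
    matrix is replaced by the average of ``dof ~ 1/noise_level**2``
    complex-Wishart draws with the predicted matrix as expectation (the
    natural noise model for a CSD estimated from finitely many epochs).
    noise_level = 0 returns the exact predictions.
    """
    if noise_level < 0:
        raise ValueError("noise level must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for params in models:
        sys = assemble_system(params, net, n_outputs=n_eigenmodes)
        pred = predict_csd(sys, params, freqs)
        if noise_level == 0:
            out.append(pred)
            continue
        dof = max(pred.csd.shape[1] + 1, int(round(1.0 / noise_level ** 2)))
        noisy = np.stack([_wishart_perturb(Gf, dof, rng) for Gf in pred.csd])
        out.append(CrossSpectralData(freqs=pred.freqs, csd=noisy,
                                     n_eigenmodes=pred.n_eigenmodes))
    return out


def generate_covariate_table(spec: CohortSpec, seed: int,
                             regressor: np.ndarray | None = None
                             ) -> pd.DataFrame:
    """Covariate CSV contents: subject_id, kbit_raw, age, order, protocol.

    The cognitive score realizes the regressor on the printed cohort scale
    (mean 54.84, SD 19.64, clipped to the 10-102 range); ages are uniform on
    16-56; counterbalancing order is a random permutation rank; protocol is
    a split-block/whole-block indicator.
    """
    rng = np.random.default_rng(seed + 1)
    n = spec.n_subjects
    z = regressor if regressor is not None else rng.standard_normal(n)
    kbit = np.clip(spec.score_mean + spec.score_sd * np.asarray(z),
                   *KBIT_RANGE)
    age = rng.uniform(*spec.age_range, size=n)
    order = rng.permutation(n) + 1
    protocol = (rng.random(n) < 20.0 / 36.0).astype(int)  # 1 = split block
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "kbit_raw": kbit,
        "age": age,
        "order": order,
        "protocol": protocol,
    })


# ---------------------------------------------------------------------------
# Sensor-level cohort
# ---------------------------------------------------------------------------


def _resonant_noise(f0: float, fs: float, n: int, rng, bandwidth: float = 1.2
                    ) -> np.ndarray:
    """Stochastic oscillator: white noise through a narrow resonator at f0."""
    r = np.exp(-np.pi * bandwidth / fs)
    a = [1.0, -2.0 * r * np.cos(2 * np.pi * f0 / fs), r ** 2]
    x = sp_signal.lfilter([1.0], a, rng.standard_normal(n))
    return x / max(x.std(), 1e-12)


def _one_over_f(fs: float, n: int, rng) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    z = (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs))) * amp
    x = np.fft.irfft(z, n=n)
    return x / max(x.std(), 1e-12)


def generate_sensor_cohort(spec: CohortSpec, channels: list[str] | None = None,
                           fs: float = 250.0, epochs_per_subject: int = 20,
                           seed: int = 0, amplitude_effect: float = 0.25,
                           epoch_seconds: float = 2.0):
    """Epoched sensor EEG whose theta-alpha content tracks the score.

    Each subject's record mixes a ~10 Hz stochastic oscillator with
    posterior-dominant topography and a ~5 Hz oscillator with frontal
    topography over spatially independent 1/f background noise.  Both
    oscillator amplitudes scale linearly with the subject's standardized
    score: amplitude_i = base * (1 + amplitude_effect * z_i).

    Returns (epochs, covariates, regressor): a list of per-subject arrays of
    shape (n_epochs, n_channels, n_times), the covariate table, and z.
    """
    if epochs_per_subject < 12:
        raise ValueError("fewer than 12 epochs per subject requested "
                         "(subjects would fail the inclusion rule)")
    channels = channels if channels is not None else spectral.usable_channels()
    pos = spectral.channel_positions_2d(channels)
    n_ch = len(channels)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(spec.n_subjects)
    z = (z - z.mean()) / max(z.std(), 1e-12)

    # topographies on the 2-D head disk: alpha posterior (y < 0), theta frontal
    alpha_topo = np.exp(-((pos[:, 0]) ** 2 + (pos[:, 1] + 0.7) ** 2) / 0.35)
    theta_topo = np.exp(-((pos[:, 0]) ** 2 + (pos[:, 1] - 0.7) ** 2) / 0.35)

    n_t = int(round(epoch_seconds * fs))
    n_total = epochs_per_subject * n_t
    cohort = []
    for i in range(spec.n_subjects):
        gain = max(1.0 + amplitude_effect * z[i], 0.05)
        alpha_src = 4.0 * gain * _resonant_noise(10.0, fs, n_total, rng)
        theta_src = 2.5 * gain * _resonant_noise(5.0, fs, n_total, rng)
        X = np.outer(alpha_topo, alpha_src) + np.outer(theta_topo, theta_src)
        for c in range(n_ch):
            X[c] += 1.0 * _one_over_f(fs, n_total, rng)
        X += 0.25 * rng.standard_normal(X.shape)
        cohort.append(X.reshape(n_ch, epochs_per_subject, n_t)
                      .transpose(1, 0, 2).copy())

    cov = generate_covariate_table(spec, seed, regressor=z)
    return cohort, cov, z


def construct_validity_cohort(seed: int, n_subjects: int = 36,
                      effect_size: float = 0.4,
                      noise_level: float = 0.05,
                      n_eigenmodes: int = 8,
                      freqs: np.ndarray | None = None,
                      target_classes: tuple = ("intrinsic",)):
    """Construct-validity cohort: baseline model + intrinsic-inhibition
    effects of a random regressor, realized as noisy cross-spectra.

    Returns (models, csds, covariates, regressor, net, base).
    """
    from .cmc import default_freqs
    net = default_network()
    base = alpha_prior_parameters()
    spec = CohortSpec(n_subjects=n_subjects, effect_size=effect_size,
                      noise_level=noise_level, target_classes=target_classes)
    models, z = generate_cohort_models(base, spec, seed, net)
    f = freqs if freqs is not None else default_freqs()
    csds = generate_cohort_csds(models, net, f, noise_level, seed + 1,
                                n_eigenmodes=n_eigenmodes)
    cov = generate_covariate_table(spec, seed, regressor=z)
    return models, csds, cov, z, net, base
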