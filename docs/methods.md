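# Methods

This note documents the models, estimators and numerical choices behind
`specdcm`, and what the synthetic-data experiments do and do not establish.

## The canonical microcircuit and the alpha network

Each cortical source contains four neuronal populations assigned to cortical
layers: spiny stellate cells (granular layer), superficial pyramidal cells,
inhibitory interneurons and deep pyramidal cells.  Population `p` obeys
second-order synaptic dynamics

    dv_p/dt = u_p
    du_p/dt = kappa_p * (sum_q w_pq * sigma(v_q) + input_p)
              - 2 kappa_p u_p - kappa_p^2 v_p

with `sigma(v) = expit(r v) - 1/2` a centred firing-rate sigmoid and
`kappa_p` the inverse synaptic time constant.  Intrinsic wiring: stellate
cells excite superficial pyramidal cells and interneurons; superficial
pyramidal cells excite interneurons and deep pyramidal cells; interneurons
inhibit all pyramidal populations and the stellate cells; every population
inhibits itself.  Three named intrinsic gains vary per node — `g1`
(superficial-pyramidal self-inhibition, the quantity of scientific
interest), `g2` (superficial-pyramidal-to-stellate inhibition) and `g3`
(interneuron-to-stellate inhibition).

Six sources form a bilateral hierarchy — V1, superior parietal lobule (SPL)
and middle frontal gyrus (MFG) in each hemisphere, at the MNI coordinates
used throughout the package.  Excitatory extrinsic connections: forward
V1->SPL->MFG (targeting granular and deep layers), backward the reverse
(targeting superficial pyramidal cells and interneurons), and bidirectional
interhemispheric lateral connections between homologous nodes (treated like
forward connections); there is no direct V1->MFG edge.

**Parameterization.**  Every subject-specific parameter is a dimensionless
log-scaling deviation on a fixed base constant, so 0 is the canonical
circuit and Gaussian priors are natural.  Positive time-constant deviations
*slow* a population (`T_eff = T_base * exp(tau)`); this sign convention is
what lets the bundled preset — large positive deviations on the superficial
pyramidal, interneuron and stellate time constants plus a reduced sigmoid
slope — move the circuit's resonance from its intrinsically fast regime
down into the theta–alpha band.  The parameter vector has 47 entries: 4
shared time constants, 18 per-node intrinsic gains, the sigmoid slope, 14
extrinsic gains, 4 spectral noise parameters and 6 lead-field gains.

**Base constants.**  Base time constants are 2, 2, 16 and 28 ms
(superficial pyramidal, interneuron, stellate, deep pyramidal).  Intrinsic
gains are small integer multiples of a single scale G0 = 600, with strong
self-inhibition (multiples 16, 8, 8, 2) providing damping and the
superficial-pyramidal/interneuron loop providing the resonance.  These
values are the package's canonical choice, frozen after verifying three
properties of the generative model at the bundled preset: an alpha-band
spectral peak (9.5 Hz), a comfortable stability margin (largest eigenvalue
real part about -1.3 s^-1), and robustness of stability under the
random-effect jitter used by the cohort generator.  At zero deviations the
circuit is stable with a fast, low-amplitude spectrum, which is why the
preset tuning step (`tune_alpha_priors`) is needed to obtain alpha.

**Spectra.**  With the centred sigmoid and no exogenous drive the origin is
an exact fixed point; the dynamics are linearized there (a damped
root-finder is retained as a safeguard for perturbed variants).  Predicted
cross-spectra follow from the transfer function,

    G_y(f) = T(f) G_u(f) T(f)^H + G_n(f),
    T(f)   = C (2i pi f I - J)^-1 B,

with innovations entering the stellate population of every node
(independent channels, one shared power-law spectrum `a (f^-b + 1/4)`) and
diagonal observation noise of the same form.  All spectra are one-sided
densities.  `T(f)` is evaluated from one eigendecomposition of the Jacobian
rather than per-frequency solves, with a direct-solve fallback when the
eigenvector matrix is ill-conditioned.  The time-domain oracle integrates
the same linearized stochastic system with exact zero-order-hold
discretization and frequency-domain noise shaping; agreement with the
analytic spectra is assessed on power band-averaged over the spectral peak
+-0.5 Hz, because a pointwise periodogram ordinate at an isolated bin of a
high-Q resonance estimates a window-smoothed quantity, whereas the local
average is estimated without bias by both routes.

**Observation model.**  The lead field for synthetic data is a fixed,
seeded 6-to-m mixing matrix with per-node log-gain deviations `L`; a
physical head model is deliberately out of scope, since all model fitting
happens in a reduced spatial basis.

## Subject-level inversion

The data feature is the complex cross-spectral density in a basis of
principal spatial eigenmodes (default 8) of the sensor covariance, with the
multitaper estimator and the inclusion rule that a subject needs at least
twelve 2-s epochs.  The data vector stacks the upper-triangular CSD entries
(real parts of all, imaginary parts off the diagonal) per frequency on a
1–30 Hz grid at 0.5 Hz.

Fitting is Gauss–Newton ascent on the variational free energy under the
Laplace approximation, with Levenberg damping (steps that do not increase
the free energy are rejected and the damping increased eightfold),
finite-difference Jacobians (step 1e-3, with one-sided fallback at the
stability boundary), and a scalar observation log-precision hyperparameter
updated by damped Newton steps each outer iteration under a wide Gaussian
hyperprior centred on the precision implied by the initial residual.
Convergence requires |dF| < 0.01 nats on three consecutive accepted steps
(at most 64 iterations; non-convergence returns the best iterate, flagged).
Everything is deterministic given the inputs.

**Per-frequency weighting.**  Residuals are weighted by the inverse of the
mean observed power at each frequency (a fixed, data-derived weight, i.e.
ordinary weighted least squares inside the free energy).  CSD sampling
noise is multiplicative — proportional to the local power — while the
likelihood assumes homoscedastic residuals; without the weights the
spectral peak dominates the objective, the tails carry no information, and
the ascent is prone to local optima in which intrinsic-gain effects are
absorbed by other parameters.  This choice was decisive for parameter
identifiability in the construct-validity experiments.

**Priors.**  Deviation priors are zero-mean diagonal Gaussians: variance
1/16 on time constants, intrinsic gains and the sigmoid slope, 1/8 on
extrinsic gains and noise amplitudes, and 1/64 on lead-field gains and
noise spectral exponents.  The tighter lead-field prior matters: per-node
output gains are almost exactly degenerate with per-node power changes
caused by self-inhibition, so a loose `L` prior absorbs the very effects
the analysis is designed to detect.  The prior mean for cohort analyses is
the bundled alpha-tuned preset.

## Between-subject level: PEB and BMR

Subject-level marginal posteriors over the selected connection-class
parameters (forward, backward, intrinsic; 14 parameters) enter a
hierarchical Gaussian model

    theta_i = prior_mean + B' x_i + eps_i,   eps_i ~ N(0, Psi),

where `x_i` is row i of the design matrix and `B` holds one effect per
(design column, parameter).  The design has six columns: intercept,
standardized cognitive score, age orthogonalized to the score (residuals of
age on score, standardized), their interaction, and two mean-centred
nuisance regressors (counterbalancing-order rank and a split/whole-block
indicator).  Continuous columns are scaled to unit SD, so effects are per
SD of the covariate.

Given the random-effect covariance `Psi = exp(-gamma) * prior/16`, the
second level is linear-Gaussian and the group free energy, effect posterior
and empirical-Bayes subject estimates are all closed-form; the scalar
log-precision `gamma` is optimized on a grid (17 points on [-3, 5]) with a
standard-Gaussian hyperprior.  The group-effect prior is zero-mean with one
shared variance (1/16) for every effect entry.  Using the first-level class
variances here instead would make the complexity cost of an effect depend
on its class and demonstrably biases null-cohort model comparison toward
the extrinsic-effect candidates; a shared width keeps the seven hypotheses
on an equal footing.

**Model comparison.**  The seven candidates are the non-empty subsets of
{forward, backward, intrinsic}.  Each candidate is scored by Bayesian model
reduction on the group-effect posterior: the prior variances of the
effect-of-interest entries (score, age, interaction columns) for excluded
classes are shrunk to ~0, and the evidence change is computed in closed
form; the intercept and nuisance columns are retained in every candidate,
as are random effects on all parameters.  Posterior model probabilities are
the softmax of the candidate free energies.  `gamma` is estimated once
under the full model and held fixed across candidates.  An exhaustive
search over arbitrary effect-entry subsets is implemented for completeness
but the headline comparison uses the motivated seven-model space.
Per-node effects are reported with 90% central credible intervals (the
figure convention being unstated, a central interval was chosen).

## Sensor-space analysis

Multitaper spectra use 400-ms sliding windows stepped by 50 ms within each
2-s epoch, averaged within and across windows and epochs, zero-padded to a
0.5 Hz grid.  The taper half-bandwidth parameter defaults to 1.5 Hz; for
400-ms windows the time-bandwidth product is below 1 and a single Slepian
taper is used (`max(1, floor(2NW-1))` tapers in general) — the "bandwidth"
setting of the original toolchain is not recoverable, so it is an explicit
parameter.  Alpha-peak amplitude and frequency are the maximum and argmax
of power on 8–13 Hz (ties resolve to the lowest frequency).  Regional
spectra are unweighted means over the named occipital (7) and frontal (8)
electrode groups of the 128-channel geodesic net; the six electrodes
nearest the ears (computed geometrically from the standard montage) are
excluded from all analyses.

Scalp maps interpolate channel values onto a 64x64 pixel head disk
(azimuthal-equidistant electrode projection, linear interpolation inside
the electrode hull, nearest-neighbour fill, Gaussian smoothing with sigma =
2 px using mask-normalized convolution so the in-mask mean is preserved).
Pixel-wise regression of per-subject maps on a covariate controls the
family-wise error rate by max-T permutation (default 1000 permutations of
the covariate, two-sided) rather than random-field theory: permutation is
assumption-light, exactly testable, and appropriate at these map sizes.
This is a deliberate method substitution and is validated by a null
calibration (false-positive rate within [0.01, 0.10] at nominal 0.05) for
both Gaussian and heavy-tailed noise.

## Synthetic cohorts

`figure_one_cohort` realizes the construct-validity design: a baseline
parameterization (the alpha preset), a standard-normal between-subject
regressor, per-subject models whose intrinsic self-inhibition gains move by
`effect_size * z_i` (default 0.4 deviation units per regressor SD) with
N(0, 0.1^2) random-effect jitter on all parameters (unstable draws are
re-jittered up to 10 times), and per-subject CSDs perturbed by averaging
`1/noise_level^2` complex-Wishart draws around the prediction (default
noise level 0.05, the natural noise model for a CSD estimated from finitely
many epochs; ~0.05 corresponds to the several hundred degrees of freedom of
a well-recorded subject).  The covariate table echoes the cohort
descriptives (score 54.84 +- 19.64 clipped to 10–102, ages uniform on
16–56, order ranks, split/whole-block codes) purely for realism.

The sensor-level generator mixes ~10 Hz (posterior topography) and ~5 Hz
(frontal topography) stochastic resonator sources over independent 1/f
channel noise, with both oscillator amplitudes linear in the standardized
score (default 0.25 per SD).  It emulates the statistical structure the
sensor analyses assume — narrowband rhythms over 1/f background whose
amplitude tracks a covariate — and none of the things real EEG adds:
artifacts, bad channels, volume-conduction geometry, non-stationarity, or
spectral slowing.  Passing tests on these cohorts therefore demonstrate
internal (construct) validity of the estimators, not performance on
empirical recordings.

## Numerical choices and degenerate inputs

* Stability is certified by the largest real part of the Jacobian
  eigenvalues; unstable parameterizations raise rather than return spectra,
  and unstable Gauss–Newton proposals are rejected by the damping loop.
* Hermitian symmetry is enforced exactly on predicted and perturbed CSDs;
  positive semi-definiteness holds by construction.
* Rank-deficient sensor covariances return fewer eigenmodes with a warning;
  constant covariates, rank-deficient designs, mismatched parameter
  layouts, empty model spaces and missing design columns are rejected with
  named errors.
* The BMR reduction rejects (with the offending eigenvalue) any reduced
  prior whose implied posterior precision is indefinite.
* Flat-spectrum alpha-peak ties resolve to the band's lower edge; scalp-map
  pixels outside the head are NaN and masked.

## Problem sizes

Default analyses use 36 subjects, 8 eigenmodes and the 1–30 Hz grid at
0.5 Hz.  The bundled test and acceptance runs use the same settings for the
headline cohort, a 12-subject / 4-eigenmode variant to demonstrate the
scaled-down path, 20 null cohorts of 12 subjects at 4 eigenmodes for
model-comparison calibration, 200 null replications on 16x16 maps for the
permutation calibration, and 200-s simulations for the spectral oracle;
these sizes keep a full run in the minutes range on a single core while
leaving all statistical conclusions comfortably clear of their thresholds.

## Known limitations

* The linearized spectral prediction ignores the sigmoid's curvature;
  strongly driven or near-unstable regimes would need the nonlinear
  simulator.
* Conduction delays, thalamic nodes and realistic head models are out of
  scope; the lead field is synthetic and seeded.
* `gamma` (between-subject log-precision) is a single scalar shared by all
  parameters and is not re-optimized per candidate during model comparison.
* Subject-level free energies are Laplace approximations; their absolute
  values are only meaningful in differences.
* The empirical sensor-space statistics of the motivating study (e.g. a
  specific t(34) or cluster locations) depend on recordings that are not
  redistributable, and are not reproduction targets of this package.
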