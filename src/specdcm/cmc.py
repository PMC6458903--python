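"""Canonical-microcircuit (CMC) neural mass model and six-node alpha network.

Each cortical source is modelled by four interacting neuronal populations
assigned to cortical layers: spiny stellate cells (granular layer, ``ss``),
superficial pyramidal cells (``sp``), inhibitory interneurons (``ii``) and
deep pyramidal cells (``dp``).  Every population obeys second-order synaptic
dynamics

    dv/dt = u
    du/dt = kappa * (synaptic input) - 2 * kappa * u - kappa**2 * v

where ``kappa`` is the inverse synaptic time constant and the synaptic input
is a weighted sum of presynaptic firing rates passed through a centred
sigmoid.  Sources are coupled by excitatory extrinsic connections: forward
connections target the granular and deep layers, backward connections the
superficial pyramidal cells and interneurons, and interhemispheric lateral
connections are treated like forward ones.

All subject-specific parameters are dimensionless log-scaling deviations
applied to fixed base constants, so a deviation of 0 denotes the canonical
microcircuit and Gaussian priors over deviations are natural.  Positive time
constant deviations *slow* a population (they multiply the base time
constant), which is how the bundled preset shifts the working point of the
circuit from its intrinsically fast regime down into the theta-alpha band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import SpectralSolveError, UnstableModelError

__all__ = [
    "POPULATIONS",
    "NODES",
    "CMCParameters",
    "NetworkModel",
    "LinearizedSystem",
    "CrossSpectralData",
    "default_network",
    "alpha_prior_parameters",
    "sigmoid_firing",
    "assemble_system",
    "predict_csd",
    "simulate_timeseries",
    "tune_alpha_priors",
    "mixing_matrix",
    "default_freqs",
]

# ---------------------------------------------------------------------------
# Fixed base constants of the canonical microcircuit.
# ---------------------------------------------------------------------------

#: population order used for the tau vector (matches the preset symbols
#: T1..T4: superficial pyramidal, inhibitory interneuron, spiny stellate,
#: deep pyramidal)
TAU_ORDER = ("sp", "ii", "ss", "dp")

#: state-vector population order (per node: ss, sp, ii, dp; each with v, u)
POPULATIONS = ("ss", "sp", "ii", "dp")

NODES = ("lV1", "rV1", "lSPL", "rSPL", "lMFG", "rMFG")

#: base synaptic time constants in ms, in TAU_ORDER
T_BASE_MS = np.array([2.0, 2.0, 16.0, 28.0])

#: base sigmoid slope (firing per mV); effective slope is R_BASE * exp(s)
R_BASE = 2.0

#: intrinsic coupling scale (mV per unit firing); individual connections
#: below are small-integer multiples of this
G0 = 600.0

#: intrinsic wiring: (target, source, multiple of G0, scaled-by)
#: negative multiples are inhibitory.  g1 scales superficial-pyramidal
#: self-inhibition, g2 the superficial-pyramidal->stellate inhibition and
#: g3 the interneuron->stellate inhibition.  Strong self-inhibition damps
#: every population while the superficial-pyramidal/interneuron loop
#: supplies the theta-alpha resonance at the bundled (slowed) time
#: constants.
INTRINSIC_WIRING = (
    ("ss", "ss", -16.0, None),
    ("ss", "sp", -1.0, "g2"),
    ("ss", "ii", -1.0, "g3"),
    ("sp", "ss", +1.0, None),
    ("sp", "sp", -8.0, "g1"),
    ("sp", "ii", -2.0, None),
    ("ii", "ss", +1.0, None),
    ("ii", "sp", +2.0, None),
    ("ii", "ii", -8.0, None),
    ("dp", "sp", +3.0, None),
    ("dp", "ii", -2.0, None),
    ("dp", "dp", -2.0, None),
)

#: extrinsic base gains (mV per unit firing), per connection class
EXTRINSIC_BASE = {"forward": 0.5 * G0, "backward": 0.25 * G0, "lateral": 0.25 * G0}

#: extrinsic targets: class -> ((target population, weight sign/scale), ...)
#: and the population whose firing is propagated
EXTRINSIC_TARGETS = {
    "forward": (("ss", 1.0), ("dp", 0.5)),
    "backward": (("sp", 1.0), ("ii", 0.5)),
    "lateral": (("ss", 1.0), ("dp", 0.5)),
}
EXTRINSIC_SOURCE = {"forward": "sp", "backward": "dp", "lateral": "sp"}

#: base one-sided PSD amplitude of neuronal innovations / observation noise
#: at 1 Hz (arbitrary units**2/Hz), and the white floor of the power-law
#: spectra a * (f^-b + W_FLOOR)
A_U_BASE = 1.0
A_N_BASE = 1e-9
W_FLOOR = 0.25

_MIXING_SEED = 902101  # fixed lead-field seed; part of the model, not a dial


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _edge_lists():
    fwd = [("lV1", "lSPL"), ("lSPL", "lMFG"), ("rV1", "rSPL"), ("rSPL", "rMFG")]
    bwd = [(b, a) for a, b in fwd]
    lat = [
        ("lV1", "rV1"), ("rV1", "lV1"),
        ("lSPL", "rSPL"), ("rSPL", "lSPL"),
        ("lMFG", "rMFG"), ("rMFG", "lMFG"),
    ]
    return fwd, bwd, lat


N_FWD, N_BWD, N_LAT = 4, 4, 6


@dataclass
class CMCParameters:
    """Log-scaling parameter deviations for one subject-level network model.

    All fields are dimensionless deviations; ``exp(deviation)`` multiplies a
    positive base constant.  ``tau`` follows the order (sp, ii, ss, dp) and is
    shared across nodes; ``g1``/``g2``/``g3`` carry one entry per node.
    """

    tau: np.ndarray = field(default_factory=lambda: np.zeros(4))
    g1: np.ndarray = field(default_factory=lambda: np.zeros(6))
    g2: np.ndarray = field(default_factory=lambda: np.zeros(6))
    g3: np.ndarray = field(default_factory=lambda: np.zeros(6))
    s: float = 0.0
    a_fwd: np.ndarray = field(default_factory=lambda: np.zeros(N_FWD))
    a_bwd: np.ndarray = field(default_factory=lambda: np.zeros(N_BWD))
    a_lat: np.ndarray = field(default_factory=lambda: np.zeros(N_LAT))
    noise_alpha_u: float = 0.0
    noise_beta_u: float = 0.0
    noise_alpha_n: float = 0.0
    noise_beta_n: float = 0.0
    L: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.g1 = np.asarray(self.g1, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        self.g3 = np.asarray(self.g3, dtype=float)
        self.a_fwd = np.asarray(self.a_fwd, dtype=float)
        self.a_bwd = np.asarray(self.a_bwd, dtype=float)
        self.a_lat = np.asarray(self.a_lat, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.validate()

    def validate(self):
        if self.tau.shape != (4,):
            raise ValueError("tau must have exactly 4 entries")
        for name in ("g1", "g2", "g3", "L"):
            if getattr(self, name).shape != (6,):
                raise ValueError(f"{name} must have one entry per node (6)")
        if self.a_fwd.shape != (N_FWD,) or self.a_bwd.shape != (N_BWD,):
            raise ValueError("extrinsic deviation vectors have wrong length")
        if self.a_lat.shape != (N_LAT,):
            raise ValueError("a_lat must have one entry per lateral edge")
        if not np.isfinite(self.to_vector()).all():
            raise ValueError("all parameter deviations must be finite")

    # -- flat-vector layout (used by inversion and PEB) ---------------------

    @staticmethod
    def names() -> list[str]:
        names = [f"tau_{p}" for p in TAU_ORDER]
        for g in ("g1", "g2", "g3"):
            names += [f"{g}_{n}" for n in NODES]
        names += ["s"]
        fwd, bwd, lat = _edge_lists()
        names += [f"a_fwd_{a}->{b}" for a, b in fwd]
        names += [f"a_bwd_{a}->{b}" for a, b in bwd]
        names += [f"a_lat_{a}->{b}" for a, b in lat]
        names += ["noise_alpha_u", "noise_beta_u", "noise_alpha_n", "noise_beta_n"]
        names += [f"L_{n}" for n in NODES]
        return names

    @staticmethod
    def size() -> int:
        return 4 + 18 + 1 + N_FWD + N_BWD + N_LAT + 4 + 6

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.tau, self.g1, self.g2, self.g3, [self.s],
            self.a_fwd, self.a_bwd, self.a_lat,
            [self.noise_alpha_u, self.noise_beta_u,
             self.noise_alpha_n, self.noise_beta_n],
            self.L,
        ])

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "CMCParameters":
        v = np.asarray(vec, dtype=float)
        if v.shape != (cls.size(),):
            raise ValueError(f"expected vector of length {cls.size()}")
        i = 0
        def take(n):
            nonlocal i
            out = v[i:i + n]
            i += n
            return out
        return cls(
            tau=take(4), g1=take(6), g2=take(6), g3=take(6), s=take(1)[0],
            a_fwd=take(N_FWD), a_bwd=take(N_BWD), a_lat=take(N_LAT),
            noise_alpha_u=take(1)[0], noise_beta_u=take(1)[0],
            noise_alpha_n=take(1)[0], noise_beta_n=take(1)[0], L=take(6),
        )

    def copy(self) -> "CMCParameters":
        return CMCParameters.from_vector(self.to_vector())

    @staticmethod
    def parameter_class(name: str) -> str:
        """Connection class of a flat-vector entry, for PEB field selection.

        Returns one of {"intrinsic", "forward", "backward", "lateral",
        "tau", "s", "noise", "leadfield", "g2", "g3"}; "intrinsic" denotes the
        per-node self-inhibition gains (g1), the between-subject effect
        carrier of interest.
        """
        if name.startswith("g1_"):
            return "intrinsic"
        if name.startswith("g2_"):
            return "g2"
        if name.startswith("g3_"):
            return "g3"
        if name.startswith("a_fwd"):
            return "forward"
        if name.startswith("a_bwd"):
            return "backward"
        if name.startswith("a_lat"):
            return "lateral"
        if name.startswith("tau"):
            return "tau"
        if name == "s":
            return "s"
        if name.startswith("noise"):
            return "noise"
        return "leadfield"


@dataclass(frozen=True)
class NetworkModel:
    """Six-node bilateral alpha network (V1, SPL, MFG in each hemisphere)."""

    nodes: tuple = NODES
    coordinates: dict = field(default_factory=lambda: {
        # MNI mm, from EEG/fMRI correlates of posterior alpha power
        "lV1": (-16, -92, 0), "rV1": (12, -92, 21),
        "lSPL": (-48, -56, 52), "rSPL": (34, -51, 39),
        "lMFG": (-46, 37, 16), "rMFG": (46, 18, 21),
    })
    edges: tuple = ()

    def __post_init__(self):
        if len(self.nodes) != 6:
            raise ValueError("the alpha network has exactly 6 nodes")
        if not self.edges:
            fwd, bwd, lat = _edge_lists()
            edges = tuple(
                [(a, b, "forward") for a, b in fwd]
                + [(a, b, "backward") for a, b in bwd]
                + [(a, b, "lateral") for a, b in lat]
            )
            object.__setattr__(self, "edges", edges)
        for a, b, cls in self.edges:
            if cls not in ("forward", "backward", "lateral"):
                raise ValueError(f"unknown edge class {cls!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {a}->{b} references unknown node")

    def edges_of_class(self, cls: str):
        return [(a, b) for a, b, c in self.edges if c == cls]


def default_network() -> NetworkModel:
    return NetworkModel()


def alpha_prior_parameters() -> CMCParameters:
    """The bundled alpha-tuned prior-mean parameterization.

    Time constants and sigmoid slope are shared across nodes; the three named
    intrinsic gains vary per node (order lV1, rV1, lSPL, rSPL, lMFG, rMFG).
    """
    return CMCParameters(
        tau=np.array([2.17, 2.94, 3.81, 0.66]),
        g1=np.array([-0.39, -0.05, -0.33, 0.18, -0.14, -0.03]),
        g2=np.array([-0.33, 0.22, 0.84, 0.73, 0.42, -0.08]),
        g3=np.array([-0.05, -0.05, -0.23, -0.54, -0.31, -1.67]),
        s=-0.63,
    )


@dataclass
class LinearizedSystem:
    """First-order form of the network dynamics around a fixed point."""

    jacobian: np.ndarray       # (48, 48)
    input_map: np.ndarray      # (48, n_innovation_channels)
    output_map: np.ndarray     # (n_out, 48): sensors or eigenmodes
    fixed_point: np.ndarray    # (48,)
    node_output_map: np.ndarray  # (6, 48): per-node observed depolarization

    @property
    def n_states(self) -> int:
        return self.jacobian.shape[0]

    def max_eigenvalue_real(self) -> float:
        return float(np.linalg.eigvals(self.jacobian).real.max())

    def is_stable(self, tol: float = 0.0) -> bool:
        return self.max_eigenvalue_real() < tol


@dataclass
class CrossSpectralData:
    """Complex cross-spectral matrices on a frequency grid.

    ``csd[k]`` is the Hermitian m-by-m cross-spectral matrix at ``freqs[k]``
    (one-sided density, units**2/Hz).
    """

    freqs: np.ndarray
    csd: np.ndarray
    n_eigenmodes: int = 0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.csd.ndim != 3 or self.csd.shape[1] != self.csd.shape[2]:
            raise ValueError("csd must be (n_freqs, m, m)")
        if self.csd.shape[0] != self.freqs.shape[0]:
            raise ValueError("freqs and csd disagree on n_freqs")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.n_eigenmodes == 0:
            self.n_eigenmodes = self.csd.shape[1]

    def hermitian_error(self) -> float:
        h = np.linalg.norm(self.csd - np.conj(np.swapaxes(self.csd, 1, 2)))
        return float(h / max(np.linalg.norm(self.csd), 1e-300))


def default_freqs(lo: float = 1.0, hi: float = 30.0, df: float = 0.5) -> np.ndarray:
    """Default analysis grid: 1-30 Hz at 0.5 Hz."""
    n = int(round((hi - lo) / df))
    return lo + df * np.arange(n + 1)


# ---------------------------------------------------------------------------
# Firing-rate nonlinearity
# ---------------------------------------------------------------------------


def sigmoid_firing(v, s: float = 0.0):
    """Centred sigmoid firing rate in (-1/2, 1/2).

    ``s`` is the log-deviation of the slope ("population variance"
    parameter): slope at v=0 is R_BASE*exp(s)/4, i.e. proportional to exp(s).
    """
    v = np.asarray(v, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("membrane potential must be finite")
    from scipy.special import expit
    r = R_BASE * np.exp(s)
    out = expit(r * v) - 0.5
    return out if out.ndim else float(out)


def _sigmoid_slope(v, s: float):
    r = R_BASE * np.exp(s)
    sig = 1.0 / (1.0 + np.exp(-r * np.asarray(v, dtype=float)))
    return r * sig * (1.0 - sig)


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

_POP_IDX = {p: i for i, p in enumerate(POPULATIONS)}
_TAU_IDX = {p: i for i, p in enumerate(TAU_ORDER)}
_NODE_IDX = {n: i for i, n in enumerate(NODES)}


def _state_index(node: int, pop: str, which: str) -> int:
    return node * 8 + _POP_IDX[pop] * 2 + (0 if which == "v" else 1)


def _kappas(params: CMCParameters) -> np.ndarray:
    """Effective rate constants (1/s) per population in POPULATIONS order."""
    t_eff_ms = T_BASE_MS * np.exp(params.tau)  # TAU_ORDER
    kap = {p: 1000.0 / t_eff_ms[_TAU_IDX[p]] for p in TAU_ORDER}
    return np.array([kap[p] for p in POPULATIONS])


def _weight_matrix(params: CMCParameters, net: NetworkModel,
                   decoupled: bool = False) -> np.ndarray:
    """(24, 24) synaptic weight matrix over (node, population) pairs: the
    input to population (n,p) is sum_q W[(n,p),(m,q)] * firing(m,q)."""
    W = np.zeros((24, 24))
    gmaps = {"g1": params.g1, "g2": params.g2, "g3": params.g3}
    for n in range(6):
        for tgt, src, mult, scaled in INTRINSIC_WIRING:
            w = mult * G0
            if scaled is not None:
                w *= np.exp(gmaps[scaled][n])
            W[n * 4 + _POP_IDX[tgt], n * 4 + _POP_IDX[src]] += w
    if not decoupled:
        devs = {"forward": params.a_fwd, "backward": params.a_bwd,
                "lateral": params.a_lat}
        for cls in ("forward", "backward", "lateral"):
            base = EXTRINSIC_BASE[cls]
            src_pop = EXTRINSIC_SOURCE[cls]
            for k, (a, b) in enumerate(net.edges_of_class(cls)):
                gain = base * np.exp(devs[cls][k])
                ia, ib = _NODE_IDX[a], _NODE_IDX[b]
                for tgt_pop, frac in EXTRINSIC_TARGETS[cls]:
                    W[ib * 4 + _POP_IDX[tgt_pop], ia * 4 + _POP_IDX[src_pop]] += gain * frac
    return W


def _dynamics(x: np.ndarray, kap24: np.ndarray, W: np.ndarray, s: float) -> np.ndarray:
    v = x[0::2]
    u = x[1::2]
    inp = W @ sigmoid_firing(v, s)
    dv = u
    du = kap24 * inp - 2.0 * kap24 * u - kap24 ** 2 * v
    out = np.empty_like(x)
    out[0::2] = dv
    out[1::2] = du
    return out


def _find_fixed_point(kap24, W, s) -> np.ndarray:
    """Damped root-finding from the origin.  With the centred sigmoid and no
    exogenous drive the origin is an exact equilibrium, so this is a
    safeguard for perturbed variants rather than a search."""
    x0 = np.zeros(48)
    f0 = _dynamics(x0, kap24, W, s)
    if np.linalg.norm(f0) < 1e-12:
        return x0
    sol = optimize.root(lambda x: _dynamics(x, kap24, W, s), x0, method="hybr")
    if not sol.success:
        return x0
    return sol.x


def mixing_matrix(m: int, n_nodes: int = 6, seed: int = _MIXING_SEED) -> np.ndarray:
    """Fixed seeded lead-field mixing from node outputs to m virtual sensors
    or eigenmodes.  Part of the synthetic observation model (a physical head
    model is out of scope); deterministic for a given (m, seed)."""
    rng = np.random.default_rng(seed + 7919 * m)
    M = rng.normal(size=(m, n_nodes)) / np.sqrt(n_nodes)
    return M


def assemble_system(params: CMCParameters, net: NetworkModel,
                    n_outputs: int | None = None,
                    decoupled: bool = False,
                    require_stable: bool = True) -> LinearizedSystem:
    """Linearize the six-node CMC network around its fixed point.

    Parameters
    ----------
    n_outputs : int or None
        If None, outputs are the six per-node observed depolarizations
        (superficial-pyramidal potentials scaled by exp(L)).  Otherwise a
        fixed seeded mixing projects them to ``n_outputs`` channels.
    decoupled : bool
        Drop all extrinsic connections (isolated nodes); used for prior
        tuning and decoupling checks.
    require_stable : bool
        Raise :class:`UnstableModelError` if the Jacobian has an eigenvalue
        with non-negative real part.
    """
    kap = _kappas(params)
    kap24 = np.tile(kap, 6)  # POPULATIONS order within each node
    W = _weight_matrix(params, net, decoupled=decoupled)
    xstar = _find_fixed_point(kap24, W, params.s)
    vstar = xstar[0::2]

    slope = _sigmoid_slope(vstar, params.s)  # (24,)
    J = np.zeros((48, 48))
    # dv/dt = u
    J[0::2, 1::2] = np.eye(24)
    # du/dt rows
    ku = -2.0 * kap24
    kv = -(kap24 ** 2)
    J[1::2, 1::2] = np.diag(ku)
    J[1::2, 0::2] = np.diag(kv) + (kap24[:, None] * W) * slope[None, :]

    # innovations drive the stellate population of every node
    B = np.zeros((48, 6))
    for n in range(6):
        B[_state_index(n, "ss", "u"), n] = kap[_POP_IDX["ss"]]

    # per-node output: superficial pyramidal depolarization, gain exp(L)
    C_node = np.zeros((6, 48))
    for n in range(6):
        C_node[n, _state_index(n, "sp", "v")] = np.exp(params.L[n])
    if n_outputs is None:
        C = C_node
    else:
        C = mixing_matrix(n_outputs) @ C_node

    sys = LinearizedSystem(jacobian=J, input_map=B, output_map=C,
                           fixed_point=xstar, node_output_map=C_node)
    if require_stable and not sys.is_stable():
        raise UnstableModelError(
            f"max Re(eigenvalue) = {sys.max_eigenvalue_real():.4g} >= 0 "
            "at the requested parameters")
    return sys


# ---------------------------------------------------------------------------
# Spectral prediction
# ---------------------------------------------------------------------------


def innovation_spectrum(params: CMCParameters, freqs: np.ndarray) -> np.ndarray:
    """One-sided PSD of the shared neuronal innovations, per channel."""
    f = np.asarray(freqs, dtype=float)
    a = A_U_BASE * np.exp(params.noise_alpha_u)
    b = np.exp(params.noise_beta_u)
    return a * (f ** (-b) + W_FLOOR)


def observation_spectrum(params: CMCParameters, freqs: np.ndarray) -> np.ndarray:
    """One-sided PSD of channel observation noise."""
    f = np.asarray(freqs, dtype=float)
    a = A_N_BASE * np.exp(params.noise_alpha_n)
    b = np.exp(params.noise_beta_n)
    return a * (f ** (-b) + W_FLOOR)


def transfer_functions(sys: LinearizedSystem, freqs: np.ndarray) -> np.ndarray:
    """T(f) = C (i 2 pi f I - J)^-1 B, batched over frequencies.

    Uses the eigendecomposition of the Jacobian when it is well conditioned
    (one decomposition instead of one linear solve per frequency), falling
    back to direct solves otherwise.
    """
    f = np.asarray(freqs, dtype=float)
    n = sys.n_states
    iw = 2j * np.pi * f
    lam, V = np.linalg.eig(sys.jacobian)
    cond = np.linalg.cond(V)
    if np.isfinite(cond) and cond < 1e8:
        CV = sys.output_map @ V
        ViB = np.linalg.solve(V, sys.input_map.astype(complex))
        D = 1.0 / (iw[:, None] - lam[None, :])
        if not np.isfinite(D).all():
            k = int(np.argwhere(~np.isfinite(D).all(axis=1))[0, 0])
            raise SpectralSolveError(float(f[k]))
        return np.einsum("mk,fk,kj->fmj", CV, D, ViB)
    A = iw[:, None, None] * np.eye(n)[None] - sys.jacobian[None]
    try:
        sol = np.linalg.solve(A, np.broadcast_to(
            sys.input_map.astype(complex), (len(f), n, sys.input_map.shape[1])))
    except np.linalg.LinAlgError:
        # identify the offending frequency for the error report
        for k, fk in enumerate(f):
            try:
                np.linalg.solve(A[k], sys.input_map.astype(complex))
            except np.linalg.LinAlgError:
                raise SpectralSolveError(float(fk)) from None
        raise
    return sys.output_map[None] @ sol  # (F, n_out, n_in)


def predict_csd(sys: LinearizedSystem, params: CMCParameters,
                freqs: np.ndarray) -> CrossSpectralData:
    """Predicted sensor/eigenmode cross-spectral density.

    G_y(f) = T(f) G_u(f) T(f)^H + G_n(f), with power-law innovation and
    observation spectra.  The result is Hermitian positive semi-definite at
    every frequency by construction.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    T = transfer_functions(sys, freqs)
    gu = innovation_spectrum(params, freqs)  # shared across channels
    gn = observation_spectrum(params, freqs)
    m = T.shape[1]
    G = np.einsum("fij,f,fkj->fik", T, gu, np.conj(T))
    G = G + gn[:, None, None] * np.eye(m)[None]
    # enforce exact Hermitian symmetry against rounding
    G = 0.5 * (G + np.conj(np.swapaxes(G, 1, 2)))
    return CrossSpectralData(freqs=freqs, csd=G, n_eigenmodes=m)


# ---------------------------------------------------------------------------
# Time-domain oracle
# ---------------------------------------------------------------------------


def _colored_noise(psd_fun, n: int, dt: float, rng: np.random.Generator,
                   n_channels: int) -> np.ndarray:
    """Real noise with one-sided PSD psd_fun(f) via frequency-domain shaping."""
    fs = 1.0 / dt
    freqs = np.fft.rfftfreq(n, dt)
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    amp[pos] = np.sqrt(psd_fun(freqs[pos]) * fs * n / 2.0)
    z = rng.normal(size=(n_channels, len(freqs))) + 1j * rng.normal(size=(n_channels, len(freqs)))
    z *= amp / np.sqrt(2.0)
    z[:, 0] = 0.0
    if n % 2 == 0:
        z[:, -1] = z[:, -1].real * np.sqrt(2.0)
    return np.fft.irfft(z, n=n, axis=1)


def simulate_timeseries(sys: LinearizedSystem, params: CMCParameters,
                        duration: float, dt: float, seed: int) -> np.ndarray:
    """Simulate the linearized stochastic system; returns (n_out, n_samples).

    Innovations with the parameterized power-law spectrum drive the stellate
    populations; integration uses exact zero-order-hold discretization of the
    linear dynamics (expm), which is exact for piecewise-constant input.
    Deterministic given the seed.
    """
    if dt > 2e-3:
        raise ValueError("dt must be <= 2 ms")
    if duration < 10.0:
        raise ValueError("duration must be >= 10 s")
    if not sys.is_stable():
        raise UnstableModelError("refusing to integrate an unstable system")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    n_in = sys.input_map.shape[1]
    u = _colored_noise(lambda f: innovation_spectrum(params, f), n, dt, rng, n_in)

    from scipy.linalg import expm
    Ad = expm(sys.jacobian * dt)
    # ZOH input matrix: J^{-1} (Ad - I) B  (J invertible: stable system)
    Bd = np.linalg.solve(sys.jacobian, (Ad - np.eye(sys.n_states))) @ sys.input_map

    x = np.zeros(sys.n_states)
    n_out = sys.output_map.shape[0]
    Y = np.empty((n_out, n))
    for k in range(n):
        x = Ad @ x + Bd @ u[:, k]
        Y[:, k] = sys.output_map @ x
    gn_amp = observation_spectrum(params, np.array([10.0]))[0]
    if gn_amp > 0:
        Y += _colored_noise(lambda f: observation_spectrum(params, f), n, dt,
                            rng, n_out)
    return Y


# ---------------------------------------------------------------------------
# Prior tuning
# ---------------------------------------------------------------------------


def _single_node_peak(params: CMCParameters, net: NetworkModel,
                      freqs: np.ndarray) -> float | None:
    """Spectral peak frequency (Hz) of a single decoupled node, or None if
    the parameterization is unstable."""
    try:
        sys = assemble_system(params, net, decoupled=True)
    except UnstableModelError:
        return None
    csd = predict_csd(sys, params, freqs)
    power = csd.csd[:, 0, 0].real
    return float(freqs[int(np.argmax(power))])


def tune_alpha_priors(base: CMCParameters, band: tuple[float, float] = (8.0, 13.0),
                      net: NetworkModel | None = None) -> CMCParameters:
    """Search time-constant and slope deviations (tau[0..2], s) so that a
    single decoupled node's predicted spectrum peaks inside ``band``.

    Mirrors the prior-optimization step used to coax the microcircuit into
    producing an alpha-band spectral peak.  Returns a copy of ``base`` with
    adjusted tau[0..2] and s; other fields untouched.
    """
    lo, hi = band
    if not (0.0 < lo < hi < 30.0):
        raise ValueError("target band must be within (0, 30) Hz and non-empty")
    net = net or default_network()
    freqs = default_freqs(0.5, 30.0, 0.25)

    peak0 = _single_node_peak(base, net, freqs)
    if peak0 is not None and lo <= peak0 <= hi:
        return base.copy()

    center = np.sqrt(lo * hi)

    def objective(x):
        cand = base.copy()
        cand.tau = base.tau.copy()
        cand.tau[:3] = base.tau[:3] + x[:3]
        cand.s = base.s + x[3]
        if np.any(np.abs(x) > 5.0):
            return 1e6
        pk = _single_node_peak(cand, net, freqs)
        if pk is None:
            return 1e6
        pen = 0.0
        if pk < lo:
            pen = (np.log(lo / pk)) ** 2
        elif pk > hi:
            pen = (np.log(pk / hi)) ** 2
        return pen + 0.1 * (np.log(pk / center)) ** 2 + 1e-3 * np.sum(x ** 2)

    best = None
    starts = [np.zeros(4), np.array([2.0, 2.5, 3.5, -0.5]),
              np.array([1.0, 1.5, 2.0, 0.0]), np.array([3.0, 3.0, 4.0, -1.0])]
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"maxiter": 400, "xatol": 1e-3,
                                         "fatol": 1e-4})
        if best is None or res.fun < best.fun:
            best = res
        cand = base.copy()
        cand.tau = base.tau.copy()
        cand.tau[:3] = base.tau[:3] + best.x[:3]
        cand.s = base.s + best.x[3]
        pk = _single_node_peak(cand, net, freqs)
        if pk is not None and lo <= pk <= hi:
            return cand
    raise UnstableModelError(
        "no stable parameterization with an in-band peak found in the search box")
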