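"""Sensor-space spectral statistics and scalp-map regression.

Multitaper power spectra from short sliding windows, regional electrode
averages, alpha-peak amplitude/frequency metrics and their regression on a
cognitive covariate, and pixel-wise scalp-map regression with family-wise
error control by max-T permutation.

Channel geometry follows the 128-electrode geodesic net: 2-D positions are
an azimuthal-equidistant projection of the standard montage, with the six
peri-auricular channels (nearest the ears, a poor fit in this population)
removed from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage, stats
from scipy.interpolate import griddata
from scipy.signal.windows import dpss

__all__ = [
    "PowerSpectrum",
    "AlphaPeak",
    "ScalpMap",
    "SPMResult",
    "REGIONS",
    "ALPHA_BAND",
    "THETA_ALPHA_BAND",
    "usable_channels",
    "channel_positions_2d",
    "multitaper_psd",
    "regional_average",
    "alpha_peak",
    "covariate_regression",
    "build_scalp_map",
    "spm_regression",
]

ALPHA_BAND = (8.0, 13.0)
THETA_ALPHA_BAND = (4.0, 13.0)

#: regional electrode groups (geodesic sensor net labels)
REGIONS = {
    "occipital": ["E70", "E71", "E74", "E75", "E76", "E82", "E83"],
    "frontal": ["E4", "E5", "E10", "E11", "E12", "E16", "E18", "E19"],
}

N_PERIAURICULAR = 6


@dataclass
class PowerSpectrum:
    """One-sided power spectral density with a channel or region label."""

    freqs: np.ndarray
    power: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")

    def band_power(self, band: tuple[float, float]) -> float:
        lo, hi = band
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        return float(np.mean(self.power[..., sel], axis=-1))


@dataclass
class AlphaPeak:
    amplitude: float
    frequency: float

    def __post_init__(self):
        if not (ALPHA_BAND[0] <= self.frequency <= ALPHA_BAND[1]):
            raise ValueError("alpha-peak frequency must lie in 8-13 Hz")
        if self.amplitude < 0:
            raise ValueError("alpha-peak amplitude must be non-negative")


@dataclass
class ScalpMap:
    """64x64 interpolated sensor-value image with an in-head mask."""

    grid: np.ndarray
    mask: np.ndarray
    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.shape != self.mask.shape:
            raise ValueError("grid and mask shapes differ")
        if not np.isfinite(self.grid[self.mask]).all():
            raise ValueError("grid values inside the mask must be finite")


@dataclass
class SPMResult:
    tmap: np.ndarray
    threshold: float
    significant: np.ndarray
    clusters: np.ndarray
    n_clusters: int
    mask: np.ndarray
    fwe_alpha: float


# ---------------------------------------------------------------------------
# Channel geometry
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def _montage_positions() -> dict:
    import mne
    mon = mne.channels.make_standard_montage("GSN-HydroCel-128")
    pos = mon.get_positions()
    return {"ch_pos": {k: np.asarray(v) for k, v in pos["ch_pos"].items()},
            "lpa": np.asarray(pos["lpa"]), "rpa": np.asarray(pos["rpa"])}


def usable_channels() -> list[str]:
    """All 128 electrode labels minus the six nearest the ears."""
    info = _montage_positions()
    names = sorted(info["ch_pos"], key=lambda s: int(s[1:]))
    d = {}
    for name in names:
        p = info["ch_pos"][name]
        d[name] = min(np.linalg.norm(p - info["lpa"]),
                      np.linalg.norm(p - info["rpa"]))
    drop = set(sorted(names, key=lambda n: d[n])[:N_PERIAURICULAR])
    return [n for n in names if n not in drop]


def channel_positions_2d(channels: list[str] | None = None) -> np.ndarray:
    """Azimuthal-equidistant projection of electrode positions to the unit
    disk (head circle radius 1; electrodes reach ~0.92)."""
    info = _montage_positions()
    channels = channels if channels is not None else usable_channels()
    xyz = np.array([info["ch_pos"][c] for c in channels])
    x, y, z = xyz.T
    rho3 = np.linalg.norm(xyz, axis=1)
    polar = np.arccos(np.clip(z / np.maximum(rho3, 1e-12), -1, 1))
    az = np.arctan2(y, x)
    r = polar / polar.max() * 0.92
    return np.column_stack([r * np.cos(az), r * np.sin(az)])


# ---------------------------------------------------------------------------
# Multitaper spectra
# ---------------------------------------------------------------------------


def multitaper_psd(epochs: np.ndarray, fs: float = 250.0,
                   window: float = 0.4, step: float = 0.05,
                   half_bandwidth: float = 1.5,
                   out_resolution: float = 0.5) -> PowerSpectrum:
    """Sliding-window multitaper PSD averaged within and across windows.

    Parameters
    ----------
    epochs : array (n_epochs, n_times) or (n_epochs, n_channels, n_times)
        2-s data segments.
    window, step : float
        Sliding analysis window length and hop, in seconds.
    half_bandwidth : float
        Spectral concentration half-bandwidth in Hz used to construct the
        Slepian tapers; the number of tapers is ``max(1, floor(2*N*W - 1))``
        (a single near-optimal taper for short windows).
    out_resolution : float
        Frequency-grid spacing (zero-padded FFT), Hz.

    Returns a one-sided PSD in units**2/Hz on [0, fs/2].
    """
    X = np.asarray(epochs, dtype=float)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[:, None, :]
    if X.ndim != 3:
        raise ValueError("epochs must be 2-D or 3-D")
    n_ep, n_ch, n_t = X.shape
    n_win = int(round(window * fs))
    n_step = max(1, int(round(step * fs)))
    if n_win > n_t:
        raise ValueError(
            f"epoch length {n_t / fs:g}s shorter than analysis window {window:g}s")

    nw = window * half_bandwidth
    k = max(1, int(np.floor(2 * nw - 1)))
    tapers = np.atleast_2d(dpss(n_win, max(nw, 0.55), Kmax=k))
    nfft = max(n_win, int(round(fs / out_resolution)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)

    starts = np.arange(0, n_t - n_win + 1, n_step)
    segs = np.stack([X[:, :, s:s + n_win] for s in starts], axis=2)
    # (n_ep, n_ch, n_seg, n_tapers, n_win)
    tapered = segs[:, :, :, None, :] * tapers[None, None, None, :, :]
    spec = np.fft.rfft(tapered, n=nfft, axis=-1)
    p = (np.abs(spec) ** 2).mean(axis=(0, 2, 3))  # (n_ch, n_freqs)
    p /= fs * (tapers ** 2).sum(axis=1).mean()
    p[:, 1:] *= 2.0
    if nfft % 2 == 0:
        p[:, -1] /= 2.0
    power = p[0] if squeeze else p
    return PowerSpectrum(freqs=freqs, power=power)


def regional_average(spectra: dict[str, PowerSpectrum],
                     groups: dict[str, list[str]] | None = None
                     ) -> dict[str, PowerSpectrum]:
    """Unweighted mean spectrum across the named channels of each region."""
    groups = groups if groups is not None else REGIONS
    out = {}
    for region, chans in groups.items():
        missing = [c for c in chans if c not in spectra]
        if missing:
            raise ValueError(
                f"region {region!r} is missing channel(s): {', '.join(missing)}")
        f0 = spectra[chans[0]].freqs
        P = np.mean([spectra[c].power for c in chans], axis=0)
        out[region] = PowerSpectrum(freqs=f0, power=P, label=region)
    return out


def alpha_peak(spec: PowerSpectrum, band: tuple[float, float] = ALPHA_BAND
               ) -> AlphaPeak:
    """Maximum power in the alpha band and the frequency at which it occurs.

    Flat-spectrum ties resolve to the lowest frequency in the band.
    """
    lo, hi = band
    if spec.freqs[0] > lo or spec.freqs[-1] < hi:
        raise ValueError(f"spectrum does not cover the {lo}-{hi} Hz band")
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    fsel, psel = spec.freqs[sel], spec.power[sel]
    k = int(np.argmax(psel))
    return AlphaPeak(amplitude=float(psel[k]), frequency=float(fsel[k]))


# ---------------------------------------------------------------------------
# Regression statistics
# ---------------------------------------------------------------------------


def covariate_regression(values: np.ndarray, covariate: np.ndarray):
    """Ordinary least squares of per-subject values on a covariate.

    Returns (slope, t, p, df) with df = n - 2 and a two-sided p-value.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; slope is undefined")
    res = stats.linregress(x, y)
    df = len(x) - 2
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return float(res.slope), float(t), float(res.pvalue), int(df)


# ---------------------------------------------------------------------------
# Scalp maps
# ---------------------------------------------------------------------------

GRID_SIZE = 64
SMOOTH_SIGMA_PX = 2.0


def _head_mask(n: int) -> np.ndarray:
    ax = np.linspace(-1.05, 1.05, n)
    xx, yy = np.meshgrid(ax, ax)
    return xx ** 2 + yy ** 2 <= 1.0


def build_scalp_map(values: np.ndarray, positions: np.ndarray,
                    n: int = GRID_SIZE,
                    smooth_sigma: float = SMOOTH_SIGMA_PX) -> ScalpMap:
    """Interpolate channel values to an n-by-n pixel scalp image.

    Linear interpolation inside the electrode hull, nearest-neighbour
    extrapolation to the rest of the head disk, then Gaussian smoothing with
    mask-normalized convolution (which preserves the in-mask mean).
    """
    v = np.asarray(values, dtype=float)
    P = np.asarray(positions, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or len(P) != len(v):
        raise ValueError("positions must be (n_channels, 2) matching values")
    if len(v) < 16:
        raise ValueError("need at least 16 channels for a scalp map")
    uniq = np.unique(np.round(P, 6), axis=0)
    if len(uniq) < len(P):
        raise ValueError("duplicate channel positions")

    ax = np.linspace(-1.05, 1.05, n)
    xx, yy = np.meshgrid(ax, ax)
    mask = _head_mask(n)
    grid = griddata(P, v, (xx, yy), method="linear")
    near = griddata(P, v, (xx, yy), method="nearest")
    grid = np.where(np.isnan(grid), near, grid)
    if smooth_sigma > 0:
        w = mask.astype(float)
        num = ndimage.gaussian_filter(grid * w, smooth_sigma)
        den = ndimage.gaussian_filter(w, smooth_sigma)
        grid = np.where(mask, num / np.maximum(den, 1e-12), np.nan)
    else:
        grid = np.where(mask, grid, np.nan)
    return ScalpMap(grid=grid, mask=mask, positions=P)


def _pixel_tstats(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """t-statistics of the covariate slope at each pixel; Y is (n, npix)."""
    n = len(x)
    xc = x - x.mean()
    sxx = xc @ xc
    yc = Y - Y.mean(axis=0)
    beta = (xc @ yc) / sxx
    rss = (yc ** 2).sum(axis=0) - beta ** 2 * sxx
    sigma2 = rss / (n - 2)
    se = np.sqrt(np.maximum(sigma2 / sxx, 1e-300))
    return beta / se


def spm_regression(maps: np.ndarray, covariate: np.ndarray,
                   alpha: float = 0.05, n_permutations: int = 1000,
                   seed: int = 0, mask: np.ndarray | None = None) -> SPMResult:
    """Pixel-wise regression of scalp maps on a covariate with FWE control.

    Family-wise error is controlled by max-T permutation: the covariate is
    permuted across subjects (exchangeable under the null), and the observed
    |t| map is thresholded at the 1 - alpha quantile of the permutation
    distribution of the maximum |t| over in-mask pixels.
    """
    M = np.asarray(maps, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if M.ndim != 3:
        raise ValueError("maps must be (n_subjects, height, width)")
    n = M.shape[0]
    if n < 8:
        raise ValueError("need at least 8 subjects")
    if len(x) != n:
        raise ValueError("covariate length must match subject count")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if mask is None:
        mask = np.isfinite(M).all(axis=0)
    Y = M[:, mask]

    t_obs = _pixel_tstats(Y, x)
    rng = np.random.default_rng(seed)
    max_t = np.empty(n_permutations)
    for b in range(n_permutations):
        xp = x[rng.permutation(n)]
        max_t[b] = np.abs(_pixel_tstats(Y, xp)).max()
    thr = float(np.quantile(max_t, 1.0 - alpha))

    tmap = np.full(mask.shape, np.nan)
    tmap[mask] = t_obs
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = np.abs(t_obs) > thr
    clusters, n_clusters = ndimage.label(sig)
    return SPMResult(tmap=tmap, threshold=thr, significant=sig,
                     clusters=clusters, n_clusters=int(n_clusters),
                     mask=mask, fwe_alpha=alpha)
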