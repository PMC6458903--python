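"""Tests for sensor-space spectra, alpha-peak metrics and scalp maps."""

import numpy as np
import pytest

from specdcm import spectral
from specdcm.spectral import (AlphaPeak, PowerSpectrum, alpha_peak,
                              build_scalp_map, channel_positions_2d,
                              covariate_regression, multitaper_psd,
                              regional_average, spm_regression,
                              usable_channels)

FS = 250.0


def _epochs(signal, n_epochs=20, n_t=500):
    return signal[: n_epochs * n_t].reshape(n_epochs, n_t)


# ---------------------------------------------------------------------------
# Multitaper PSD
# ---------------------------------------------------------------------------


def test_pure_tone_peaks_at_its_frequency():
    t = np.arange(20 * 500) / FS
    x = np.sin(2 * np.pi * 10.0 * t)
    ps = multitaper_psd(_epochs(x))
    assert ps.freqs[np.argmax(ps.power)] == pytest.approx(10.0, abs=0.5)


def test_white_noise_parseval(rng):
    sigma = 1.7
    x = rng.normal(0, sigma, 40 * 500)
    ps = multitaper_psd(_epochs(x, 40))
    total = np.trapezoid(ps.power, ps.freqs)
    assert abs(total - sigma ** 2) / sigma ** 2 < 0.10


def test_zero_signal_gives_zero_spectrum():
    ps = multitaper_psd(np.zeros((12, 500)))
    assert np.all(ps.power == 0)


def test_epoch_shorter_than_window_rejected():
    with pytest.raises(ValueError):
        multitaper_psd(np.zeros((12, 50)), window=0.4)


def test_long_window_uses_multiple_tapers(rng):
    # 2-s window at 1.5 Hz half-bandwidth: proper multitaper, still Parseval
    x = rng.normal(0, 1.0, 30 * 500)
    ps = multitaper_psd(_epochs(x, 30), window=2.0, step=2.0)
    total = np.trapezoid(ps.power, ps.freqs)
    assert abs(total - 1.0) < 0.10


# ---------------------------------------------------------------------------
# Regional averages and alpha peak
# ---------------------------------------------------------------------------


def _spec(power, freqs=None):
    freqs = freqs if freqs is not None else np.arange(0, 31.0, 0.5)
    return PowerSpectrum(freqs=freqs, power=power)


def test_regional_average_identity_and_linearity():
    f = np.arange(0, 31.0, 0.5)
    p = np.abs(np.sin(f)) + 1.0
    spectra = {c: _spec(p) for c in spectral.REGIONS["occipital"]}
    out = regional_average(spectra, {"occipital": spectral.REGIONS["occipital"]})
    assert np.allclose(out["occipital"].power, p)
    two = {"a": _spec(p), "b": _spec(3 * p)}
    out2 = regional_average(two, {"r": ["a", "b"]})
    assert np.allclose(out2["r"].power, 2 * p)


def test_regional_average_explicit_oracle(rng):
    f = np.arange(0, 31.0, 0.5)
    chans = spectral.REGIONS["occipital"]
    powers = {c: rng.uniform(0.5, 2.0, len(f)) for c in chans}
    spectra = {c: _spec(powers[c]) for c in chans}
    out = regional_average(spectra, {"occipital": chans})
    oracle = sum(powers[c] for c in chans) / len(chans)
    assert np.allclose(out["occipital"].power, oracle)


def test_regional_average_names_missing_channel():
    spectra = {"E70": _spec(np.ones(63))}
    with pytest.raises(ValueError, match="E71"):
        regional_average(spectra, {"occipital": ["E70", "E71"]})


def test_alpha_peak_finds_injected_peak():
    f = np.arange(0, 31.0, 0.5)
    p = np.exp(-0.5 * ((f - 10.0) / 0.7) ** 2) + 0.1
    pk = alpha_peak(_spec(p))
    assert pk.frequency == pytest.approx(10.0, abs=0.5)


def test_alpha_peak_monotone_spectrum_hits_band_edge():
    f = np.arange(0, 31.0, 0.5)
    pk = alpha_peak(_spec(1.0 / (f + 1.0)))
    assert pk.frequency == 8.0


def test_alpha_peak_two_peak_fixture_selects_stronger():
    f = np.arange(0, 31.0, 0.5)
    p = (2.0 * np.exp(-0.5 * ((f - 9.0) / 0.5) ** 2)
         + 1.0 * np.exp(-0.5 * ((f - 12.0) / 0.5) ** 2) + 0.05)
    assert alpha_peak(_spec(p)).frequency == pytest.approx(
        f[np.argmax(np.where((f >= 8) & (f <= 13), p, 0))])
    assert alpha_peak(_spec(p)).frequency == pytest.approx(9.0, abs=0.5)


def test_alpha_peak_requires_band_coverage():
    with pytest.raises(ValueError):
        alpha_peak(PowerSpectrum(freqs=np.arange(0, 7.0, 0.5),
                                 power=np.ones(14)))


def test_alpha_peak_type_invariants():
    with pytest.raises(ValueError):
        AlphaPeak(amplitude=1.0, frequency=15.0)
    with pytest.raises(ValueError):
        AlphaPeak(amplitude=-1.0, frequency=10.0)


# ---------------------------------------------------------------------------
# Covariate regression
# ---------------------------------------------------------------------------


def test_regression_perfect_fit():
    x = np.linspace(0, 10, 36)
    slope, t, p, df = covariate_regression(2 * x, x)
    assert slope == pytest.approx(2.0)
    assert df == 34
    assert p < 1e-12


def test_regression_explicit_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0])
    X = np.column_stack([np.ones(4), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / 2
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    slope, t, p, df = covariate_regression(y, x)
    assert slope == pytest.approx(beta[1])
    assert t == pytest.approx(beta[1] / se)
    assert df == 2


def test_regression_null_calibration(rng):
    n, reps, alpha = 24, 1000, 0.05
    x = rng.standard_normal(n)
    hits = 0
    for _ in range(reps):
        y = rng.standard_normal(n)
        _, _, p, _ = covariate_regression(y, x)
        hits += p < alpha
    assert 0.03 <= hits / reps <= 0.07


def test_regression_rejects_constant_covariate():
    with pytest.raises(ValueError):
        covariate_regression(np.arange(5.0), np.ones(5))


# ---------------------------------------------------------------------------
# Scalp maps
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def positions():
    return channel_positions_2d()


def test_usable_channels_drop_six():
    chans = usable_channels()
    assert len(chans) == 122


def test_constant_map_is_constant(positions):
    m = build_scalp_map(np.full(len(positions), 3.3), positions)
    assert m.grid.shape == (64, 64)
    vals = m.grid[m.mask]
    assert np.allclose(vals, 3.3, atol=1e-6)


def test_smoothing_preserves_in_mask_mean(positions, rng):
    v = rng.uniform(0, 2, len(positions))
    raw = build_scalp_map(v, positions, smooth_sigma=0.0)
    sm = build_scalp_map(v, positions)
    assert abs(np.nanmean(sm.grid[sm.mask]) - np.nanmean(raw.grid[raw.mask])) \
        < 0.01 * abs(np.nanmean(raw.grid[raw.mask]))


def test_hot_channel_localizes(positions):
    v = np.zeros(len(positions))
    hot = 37
    v[hot] = 10.0
    m = build_scalp_map(v, positions)
    iy, ix = np.unravel_index(np.nanargmax(np.where(m.mask, m.grid, -np.inf)),
                              m.grid.shape)
    ax = np.linspace(-1.05, 1.05, 64)
    px = np.array([ax[ix], ax[iy]])
    dist_px = np.linalg.norm(px - positions[hot]) / (2.1 / 64)
    assert dist_px <= 2.0


def test_scalp_map_input_validation(positions):
    with pytest.raises(ValueError):
        build_scalp_map(np.ones(10), positions[:10])  # too few channels
    dup = positions.copy()
    dup[1] = dup[0]
    with pytest.raises(ValueError):
        build_scalp_map(np.ones(len(dup)), dup)


# ---------------------------------------------------------------------------
# Scalp-map regression with FWE control
# ---------------------------------------------------------------------------


def test_spm_regression_detects_injected_patch(rng):
    n, h = 20, 16
    x = rng.standard_normal(n)
    maps = rng.standard_normal((n, h, h))
    maps[:, 4:10, 4:10] += 3.0 * x[:, None, None]  # strong 6x6 effect
    res = spm_regression(maps, x, n_permutations=500, seed=1)
    patch = res.significant[4:10, 4:10]
    assert patch.mean() >= 0.9
    assert res.n_clusters >= 1


def test_spm_regression_input_validation(rng):
    maps = rng.standard_normal((10, 8, 8))
    with pytest.raises(ValueError):
        spm_regression(maps, np.zeros(10))
    with pytest.raises(ValueError):
        spm_regression(maps[:5], np.arange(5.0))


def test_spm_permutation_distribution_free(rng):
    """The max-T threshold controls family-wise errors for heavy-tailed
    noise as well as Gaussian noise (small spot check)."""
    n, h, reps = 12, 8, 40
    hits_g = hits_t = 0
    for r in range(reps):
        x = rng.standard_normal(n)
        g = rng.standard_normal((n, h, h))
        tnoise = rng.standard_t(df=3, size=(n, h, h))
        rg = spm_regression(g, x, n_permutations=200, seed=r)
        rt = spm_regression(tnoise, x, n_permutations=200, seed=r)
        hits_g += rg.significant.any()
        hits_t += rt.significant.any()
    assert hits_g / reps <= 0.15
    assert hits_t / reps <= 0.15
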