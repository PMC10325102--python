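"""Cross-spectral feature tests, anchored on a direct-summation DFT oracle."""

import numpy as np
import pytest

import dyadsync as ds
from dyadsync.spectral import DEFAULT_BANDS_CPM, SpectralFeature


def dft_cross_periodogram(x, y, fs=1.0):
    """Independent oracle: one-sided cross-periodogram by direct summation."""
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    T = x.size
    F = T // 2 + 1
    freqs = np.arange(F) * fs / T
    p = np.empty(F, complex)
    n = np.arange(T)
    for k in range(F):
        ek = np.exp(-2j * np.pi * k * n / T)
        p[k] = np.conj(np.sum(x * ek)) * np.sum(y * ek) / (fs * T)
    doubled = np.ones(F, bool)
    doubled[0] = False
    if T % 2 == 0:
        doubled[-1] = False
    p[doubled] *= 2.0
    return freqs, p


@pytest.mark.parametrize("T", [4, 5, 8, 9, 16, 31, 32])
def test_matches_direct_dft_oracle(T, rng):
    x = rng.normal(size=T)
    y = rng.normal(size=T)
    freqs, pxy = ds.cross_spectral_density(x, y, sample_rate=1.0)
    freqs_o, pxy_o = dft_cross_periodogram(x, y, 1.0)
    assert len(freqs) == T // 2 + 1
    np.testing.assert_allclose(freqs, freqs_o, atol=1e-12)
    np.testing.assert_allclose(pxy, pxy_o, rtol=1e-9, atol=1e-12)


@pytest.mark.parametrize("T", [4, 5, 6, 7, 600, 601])
def test_bin_count_and_frequency_grid(T):
    x = np.sin(np.arange(T, dtype=float))
    freqs, pxy = ds.cross_spectral_density(x, x, sample_rate=1.0)
    assert len(freqs) == len(pxy) == T // 2 + 1
    assert freqs[0] == 0.0
    # even T reaches Nyquist exactly; odd T stops one half-step short
    top = 0.5 if T % 2 == 0 else (T // 2) / T
    assert freqs[-1] == pytest.approx(top)
    assert np.all(np.diff(freqs) > 0)


def test_pure_sinusoid_concentrates_at_its_bin():
    T, k0 = 600, 30  # 0.05 Hz, an exact bin frequency
    t = np.arange(T)
    x = np.sin(2 * np.pi * k0 * t / T)
    freqs, pxy = ds.cross_spectral_density(x, x)
    mag = np.abs(pxy)
    assert np.argmax(mag) == k0
    off = np.ones(len(mag), bool)
    off[k0 - 1 : k0 + 2] = False
    assert mag[off].max() < 1e-10 * mag[k0]


def test_auto_spectrum_is_real_nonnegative_and_satisfies_parseval(rng):
    x = rng.normal(size=257)
    freqs, pxx = ds.cross_spectral_density(x, x)
    assert np.abs(pxx.imag).max() < 1e-12
    assert pxx.real.min() >= -1e-12
    df = freqs[1] - freqs[0]
    np.testing.assert_allclose(np.sum(pxx.real) * df, np.var(x), rtol=1e-9)


def test_swapping_inputs_conjugates(rng):
    x, y = rng.normal(size=100), rng.normal(size=100)
    _, pxy = ds.cross_spectral_density(x, y)
    _, pyx = ds.cross_spectral_density(y, x)
    np.testing.assert_allclose(pxy, np.conj(pyx), rtol=1e-9, atol=1e-14)


def test_cauchy_schwarz_bound(rng):
    for _ in range(20):
        x, y = rng.normal(size=64), rng.normal(size=64)
        _, pxy = ds.cross_spectral_density(x, y)
        _, pxx = ds.cross_spectral_density(x, x)
        _, pyy = ds.cross_spectral_density(y, y)
        assert np.all(
            np.abs(pxy) <= np.sqrt(pxx.real * pyy.real) * (1 + 1e-9)
        )


@pytest.mark.parametrize(
    "bad",
    [
        (np.ones(10), np.ones(9)),
        (np.ones(3), np.ones(3)),
        (np.array([1.0, np.nan, 0.0, 1.0]), np.ones(4)),
    ],
)
def test_invalid_inputs_raise(bad):
    with pytest.raises(ValueError):
        ds.cross_spectral_density(*bad)


def test_extract_features_moments_and_swap_symmetry(rng):
    a = np.full(50, 0.5)
    b = rng.uniform(-1, 1, size=50)
    d = ds.DyadSeries("c1", "positive", a, b)
    sf = ds.extract_features(d)
    assert sf.mean_a == pytest.approx(0.5)
    assert sf.var_a == 0.0
    assert sf.mean_b == pytest.approx(b.mean())
    assert sf.var_b == pytest.approx(np.var(b))  # population denominator
    swapped = ds.extract_features(ds.DyadSeries("c1", "positive", b, a))
    np.testing.assert_allclose(np.abs(sf.cpsd), np.abs(swapped.cpsd), rtol=1e-9)
    np.testing.assert_allclose(sf.cpsd, np.conj(swapped.cpsd), rtol=1e-9, atol=1e-14)


def test_generated_coupled_dyad_peaks_in_shared_band(rng):
    cfg = ds.GeneratorConfig(
        shared_band=(9.0, 11.0), sd_range=(0.3, 0.3), seed=3
    )
    d = ds.generate_dyad(cfg, coupling=1.0, rng=rng)
    sf = ds.extract_features(d)
    peak_cpm = 60.0 * sf.freqs[np.argmax(np.abs(sf.cpsd))]
    assert 8.0 <= peak_cpm <= 12.0


def _unit_feature(T=600):
    freqs = np.linspace(0, 0.5, T // 2 + 1)
    return SpectralFeature("c", "positive", freqs, np.ones(T // 2 + 1, complex),
                           0.0, 0.0, 1.0, 1.0)


def test_subband_default_partition_covers_all_bins():
    sf = _unit_feature()
    counts = []
    cpm = 60.0 * sf.freqs
    for i, (low, high) in enumerate(DEFAULT_BANDS_CPM):
        if i == len(DEFAULT_BANDS_CPM) - 1:
            counts.append(np.sum((cpm >= low) & (cpm <= high + 1e-9)))
        else:
            counts.append(np.sum((cpm >= low) & (cpm < high)))
    assert len(DEFAULT_BANDS_CPM) == 6
    assert sum(counts) == sf.n_bins == 301


def test_subband_unit_magnitude_gives_zero_log():
    np.testing.assert_allclose(ds.subband_log_magnitude(_unit_feature()), 0.0,
                               atol=1e-12)


def test_subband_amplitude_doubling_adds_log10_4(rng):
    a, b = rng.normal(size=600), rng.normal(size=600)
    sf1 = ds.extract_features(ds.DyadSeries("c", "positive", a, b, bounded=False))
    sf2 = ds.extract_features(
        ds.DyadSeries("c", "positive", 2 * a, 2 * b, bounded=False)
    )
    d = ds.subband_log_magnitude(sf2) - ds.subband_log_magnitude(sf1)
    # all bins scale by 4 except the DC bin, which is exactly zero after
    # constant detrending for both amplitudes; band 1 holds 50 bins
    # (0..4.9 cpm), one of which is that degenerate DC bin
    np.testing.assert_allclose(d[1:], np.log10(4.0), atol=1e-6)
    assert d[0] == pytest.approx(49 / 50 * np.log10(4.0), abs=1e-6)


def test_subband_rejects_bad_bands():
    sf = _unit_feature()
    with pytest.raises(ValueError):
        ds.subband_log_magnitude(sf, bands_cpm=[(0, 40)])  # beyond Nyquist*60
    with pytest.raises(ValueError):
        ds.subband_log_magnitude(sf, bands_cpm=[(5, 10), (0, 5)])  # not ascending


def test_feature_vector_layout(rng):
    a = rng.uniform(-1, 1, size=600)
    b = rng.uniform(-1, 1, size=600)
    sf = ds.extract_features(ds.DyadSeries("c", "positive", a, b))
    vec = ds.feature_vector(sf)
    assert vec.shape == (301 + 4,)
    assert np.isfinite(vec).all()
    np.testing.assert_allclose(vec[:301], np.abs(sf.cpsd))
    np.testing.assert_allclose(vec[301:], [sf.mean_a, sf.mean_b, sf.var_a, sf.var_b])
    vec_ph = ds.feature_vector(sf, include_phase=True)
    assert vec_ph.shape == (2 * 301 + 4,)
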