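"""Spectral estimator and oscillatory-parameter unit tests."""

import numpy as np
import pytest

from megspect import (
    DegenerateBandError,
    DegenerateSpectrumError,
    LagError,
    NormalizedSpectrum,
    aggregate_parameters,
    blackman_tukey_psd,
    compute_parameters,
    global_average,
    individual_alpha_frequency,
    mean_frequency,
    normalize_psd,
    relative_power,
    spectral_entropy,
)
from megspect.spectral import CANONICAL_BANDS, PRINTED_BANDS


def point_mass(freqs, f0):
    p = np.zeros(freqs.size)
    p[np.argmin(np.abs(freqs - f0))] = 1.0
    return NormalizedSpectrum(freqs=freqs, psdn=p)


class TestBlackmanTukey:
    def test_white_noise_spectrum_is_flat(self, rng):
        fs = 500.0
        x = rng.standard_normal((100, 2500))
        f, psd = blackman_tukey_psd(x, fs)
        mean_psd = psd.mean(axis=0)
        sel = (f >= 1) & (f <= 70)
        assert mean_psd[sel].max() / mean_psd[sel].min() < 3.0

    def test_sinusoid_peak_location(self):
        fs = 500.0
        t = np.arange(0, 5, 1 / fs)
        f, psd = blackman_tukey_psd(np.sin(2 * np.pi * 10 * t), fs)
        df = f[1] - f[0]
        assert abs(f[np.argmax(psd)] - 10.0) <= df

    def test_zero_signal_gives_zero_psd(self):
        _, psd = blackman_tukey_psd(np.zeros(2500), 500.0)
        assert np.all(psd == 0.0)

    def test_psd_nonnegative_with_bartlett(self, rng):
        _, psd = blackman_tukey_psd(rng.standard_normal(2500), 500.0)
        assert psd.min() >= 0.0

    def test_hamming_window_also_nonnegative_after_clip(self, rng):
        _, psd = blackman_tukey_psd(
            rng.standard_normal(2500), 500.0, lag_window="hamming"
        )
        assert psd.min() >= 0.0

    def test_max_lag_too_long_raises(self):
        with pytest.raises(LagError):
            blackman_tukey_psd(np.zeros(400), 500.0, max_lag_seconds=1.0)


class TestNormalize:
    def test_constant_psd_gives_uniform_density(self, freqs):
        ns = normalize_psd(freqs, np.full(freqs.size, 3.7))
        assert np.allclose(ns.psdn, 1.0 / freqs.size)

    def test_scale_invariance(self, freqs, rng):
        psd = rng.gamma(2.0, size=freqs.size)
        a = normalize_psd(freqs, psd)
        b = normalize_psd(freqs, 17.3 * psd)
        assert np.allclose(a.psdn, b.psdn)

    def test_out_of_range_bins_dropped(self):
        f = np.arange(0.0, 100.0, 0.5)
        ns = normalize_psd(f, np.ones(f.size))
        assert ns.freqs[0] >= 1.0 and ns.freqs[-1] <= 70.0
        assert np.isclose(ns.psdn.sum(), 1.0)

    def test_single_supported_bin(self, freqs):
        psd = np.zeros(freqs.size)
        psd[40] = 5.0
        ns = normalize_psd(freqs, psd)
        assert ns.psdn[40] == 1.0 and ns.psdn.sum() == 1.0

    def test_all_zero_raises(self, freqs):
        with pytest.raises(DegenerateSpectrumError):
            normalize_psd(freqs, np.zeros(freqs.size))


class TestRelativePower:
    def test_uniform_spectrum_rp_proportional_to_band_width(self, freqs):
        ns = NormalizedSpectrum(freqs=freqs, psdn=np.full(freqs.size, 1.0 / freqs.size))
        beta = CANONICAL_BANDS[5]
        n_beta_bins = int(np.sum((freqs >= 13.0) & (freqs < 26.0)))
        assert np.isclose(relative_power(ns, beta), n_beta_bins / freqs.size)

    def test_point_mass_at_10_falls_in_alpha2_only(self, freqs):
        ns = point_mass(freqs, 10.0)
        rps = [relative_power(ns, b) for b in CANONICAL_BANDS]
        assert rps[3] == 1.0 and sum(rps) == 1.0

    def test_partition_of_unity_on_random_spectra(self, random_spectra):
        total = sum(relative_power(random_spectra, b) for b in CANONICAL_BANDS)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_printed_band_edges_leave_gaps(self, freqs):
        ns = NormalizedSpectrum(freqs=freqs, psdn=np.full(freqs.size, 1.0 / freqs.size))
        total = sum(relative_power(ns, b) for b in PRINTED_BANDS)
        assert total < 1.0  # 3-4, 25-26, 40-41 Hz are uncovered


class TestMedianFrequencies:
    def test_uniform_mf_is_midpoint(self, freqs):
        ns = NormalizedSpectrum(freqs=freqs, psdn=np.full(freqs.size, 1.0 / freqs.size))
        assert abs(mean_frequency(ns) - 35.5) <= freqs[1] - freqs[0]

    def test_symmetric_spectrum_mf_at_centre(self, freqs):
        p = np.exp(-0.5 * ((freqs - 10.0) / 1.5) ** 2)
        ns = NormalizedSpectrum(freqs=freqs, psdn=p / p.sum())
        assert abs(mean_frequency(ns) - 10.0) <= freqs[1] - freqs[0]

    def test_point_mass_mf_exact(self, freqs):
        assert mean_frequency(point_mass(freqs, 6.0)) == pytest.approx(6.0)

    def test_iaf_point_mass(self, freqs):
        assert individual_alpha_frequency(point_mass(freqs, 10.0)) == pytest.approx(10.0)

    def test_iaf_uniform_is_alpha_band_midpoint(self, freqs):
        ns = NormalizedSpectrum(freqs=freqs, psdn=np.full(freqs.size, 1.0 / freqs.size))
        assert abs(individual_alpha_frequency(ns) - 9.5) <= freqs[1] - freqs[0]

    def test_iaf_gaussian_peak_on_floor(self, freqs):
        p = 0.01 + np.exp(-0.5 * ((freqs - 9.0) / 1.0) ** 2)
        ns = NormalizedSpectrum(freqs=freqs, psdn=p / p.sum())
        assert abs(individual_alpha_frequency(ns) - 9.0) < 0.5

    def test_iaf_requires_alpha_mass(self, freqs):
        with pytest.raises(DegenerateBandError):
            individual_alpha_frequency(point_mass(freqs, 50.0))

    def test_median_split_matches_brute_force_within_one_bin(self, random_spectra):
        """Independent oracle: smallest grid node whose cumulative mass >= 1/2."""
        freqs = random_spectra.freqs
        df = freqs[1] - freqs[0]
        mf = mean_frequency(random_spectra)
        for i in range(0, 200, 5):
            cum = np.cumsum(random_spectra.psdn[i])
            brute = freqs[np.searchsorted(cum, 0.5)]
            assert abs(mf[i] - brute) <= df


class TestSpectralEntropy:
    def test_uniform_is_one(self, freqs):
        ns = NormalizedSpectrum(freqs=freqs, psdn=np.full(freqs.size, 1.0 / freqs.size))
        assert spectral_entropy(ns) == pytest.approx(1.0, abs=1e-12)

    def test_point_mass_is_zero(self, freqs):
        assert spectral_entropy(point_mass(freqs, 10.0)) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_lines_closed_form(self, freqs):
        p = np.zeros(freqs.size)
        p[10] = p[200] = 0.5
        ns = NormalizedSpectrum(freqs=freqs, psdn=p)
        assert spectral_entropy(ns) == pytest.approx(
            np.log(2) / np.log(freqs.size), abs=1e-12
        )

    def test_matches_direct_formula_on_random_spectra(self, random_spectra):
        """Independent elementwise evaluation of -1/log(N) sum p log p."""
        n = random_spectra.n_bins
        sse = spectral_entropy(random_spectra)
        for i in range(0, 200, 10):
            p = random_spectra.psdn[i]
            direct = -sum(v * np.log(v) for v in p if v > 0) / np.log(n)
            assert abs(sse[i] - direct) < 1e-12


class TestInvariants:
    def test_raw_signal_scale_invariance(self, rng):
        """All eleven parameters are unchanged under amplitude rescaling."""
        fs = 500.0
        x = rng.standard_normal(2500)
        for sig in (x, 3.7e4 * x):
            f, psd = blackman_tukey_psd(sig, fs)
            params = compute_parameters(normalize_psd(f, psd))
            if sig is x:
                ref = params
        for k in ref:
            assert np.allclose(ref[k], params[k], rtol=1e-9), k

    def test_theta_injection_raises_rpt_and_lowers_mf(self, freqs, rng):
        raw = rng.gamma(1.5, size=freqs.size) + 0.1
        base = NormalizedSpectrum(freqs=freqs, psdn=raw / raw.sum())
        if mean_frequency(base) <= 7.0:
            pytest.skip("median already below theta")
        bump = np.where((freqs >= 4) & (freqs < 7), 1.0, 0.0)
        spiked = raw + bump * raw.sum()
        ns2 = NormalizedSpectrum(freqs=freqs, psdn=spiked / spiked.sum())
        assert relative_power(ns2, CANONICAL_BANDS[1]) > relative_power(
            base, CANONICAL_BANDS[1]
        )
        assert mean_frequency(ns2) < mean_frequency(base)


class TestAggregation:
    def test_single_epoch_identity(self):
        params = {"RPt": np.array([[0.1, 0.2]])}
        assert np.allclose(aggregate_parameters(params)["RPt"], [0.1, 0.2])

    def test_two_epoch_mean(self):
        params = {"RPt": np.array([[0.10], [0.20]])}
        assert aggregate_parameters(params)["RPt"][0] == pytest.approx(0.15)

    def test_global_average_of_constant_regions(self):
        region = {"MF": np.full(103, 9.3)}
        assert global_average(region)["MF"] == pytest.approx(9.3)

    def test_empty_epoch_set_raises(self):
        with pytest.raises(ValueError):
            aggregate_parameters({"RPt": np.empty((0, 3))})
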