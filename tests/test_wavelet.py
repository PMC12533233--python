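"""Morlet CWT, smoothing, coherence: localization, bounds, oracle agreement."""

import math

import numpy as np
import pytest

from plantsync import (
    WaveletParams,
    cone_of_influence,
    fourier_factor,
    morlet_cwt,
    phase_arrow_mask,
    smooth_field,
    wtc,
)

from _reference import reference_smooth, reference_wtc_r2

DT = 180.0


class TestMorletCwt:
    def test_fourier_factor_omega0_6(self):
        assert fourier_factor(6.0) == pytest.approx(4 * math.pi / (6 + math.sqrt(38)))
        assert fourier_factor(6.0) == pytest.approx(1.0330, abs=1e-4)

    def test_constant_signal_vanishes(self):
        res = morlet_cwt(np.full(128, 3.7), DT)
        assert np.abs(res.coeffs).max() < 1e-10

    def test_linearity(self, rng):
        x = rng.standard_normal(200)
        params = WaveletParams.for_signal(200, DT)
        c1 = morlet_cwt(x, DT, params).coeffs
        c2 = morlet_cwt(2.0 * x, DT, params).coeffs
        np.testing.assert_allclose(np.abs(c2), 2.0 * np.abs(c1), rtol=1e-10)

    def test_sinusoid_peak_scale(self, make_sinusoid):
        """Time-averaged power peaks within one dj step of scale T / FF."""
        period = 40.0 * DT
        x = make_sinusoid(512, DT, period)
        res = morlet_cwt(x, DT)
        power = (np.abs(res.coeffs) ** 2).mean(axis=1)
        peak_scale = res.scales[int(np.argmax(power))]
        expected = period / fourier_factor(6.0)
        dj = math.log2(res.scales[1] / res.scales[0])
        assert abs(math.log2(peak_scale / expected)) <= dj + 1e-12

    def test_grid_structure(self):
        params = WaveletParams.for_signal(512, DT)
        res = morlet_cwt(np.random.default_rng(0).standard_normal(512), DT, params)
        assert np.all(np.diff(res.scales) > 0)
        assert np.all(np.diff(res.freqs) < 0)
        assert res.coeffs.shape == (params.n_scales, 512)

    @pytest.mark.parametrize("bad", [np.ones(3), np.array([1.0, np.nan, 2.0, 3.0])])
    def test_bad_signal_rejected(self, bad):
        with pytest.raises(ValueError):
            morlet_cwt(bad, DT)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WaveletParams(s0=90.0, dt=DT)  # s0 < dt
        with pytest.raises(ValueError):
            WaveletParams(n_scales=1, dt=DT)


class TestSmoothField:
    def scales(self, k=16):
        return WaveletParams.for_signal(256, DT).scales[:k]

    def test_preserves_constants(self):
        field = np.ones((16, 64))
        np.testing.assert_allclose(smooth_field(field, self.scales(), DT), field, atol=1e-12)

    def test_preserves_nonnegativity(self, rng):
        field = rng.random((16, 64))
        assert smooth_field(field, self.scales(), DT).min() >= 0

    def test_matches_direct_convolution_oracle(self, rng):
        field = rng.random((16, 64))
        ours = smooth_field(field, self.scales(), DT)
        ref = reference_smooth(field, self.scales(), DT)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_delta_spike_mass_and_spread(self):
        """Smoothing conserves mass away from boundaries and spreads
        monotonically with scale."""
        field = np.zeros((16, 64))
        field[8, 32] = 1.0
        out = smooth_field(field, self.scales(), DT)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        # time spread of each row containing mass grows with scale
        widths = []
        for row in out:
            if row.sum() > 1e-9:
                t = np.arange(64)
                mu = (t * row).sum() / row.sum()
                widths.append(((t - mu) ** 2 * row).sum() / row.sum())
        assert all(b >= a - 1e-9 for a, b in zip(widths, widths[1:]))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            smooth_field(np.ones((4, 10)), self.scales(16), DT)


class TestWtc:
    def test_self_coherence(self, rng):
        x = rng.standard_normal(256)
        res = wtc(x, x, DT)
        assert res.r2.mean() > 0.999

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="align"):
            wtc(rng.standard_normal(100), rng.standard_normal(90), DT)

    def test_lagged_sinusoids_phase_and_coherence(self, make_sinusoid):
        """Two sinusoids lagged by tau: r2 > 0.9 at that period and the
        cross-wavelet phase recovers 2*pi*tau/T."""
        period = 32.0 * DT
        tau = 4.0 * DT
        a = make_sinusoid(512, DT, period)
        b = make_sinusoid(512, DT, period, phase=-2 * math.pi * tau / period)
        res = wtc(a, b, DT)
        row = int(np.argmin(np.abs(res.scales - period / fourier_factor(6.0))))
        inside = res.coi_mask[row]
        assert res.r2[row][inside].mean() > 0.9
        high = inside & (res.r2[row] > 0.9)
        expected = 2 * math.pi * tau / period
        assert np.abs(res.phase[row][high] - expected).max() < 0.1

    def test_bounded_for_white_noise(self, rng):
        for _ in range(10):
            a = rng.standard_normal(128)
            b = rng.standard_normal(128)
            res = wtc(a, b, DT)
            assert res.r2.min() >= 0.0 and res.r2.max() <= 1.0

    def test_matches_brute_force_reference(self, rng):
        """FFT-path coherence agrees with the naive time-domain oracle
        inside the cone of influence."""
        n = 300
        t = np.arange(n) * DT
        a = np.sin(2 * np.pi * t / 8000) + 0.3 * rng.standard_normal(n)
        b = np.sin(2 * np.pi * (t - 900) / 8000) + 0.3 * rng.standard_normal(n)
        params = WaveletParams.for_signal(n, DT)
        res = wtc(a, b, DT, params)
        ref = reference_wtc_r2(a, b, DT, params.scales)
        mad = np.abs(res.r2 - ref)[res.coi_mask].mean()
        assert mad < 0.05


class TestConeOfInfluence:
    def params(self):
        return WaveletParams.for_signal(100, DT)

    def test_symmetric(self):
        coi = cone_of_influence(100, DT, self.params())
        np.testing.assert_allclose(coi, coi[::-1])

    def test_monotone_to_center(self):
        coi = cone_of_influence(101, DT, self.params())
        assert np.all(np.diff(coi[:50]) > 0)
        assert np.all(np.diff(coi[51:]) < 0)
        assert coi.argmax() in (49, 50, 51)

    def test_center_value_formula(self):
        coi = cone_of_influence(100, DT, self.params())
        expected = fourier_factor(6.0) * math.sqrt(2.0) * DT * 49.5
        assert coi.max() == pytest.approx(expected, rel=1e-12)


class TestPhaseArrowMask:
    def test_threshold_cases(self, rng):
        x = rng.standard_normal(128)
        res = wtc(x, x, DT)
        res.r2 = np.full_like(res.r2, 0.4)
        assert phase_arrow_mask(res).sum() == 0
        res.r2 = np.ones_like(res.r2)
        assert phase_arrow_mask(res).all()
        mixed = rng.random(res.r2.shape)
        res.r2 = mixed
        assert phase_arrow_mask(res).sum() == int((mixed > 0.5).sum())

    def test_invalid_threshold_rejected(self, rng):
        x = rng.standard_normal(128)
        res = wtc(x, x, DT)
        with pytest.raises(ValueError):
            phase_arrow_mask(res, threshold=1.5)
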