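"""MPS estimator: peak recovery, normalization, contours and Welch behavior."""

import numpy as np
import pytest

from audspec.cochlear import Cochleogram
from audspec.gabor import Spectrogram
from audspec.mps import (
    ModulationPowerSpectrum,
    ModulationRange,
    mask_static_band,
    mps_marginals,
    power_contour,
    welch_mps,
)


def _fourier_rep(values, frame_rate=2100.0, spacing_hz=10.0):
    freqs = 100.0 + spacing_hz * np.arange(values.shape[1])
    return Spectrogram(values=values.astype(np.float32), frame_rate=frame_rate, freqs=freqs)


def _cochlear_rep(values, frame_rate=2100.0):
    cfs = 100.0 * 2.0 ** (0.01 * np.arange(1, values.shape[1] + 1))
    return Cochleogram(
        values=values.astype(np.float32), env_fs=frame_rate, cfs=cfs, octaves=np.log2(cfs / 100.0)
    )


class TestWelchMPS:
    def test_constant_input_concentrates_at_dc(self):
        rep = _fourier_rep(np.full((4200, 64), 3.0))
        mps = welch_mps(rep, remove_segment_mean=False, window="boxcar")
        peak = np.unravel_index(np.argmax(mps.power), mps.power.shape)
        assert mps.fm_axis[peak[0]] == 0.0
        assert mps.omega_axis[peak[1]] == 0.0
        # without a taper the transform of a constant is a single DC line
        assert mps.power[peak] / mps.power.sum() > 1.0 - 1e-9

    def test_ripple_peak_recovered_within_one_bin(self):
        f0, om0 = 8.0, 2.0  # Hz, cyc/kHz
        t = np.arange(6300) / 2100.0
        x_khz = 0.1 + 0.01 * np.arange(256)
        ripple = 1.0 + np.cos(2 * np.pi * (om0 * x_khz[None, :] + f0 * t[:, None]))
        mps = welch_mps(_fourier_rep(ripple), remove_segment_mean=True)
        peak = np.unravel_index(np.argmax(mps.power), mps.power.shape)
        assert abs(abs(mps.fm_axis[peak[0]]) - f0) <= mps.d_fm
        assert abs(mps.omega_axis[peak[1]] - om0) <= mps.d_omega
        temporal, _ = mps_marginals(mps)
        assert abs(abs(mps.fm_axis[np.argmax(temporal)]) - f0) <= mps.d_fm

    def test_parseval_total_power(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((6300, 128))
        rep = _fourier_rep(vals)
        mps = welch_mps(rep, segment_dur=1.0, window="boxcar", remove_segment_mean=False)
        n_used = mps.n_segments * int(1.0 * 2100)
        ms = np.mean(vals[:n_used] ** 2)
        assert np.isclose(mps.total_power(), ms, rtol=1e-6)

    def test_welch_averaging_reduces_bin_scatter(self):
        # relative bin scatter of a flat MPS shrinks ~ 1/sqrt(n_segments)
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((16 * 1050, 96))
        scatter = {}
        for n_seg, frames in ((2, 16 * 1050), (8, 16 * 1050)):
            rep = _fourier_rep(vals[:frames], frame_rate=1050.0)
            mps = welch_mps(rep, segment_dur=16.0 / n_seg, window="boxcar")
            p = mps.power[:, 1:-1][1:-1]
            scatter[n_seg] = p.std() / p.mean()
        assert np.isclose(scatter[2] / scatter[8], 2.0, atol=0.4)

    def test_kaiser_temporal_resolution_near_nominal(self):
        # 1.5 s Kaiser (beta 3.4) window: ~0.8 Hz 3 dB modulation resolution
        win = np.kaiser(3150, 3.4)
        mag2 = np.abs(np.fft.rfft(win, 1 << 20)) ** 2
        f = np.fft.rfftfreq(1 << 20, 1 / 2100.0)
        half = f[np.searchsorted(-mag2, -mag2[0] / 2)]
        assert 0.6 < 2 * half < 0.9

    def test_units_follow_source(self):
        f_mps = welch_mps(_fourier_rep(np.ones((3150, 32)) + 0.0))
        c_mps = welch_mps(_cochlear_rep(np.ones((3150, 32)) + 0.0))
        assert f_mps.omega_unit == "cyc/kHz"
        assert c_mps.omega_unit == "cyc/oct"

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="shorter than one"):
            welch_mps(_fourier_rep(np.ones((100, 8))))


def _synthetic_mps(power, fm, om):
    return ModulationPowerSpectrum(
        power=power, fm_axis=fm, omega_axis=om, omega_unit="cyc/oct",
        source="cochlear", n_segments=1, dc_removed=True,
    )


class TestContour:
    def test_gaussian_contour_matches_closed_form_quantile(self):
        # separable Gaussian density: 90% super-level set is an ellipse with
        # radius sqrt(2 ln 10) sigma on each axis
        fm = np.linspace(-200, 200, 801)
        om = np.linspace(0, 30, 301)
        sf, so = 40.0, 5.0
        P = np.exp(-(fm[:, None] ** 2) / (2 * sf**2) - (om[None, :] ** 2) / (2 * so**2))
        mrange = power_contour(_synthetic_mps(P, fm, om), 0.9)
        r = np.sqrt(2 * np.log(10.0))
        assert abs(mrange.fm_max - r * sf) <= 2 * (fm[1] - fm[0])
        assert abs(mrange.omega_max - r * so) <= 2 * (om[1] - om[0])

    def test_full_fraction_returns_full_extent(self):
        fm = np.linspace(-10, 10, 21)
        om = np.linspace(0, 5, 11)
        P = np.random.default_rng(0).uniform(0.1, 1.0, (21, 11))
        mrange = power_contour(_synthetic_mps(P, fm, om), 1.0)
        assert mrange.fm_max == 10.0 and mrange.omega_max == 5.0

    def test_single_bin_mps(self):
        fm = np.linspace(-10, 10, 21)
        om = np.linspace(0, 5, 11)
        P = np.zeros((21, 11))
        P[15, 4] = 1.0
        mrange = power_contour(_synthetic_mps(P, fm, om), 0.5)
        assert mrange.fm_max == abs(fm[15]) and mrange.omega_max == om[4]

    def test_all_zero_rejected(self):
        fm = np.linspace(-1, 1, 5)
        om = np.linspace(0, 1, 3)
        with pytest.raises(ValueError):
            power_contour(_synthetic_mps(np.zeros((5, 3)), fm, om), 0.9)


class TestMarginalsAndMask:
    def test_marginals_unit_sum_and_factor_recovery(self):
        fm = np.linspace(-20, 20, 41)
        om = np.linspace(0, 10, 21)
        p = np.exp(-np.abs(fm) / 5)
        q = np.exp(-om / 2)
        mps = _synthetic_mps(np.outer(p, q), fm, om)
        temporal, spectral = mps_marginals(mps)
        assert np.isclose(temporal.sum(), 1.0, atol=1e-9)
        assert np.isclose(spectral.sum(), 1.0, atol=1e-9)
        assert np.allclose(temporal, p / p.sum(), atol=1e-12)
        assert np.allclose(spectral, q / q.sum(), atol=1e-12)

    def test_static_band_mask_zeroes_slow_rows_only(self):
        fm = np.arange(-10, 11, 1.0)
        om = np.linspace(0, 5, 6)
        mps = _synthetic_mps(np.ones((21, 6)), fm, om)
        masked = mask_static_band(mps, n_rows=2)
        assert masked.power[np.abs(fm) <= 2].sum() == 0.0
        assert np.all(masked.power[np.abs(fm) > 2] == 1.0)

    def test_restriction_outside_axes_rejected(self):
        from audspec.mps import restrict_mps

        fm = np.linspace(-10, 10, 21)
        om = np.linspace(1, 5, 9)
        mps = _synthetic_mps(np.ones((21, 9)), fm, om)
        with pytest.raises(ValueError):
            restrict_mps(mps, ModulationRange(10.0, 0.5, 0.9))
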