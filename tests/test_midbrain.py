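"""STRF filterbank: constant-Q tuning, MTF gains, and the two MPS routes."""

import numpy as np
import pytest

from audspec.cochlear import Cochleogram
from audspec.midbrain import (
    STRFGrid,
    STRFSpec,
    default_strf_grid,
    make_strf,
    midbrain_filter_output,
    midbrain_mps,
    mtf,
    mtf_magnitude,
    strf_kernel,
    strf_secondary_params,
)
from audspec.mps import ModulationPowerSpectrum, welch_mps


def _measured_3db_bw(spec, axis):
    """Half-power full width of |MTF| along one axis through the peak."""
    if axis == "temporal":
        z = spec.fm0 + abs(spec.fm0) * np.linspace(-1.5, 1.5, 4001)
        mag = mtf_magnitude(spec, z, np.full_like(z, spec.omega0))
        grid = z
    else:
        g = spec.omega0 * np.linspace(0.05, 3.0, 4001)
        mag = mtf_magnitude(spec, np.full_like(g, spec.fm0), g)
        grid = g
    p = mag**2
    half = p.max() / 2.0
    above = np.where(p >= half)[0]
    lo = np.interp(half, [p[above[0] - 1], p[above[0]]], [grid[above[0] - 1], grid[above[0]]])
    hi = np.interp(half, [p[above[-1] + 1], p[above[-1]]], [grid[above[-1] + 1], grid[above[-1]]])
    return hi - lo


class TestSecondaryParams:
    def test_closed_form_values(self):
        tau, bw = strf_secondary_params(512.0, 1.0)
        assert np.isclose(tau, np.sqrt(np.sqrt(2) - 1) / (np.pi * 512.0), rtol=1e-12)
        assert np.isclose(tau * 1e3, 0.40, atol=0.005)
        # half-power convention on the spectral axis: 2 sqrt(ln 2)/pi
        assert np.isclose(bw, 0.5300, atol=5e-4)

    def test_zero_arguments_rejected(self):
        with pytest.raises(ValueError):
            strf_secondary_params(0.0, 1.0)
        with pytest.raises(ValueError):
            strf_secondary_params(8.0, 0.0)

    def test_constant_q_across_whole_grid(self):
        # measured 3 dB MTF bandwidth / center = 1 +- 0.05 on both axes
        grid = default_strf_grid()
        worst_t, worst_s = 0.0, 0.0
        for fm0 in grid.fm0_values:
            for om0 in grid.omega0_values:
                tau, bw = strf_secondary_params(fm0, om0)
                spec = STRFSpec(fm0=fm0, omega0=om0, tau=tau, bw=bw)
                qt = _measured_3db_bw(spec, "temporal") / abs(fm0)
                qs = _measured_3db_bw(spec, "spectral") / om0
                worst_t = max(worst_t, abs(qt - 1.0))
                worst_s = max(worst_s, abs(qs - 1.0))
        assert worst_t <= 0.05
        assert worst_s <= 0.05


class TestKernelAndMTF:
    def test_kernel_zero_at_time_origin(self):
        kern, t, x = strf_kernel(make_strf(16.0, 0.5), 2100.0, 0.01)
        assert np.all(kern[0] == 0.0)

    def test_sign_flip_mirrors_orientation(self):
        k_pos, _, _ = strf_kernel(make_strf(16.0, 0.5), 2100.0, 0.01)
        k_neg, _, _ = strf_kernel(make_strf(-16.0, 0.5), 2100.0, 0.01)
        assert np.allclose(k_neg, k_pos[:, ::-1], atol=1e-12)

    def test_under_resolved_kernel_rejected(self):
        with pytest.raises(ValueError, match="under-resolves"):
            strf_kernel(make_strf(512.0, 0.5), 2100.0, 0.01)
        with pytest.raises(ValueError, match="under-resolves"):
            strf_kernel(make_strf(8.0, 3.0), 2100.0, 0.1)

    @pytest.mark.parametrize("fm0,om0", [(4.0, 0.2), (-16.0, 0.5), (64.0, 1.0), (181.0, 3.4)])
    def test_unit_peak_mtf_measured_from_kernel(self, fm0, om0):
        spec = make_strf(fm0, om0)
        mag, _, _ = mtf(spec, env_fs=max(2100.0, 32 * abs(fm0)), x_step=0.005, n_pad=8)
        assert abs(mag.max() - 1.0) < 0.02

    def test_mtf_peak_location_within_one_bin(self):
        spec = make_strf(64.0, 0.5)
        mag, zeta, gamma = mtf(spec, env_fs=4200.0, x_step=0.005, n_pad=8)
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        assert abs(zeta[i] - 64.0) <= zeta[1] - zeta[0]
        assert abs(gamma[j] - 0.5) <= gamma[1] - gamma[0]

    def test_mtf_symmetric_under_fm0_sign_flip(self):
        z = np.linspace(-200, 200, 401)
        g = np.linspace(0, 3, 61)
        m_pos = mtf_magnitude(make_strf(32.0, 0.8), z[:, None], g[None, :])
        m_neg = mtf_magnitude(make_strf(-32.0, 0.8), z[:, None], g[None, :])
        assert np.allclose(m_neg, m_pos[::-1, :], atol=1e-12)


class TestFilterOutput:
    def _ripple_cochleogram(self, fm0, om0, amp=0.5, duration=4.0):
        t = np.arange(int(duration * 2100)) / 2100.0
        cfs = 100.0 * 2.0 ** (0.01 * np.arange(1, 665))
        x = np.log2(cfs / 100.0)
        vals = 1.0 + amp * np.cos(2 * np.pi * (om0 * x[None, :] + fm0 * t[:, None]))
        return Cochleogram(values=vals.astype(np.float32), env_fs=2100.0, cfs=cfs, octaves=x)

    def test_ripple_at_center_passes_with_unity_gain(self):
        fm0, om0 = -16.0, 1.0  # bw(1.0) keeps the kernel inside the channel range
        coch = self._ripple_cochleogram(fm0, om0)
        out = midbrain_filter_output(coch, make_strf(fm0, om0))
        interior = out[1050:-1050, 200:460]  # clear of kernel-length edges
        meas = np.sqrt(2.0) * interior.std()
        assert np.isclose(meas, 0.5, rtol=0.05)

    def test_dc_cochleogram_strongly_attenuated(self):
        # constant input passes only through the (small) MTF value at the origin
        spec = make_strf(16.0, 1.0)
        cfs = 100.0 * 2.0 ** (0.01 * np.arange(1, 665))
        coch = Cochleogram(
            values=np.full((4200, 664), 2.0, np.float32),
            env_fs=2100.0, cfs=cfs, octaves=np.log2(cfs / 100.0),
        )
        out = midbrain_filter_output(coch, spec)
        mtf00 = float(mtf_magnitude(spec, 0.0, 0.0))
        assert mtf00 < 0.15  # band-pass: well below the unit peak gain
        interior = out[1050:-1050, 200:460]
        assert np.allclose(interior, np.sign(interior.mean()) * 2.0 * mtf00, rtol=0.05)

    def test_linearity(self):
        coch = self._ripple_cochleogram(8.0, 0.5, duration=2.0)
        spec = make_strf(8.0, 0.5)
        out1 = midbrain_filter_output(coch, spec)
        coch2 = Cochleogram(
            values=3.0 * coch.values, env_fs=2100.0, cfs=coch.cfs, octaves=coch.octaves
        )
        out2 = midbrain_filter_output(coch2, spec)
        assert np.allclose(out2, 3.0 * out1, rtol=1e-5, atol=1e-6)


class TestMidbrainMPS:
    def test_routes_agree_on_stationary_field(self, smooth_field):
        grid = STRFGrid((-32.0, 8.0, 32.0, 64.0), (0.6, 1.5))
        m_td = midbrain_mps(smooth_field, grid, route="time_domain")
        mps_c = welch_mps(smooth_field, segment_dur=8.0, window="boxcar")
        m_md = midbrain_mps(mps_c, grid, route="modulation_domain")
        ratio = m_td.power / m_md.power
        assert np.max(np.abs(ratio - 1.0)) < 0.10  # per filter
        assert abs(m_td.power.sum() / m_md.power.sum() - 1.0) < 0.02  # summed

    def test_single_ripple_peaks_at_nearest_grid_filter(self, smooth_field):
        t = np.arange(8 * 2100) / 2100.0
        x = smooth_field.octaves
        vals = np.cos(2 * np.pi * (0.6 * x[None, :] - 32.0 * t[:, None]))
        coch = Cochleogram(
            values=vals.astype(np.float32), env_fs=2100.0,
            cfs=smooth_field.cfs, octaves=x,
        )
        grid = STRFGrid((-64.0, -32.0, -8.0, 8.0, 32.0, 64.0), (0.3, 0.6, 1.2))
        mps_c = welch_mps(coch, segment_dur=8.0, window="boxcar")
        mm = midbrain_mps(mps_c, grid)
        i, j = np.unravel_index(np.argmax(mm.power), mm.power.shape)
        assert grid.fm0_values[i] == -32.0
        assert grid.omega0_values[j] == 0.6

    def test_one_over_f_input_is_whitened(self):
        # MPS_C ~ 1/(|f_m| Omega): constant-Q bandwidth gain flattens the grid output
        fm = np.fft.fftshift(np.fft.fftfreq(3150, 1 / 2100.0))
        om = np.arange(333) / (664 * 0.01)
        F, O = np.meshgrid(np.abs(fm), om, indexing="ij")
        P = 1.0 / np.maximum(F, 0.5) / np.maximum(O, 0.07)
        mps_c = ModulationPowerSpectrum(P, fm, om, "cyc/oct", "cochlear", 1, True)
        grid = default_strf_grid()
        mm = midbrain_mps(mps_c, grid)
        db = 10 * np.log10(mm.power)
        # exclude the lowest omega0 column: 0.1 cyc/oct sits below the
        # 1/6.64 oct spectral-modulation resolution of the cochleogram MPS
        resolved = np.asarray(grid.omega0_values) >= 0.15
        dev = db[:, resolved] - db[:, resolved].mean()
        assert np.max(np.abs(dev)) < 3.0

    def test_unit_mismatch_rejected(self):
        fm = np.linspace(-50, 50, 101)
        om = np.linspace(0, 20, 41)
        bad = ModulationPowerSpectrum(
            np.ones((101, 41)), fm, om, "cyc/kHz", "fourier", 1, True
        )
        with pytest.raises(ValueError, match="cyc/oct"):
            midbrain_mps(bad, default_strf_grid())
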