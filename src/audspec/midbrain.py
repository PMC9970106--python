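"""Mid-level (auditory midbrain) STRF filterbank with constant-Q modulation tuning.

Inferior-colliculus neurons are selective for spectro-temporal modulations of
the cochlear output, with modulation bandwidths that scale proportional to
the best modulation frequency (quality factor Q ~ 1).  Each model filter is a
Gabor-alpha spectro-temporal receptive field (STRF)

    STRF(t, x) = A * (t/tau) * exp(-(t - tau)/tau) * exp(-2 x^2 / bw^2)
                 * cos(2 pi Omega0 x + 2 pi fm0 t + phi) * u(t)

with best temporal modulation ``fm0`` (signed Hz; the sign selects upward vs
downward ripple orientation) and best spectral modulation ``Omega0``
(cycles/octave).  The secondary parameters are tied to the primaries so that
the measured 3 dB (half-power) bandwidths of the modulation transfer function
(MTF) equal the best modulation frequencies on both axes:

    tau = sqrt(sqrt(2) - 1) / (pi |fm0|)
    bw  = 2 sqrt(ln 2)      / (pi Omega0)

and the amplitude ``A`` is normalized numerically to unit peak |MTF|.
The filterbank covers ``fm0 = +-(2 .. 512) Hz`` in quarter-octave steps and
``Omega0 = 0.1 .. 3.6 cyc/oct`` in tenth-octave steps.

The midbrain modulation power spectrum is the power at each filter output.
It can be computed by convolving STRF kernels with the cochleogram
(``route="time_domain"``) or, via Parseval's theorem, by integrating
``|MTF|**2`` against the cochlear MPS (``route="modulation_domain"``); the
latter uses the closed-form MTF and is the cheap default for long sounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .mps import ModulationPowerSpectrum

__all__ = [
    "STRFSpec",
    "STRFGrid",
    "strf_secondary_params",
    "make_strf",
    "default_strf_grid",
    "mtf_magnitude",
    "strf_kernel",
    "mtf",
    "midbrain_filter_output",
    "midbrain_mps",
]

_SQRT_SQRT2_M1 = np.sqrt(np.sqrt(2.0) - 1.0)
_2_SQRT_LN2 = 2.0 * np.sqrt(np.log(2.0))


def strf_secondary_params(fm0: float, omega0: float) -> tuple[float, float]:
    """Temporal decay ``tau`` (s) and spectral spread ``bw`` (oct) for Q = 1.

    Chosen so the 3 dB MTF bandwidths equal ``|fm0|`` and ``omega0``.
    """
    if fm0 == 0 or omega0 <= 0:
        raise ValueError("fm0 must be nonzero and omega0 positive")
    tau = _SQRT_SQRT2_M1 / (np.pi * abs(fm0))
    bw = _2_SQRT_LN2 / (np.pi * omega0)
    return tau, bw


@dataclass(frozen=True)
class STRFSpec:
    """One STRF: best modulation frequencies, derived spread parameters, gain."""

    fm0: float  # signed Hz
    omega0: float  # cyc/oct
    tau: float  # s
    bw: float  # oct
    phase: float = 0.0
    amplitude: float = 1.0


def _mtf_unnorm(spec: STRFSpec, zeta, gamma):
    """Closed-form 2D Fourier transform of the STRF (amplitude = 1).

    ``Et`` is the transform of the alpha envelope ``(e/tau) t exp(-t/tau)``,
    ``Gx`` the transform of the spectral Gaussian; the cosine carrier splits
    the MTF into lobes at ``(fm0, omega0)`` and ``(-fm0, -omega0)``.
    """
    zeta = np.asarray(zeta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)

    def Et(f):
        return np.e * spec.tau / (1.0 + 2j * np.pi * f * spec.tau) ** 2

    def Gx(g):
        return spec.bw * np.sqrt(np.pi / 2.0) * np.exp(-np.pi**2 * g**2 * spec.bw**2 / 2.0)

    term1 = np.exp(1j * spec.phase) * Et(zeta - spec.fm0) * Gx(gamma - spec.omega0)
    term2 = np.exp(-1j * spec.phase) * Et(zeta + spec.fm0) * Gx(gamma + spec.omega0)
    return 0.5 * (term1 + term2)


def make_strf(fm0: float, omega0: float, phase: float = 0.0) -> STRFSpec:
    """Build an STRF with Q = 1 secondary parameters and unit peak |MTF|."""
    tau, bw = strf_secondary_params(fm0, omega0)
    raw = STRFSpec(fm0=fm0, omega0=omega0, tau=tau, bw=bw, phase=phase, amplitude=1.0)
    zg = fm0 + abs(fm0) * np.linspace(-0.8, 0.8, 401)
    gg = omega0 * np.linspace(0.2, 1.8, 201)
    peak = np.max(np.abs(_mtf_unnorm(raw, zg[:, None], gg[None, :])))
    return STRFSpec(fm0=fm0, omega0=omega0, tau=tau, bw=bw, phase=phase, amplitude=1.0 / peak)


def mtf_magnitude(spec: STRFSpec, zeta, gamma):
    """|MTF| at temporal modulation ``zeta`` (Hz) and spectral modulation ``gamma`` (cyc/oct)."""
    return spec.amplitude * np.abs(_mtf_unnorm(spec, zeta, gamma))


@dataclass(frozen=True)
class STRFGrid:
    """Octave-spaced constant-Q filter grid (symmetric in the sign of fm0)."""

    fm0_values: tuple[float, ...]  # signed, ordered by magnitude then sign
    omega0_values: tuple[float, ...]
    phase: float = 0.0

    def specs(self) -> list[STRFSpec]:
        return [make_strf(f, o, self.phase) for f in self.fm0_values for o in self.omega0_values]


def default_strf_grid(
    fm_min: float = 2.0,
    fm_max: float = 512.0,
    fm_step_oct: float = 0.25,
    omega_min: float = 0.1,
    omega_max: float = 3.6,
    omega_step_oct: float = 0.1,
    phase: float = 0.0,
) -> STRFGrid:
    """Default grid: fm0 = +-2..512 Hz (1/4 oct), Omega0 = 0.1..3.6 cyc/oct (1/10 oct)."""
    n_fm = int(np.floor(np.log2(fm_max / fm_min) / fm_step_oct + 1e-9)) + 1
    mags = fm_min * 2.0 ** (fm_step_oct * np.arange(n_fm))
    fm0 = np.concatenate([-mags[::-1], mags])
    n_om = int(np.floor(np.log2(omega_max / omega_min) / omega_step_oct + 1e-9)) + 1
    om0 = omega_min * 2.0 ** (omega_step_oct * np.arange(n_om))
    return STRFGrid(tuple(fm0), tuple(om0), phase)


def strf_kernel(
    spec: STRFSpec, env_fs: float, x_step: float, t_max_tau: float = 12.0, x_max_bw: float = 3.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled STRF kernel, scaled so discrete 2D convolution has unit peak MTF gain.

    Requires at least 8 samples per carrier period on each axis; raises
    otherwise, naming the rates needed.  Returns ``(kernel, t, x)`` with
    ``t`` causal from 0 and ``x`` symmetric about 0.
    """
    if env_fs < 8.0 * abs(spec.fm0):
        raise ValueError(
            f"env_fs = {env_fs:g} Hz under-resolves fm0 = {spec.fm0:g} Hz; need >= {8 * abs(spec.fm0):g} Hz"
        )
    if x_step > 1.0 / (8.0 * spec.omega0):
        raise ValueError(
            f"x_step = {x_step:g} oct under-resolves omega0 = {spec.omega0:g} cyc/oct; "
            f"need <= {1.0 / (8.0 * spec.omega0):g} oct"
        )
    t = np.arange(0.0, t_max_tau * spec.tau, 1.0 / env_fs)
    half = int(np.ceil(x_max_bw * spec.bw / x_step))
    x = np.arange(-half, half + 1) * x_step
    envelope_t = (t / spec.tau) * np.exp(-(t - spec.tau) / spec.tau)
    envelope_x = np.exp(-2.0 * x**2 / spec.bw**2)
    carrier = np.cos(
        2 * np.pi * spec.omega0 * x[None, :] + 2 * np.pi * spec.fm0 * t[:, None] + spec.phase
    )
    kern = spec.amplitude * envelope_t[:, None] * envelope_x[None, :] * carrier
    # discrete convolution approximates the continuous integral times (dt dx)
    kern *= (1.0 / env_fs) * x_step
    return kern, t, x


def mtf(
    spec: STRFSpec, env_fs: float = 2100.0, x_step: float = 0.01, n_pad: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Numerically measured MTF: magnitude of the 2D FFT of the sampled kernel.

    Independent of the closed form used by the modulation-domain route, so the
    two can be cross-checked.  Returns ``(magnitude, zeta_axis, gamma_axis)``
    on the folded (signed zeta, gamma >= 0) grid.
    """
    kern, t, x = strf_kernel(spec, env_fs, x_step)
    nt = n_pad * kern.shape[0]
    nx = n_pad * kern.shape[1]
    spect = np.fft.rfft2(kern, s=(nt, nx))
    # undo the (dt dx) scaling: the DFT sum times dt dx is the continuous FT
    mag = np.abs(spect)
    mag = np.fft.fftshift(mag, axes=0)
    zeta = np.fft.fftshift(np.fft.fftfreq(nt, 1.0 / env_fs))
    gamma = np.arange(nx // 2 + 1) / (nx * x_step)
    return mag, zeta, gamma


def midbrain_filter_output(coch, spec: STRFSpec) -> np.ndarray:
    """Convolve one STRF with a cochleogram; same time length as the input.

    The kernel is causal in time and centered on the spectral axis; edge
    frames within one kernel length are transient.
    """
    vals = np.asarray(coch.values, dtype=np.float64)
    dx = float(coch.channel_positions[1] - coch.channel_positions[0])
    kern, _, x = strf_kernel(spec, coch.frame_rate, dx)
    if kern.shape[0] > vals.shape[0] or kern.shape[1] > vals.shape[1]:
        raise ValueError("STRF kernel larger than the cochleogram")
    full = fftconvolve(vals, kern, mode="full")
    x0 = len(x) // 2
    return full[: vals.shape[0], x0 : x0 + vals.shape[1]]


def _eq19_grid_power(mps_c: ModulationPowerSpectrum, grid: STRFGrid) -> np.ndarray:
    """Integrate |MTF|^2 against the cochlear MPS for every grid filter.

    Exploits the separability of the two MTF lobes (and their cross term) in
    (zeta, gamma) to reduce the whole grid to a handful of matrix products.
    """
    zeta = mps_c.fm_axis
    gamma = mps_c.omega_axis
    P = mps_c.power * (mps_c.d_fm * mps_c.d_omega)
    fm0s = np.asarray(grid.fm0_values)
    om0s = np.asarray(grid.omega0_values)
    specs = {}
    amp = np.empty((fm0s.size, om0s.size))
    for i, f in enumerate(fm0s):
        for j, o in enumerate(om0s):
            s = make_strf(f, o, grid.phase)
            specs[(i, j)] = s
            amp[i, j] = s.amplitude
    # tau and bw depend only on |fm0| and omega0 -> per-column parameters
    taus = _SQRT_SQRT2_M1 / (np.pi * np.abs(fm0s))
    bws = _2_SQRT_LN2 / (np.pi * om0s)

    def Et(f, tau):
        return np.e * tau / (1.0 + 2j * np.pi * f * tau) ** 2

    def Gx(g, bw):
        return bw * np.sqrt(np.pi / 2.0) * np.exp(-np.pi**2 * g**2 * bw**2 / 2.0)

    E1 = Et(zeta[:, None] - fm0s[None, :], taus[None, :])  # (nz, nF)
    E2 = Et(zeta[:, None] + fm0s[None, :], taus[None, :])
    G1 = Gx(gamma[:, None] - om0s[None, :], bws[None, :])  # (ng, nO), real
    G2 = Gx(gamma[:, None] + om0s[None, :], bws[None, :])
    ph = grid.phase
    cross_t = 2.0 * np.real(np.exp(2j * ph) * E1 * np.conj(E2))
    term = (np.abs(E1) ** 2).T @ P @ (G1**2)
    term += (np.abs(E2) ** 2).T @ P @ (G2**2)
    term += cross_t.T @ P @ (G1 * G2)
    return 0.25 * amp**2 * term


def midbrain_mps(obj, grid: STRFGrid | None = None, route: str = "modulation_domain") -> ModulationPowerSpectrum:
    """Midbrain MPS: mean output power of every grid filter.

    ``route="modulation_domain"`` takes a cochlear
    :class:`ModulationPowerSpectrum` and integrates ``|MTF|**2`` against it;
    ``route="time_domain"`` takes a cochleogram, convolves every kernel and
    averages the squared output.  Both estimate the filter-output mean square,
    so on stationary inputs they agree up to windowing/edge effects.  Axes of
    the result are the (log-spaced) ``fm0`` and ``Omega0`` grids; the power
    array is indexed ``[fm0, omega0]``.
    """
    if grid is None:
        grid = default_strf_grid()
    if route == "modulation_domain":
        if not isinstance(obj, ModulationPowerSpectrum):
            raise TypeError("modulation_domain route requires a cochlear MPS")
        if obj.omega_unit != "cyc/oct":
            raise ValueError(
                f"cochlear MPS must have omega in cyc/oct, got {obj.omega_unit}"
            )
        power = _eq19_grid_power(obj, grid)
        n_seg = obj.n_segments
    elif route == "time_domain":
        vals = np.asarray(obj.values, dtype=np.float64)
        mean_removed = vals - vals.mean()
        field_f = np.fft.rfft2(mean_removed)
        nt, nx = mean_removed.shape
        dx = float(np.diff(obj.channel_positions).mean())
        power = np.empty((len(grid.fm0_values), len(grid.omega0_values)))
        for i, f in enumerate(grid.fm0_values):
            for j, o in enumerate(grid.omega0_values):
                spec = make_strf(f, o, grid.phase)
                kern, t, x = strf_kernel(spec, obj.frame_rate, dx)
                if kern.shape[0] > nt or kern.shape[1] > nx:
                    raise ValueError("STRF kernel larger than the cochleogram")
                # circular convolution: the discrete-exact Parseval partner of
                # integrating |MTF|^2 against the MPS
                kern_f = np.fft.rfft2(kern, s=(nt, nx))
                out = np.fft.irfft2(field_f * kern_f, s=(nt, nx))
                power[i, j] = np.mean(out**2)
        n_seg = 1
    else:
        raise ValueError(f"unknown route {route!r}")
    return ModulationPowerSpectrum(
        power=power,
        fm_axis=np.asarray(grid.fm0_values, dtype=float),
        omega_axis=np.asarray(grid.omega0_values, dtype=float),
        omega_unit="cyc/oct",
        source="midbrain",
        n_segments=n_seg,
        dc_removed=True,
    )
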