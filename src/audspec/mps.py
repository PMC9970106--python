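"""Modulation power spectrum (MPS) estimation by Welch-averaged 2D transforms.

A spectrogram-like representation ``S(t, x)`` (Fourier spectrogram with ``x``
in kHz, or cochleogram with ``x`` in octaves) is partitioned into adjacent
non-overlapping time segments; each segment is windowed by a separable 2D
Kaiser window (temporal extent = segment duration, spectral extent = the full
channel range), 2D Fourier transformed, magnitude-squared, and averaged.
The result is power density over temporal modulation frequency ``f_m``
(signed, Hz) and spectral modulation frequency ``Omega`` (non-negative,
cycles/kHz or cycles/octave depending on the source; the real-input Hermitian
symmetry ``P(-f_m, -Omega) = P(f_m, Omega)`` is folded onto ``Omega >= 0``
with the power of the mirrored half included).

Densities are normalized so that summing ``power * d_fm * d_omega`` over all
bins recovers the windowed mean square of the input, which makes the
modulation-domain route of the midbrain stage an exact Parseval partner of
the time-domain route.

The treatment of the segment mean (the DC bin and its window skirt) is an
explicit toggle: ``remove_segment_mean=True`` (the default used by the
entropy pipeline) subtracts each segment's scalar mean before transforming,
so the estimate describes structured modulations rather than static offset
power.  Equations operating on ``S`` directly correspond to
``remove_segment_mean=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import rfft2

__all__ = [
    "ModulationPowerSpectrum",
    "ModulationRange",
    "welch_mps",
    "power_contour",
    "mps_marginals",
    "restrict_mps",
    "mps_to_dataframe",
]

_OMEGA_UNIT = {"kHz": "cyc/kHz", "oct": "cyc/oct"}


@dataclass
class ModulationPowerSpectrum:
    """Power density over (f_m, Omega) with explicit axes and unit tags."""

    power: np.ndarray  # (n_fm, n_omega), >= 0
    fm_axis: np.ndarray  # signed Hz, ascending
    omega_axis: np.ndarray  # >= 0, cyc/kHz or cyc/oct
    omega_unit: str
    source: str  # fourier | cochlear | midbrain
    n_segments: int
    dc_removed: bool = False

    @property
    def d_fm(self) -> float:
        return float(self.fm_axis[1] - self.fm_axis[0])

    @property
    def d_omega(self) -> float:
        return float(self.omega_axis[1] - self.omega_axis[0])

    def total_power(self) -> float:
        """Integrated power (mean-square of the windowed input for Welch MPS)."""
        return float(self.power.sum() * self.d_fm * self.d_omega)


@dataclass(frozen=True)
class ModulationRange:
    """Axis extents of a power contour, used to bound entropy integration."""

    fm_max: float
    omega_max: float
    contour_fraction: float

    def __post_init__(self) -> None:
        if not (self.fm_max > 0 and self.omega_max > 0):
            raise ValueError("contour extents must be positive")


def welch_mps(
    rep,
    segment_dur: float = 1.5,
    kaiser_beta: float = 3.4,
    remove_segment_mean: bool = True,
    window: str = "kaiser",
) -> ModulationPowerSpectrum:
    """Welch-averaged MPS of a :class:`Spectrogram` or :class:`Cochleogram`.

    Parameters
    ----------
    rep
        Object with ``values`` (frames x channels), ``frame_rate``,
        ``channel_positions`` (uniform) and ``source``/``channel_unit`` tags.
    segment_dur : float
        Segment length in seconds (non-overlapping partition; default 1.5 s).
    kaiser_beta : float
        Shape of the separable 2D Kaiser window (``window="boxcar"`` disables
        windowing, useful for Parseval checks).
    remove_segment_mean : bool
        Subtract each segment's scalar mean before transforming (see module
        docstring).
    """
    vals = rep.values
    n_t = int(round(segment_dur * rep.frame_rate))
    if n_t < 2:
        raise ValueError("segment duration too short for the frame rate")
    n_seg = vals.shape[0] // n_t
    if n_seg < 1:
        raise ValueError(
            f"input ({vals.shape[0] / rep.frame_rate:.2f} s) shorter than one "
            f"{segment_dur:.2f} s segment"
        )
    n_x = vals.shape[1]
    pos = np.asarray(rep.channel_positions)
    dx = float(pos[1] - pos[0])
    dt = 1.0 / rep.frame_rate
    if window == "kaiser":
        w2d = np.outer(np.kaiser(n_t, kaiser_beta), np.kaiser(n_x, kaiser_beta))
    elif window == "boxcar":
        w2d = np.ones((n_t, n_x))
    else:
        raise ValueError(f"unknown window {window!r}")
    w2d = w2d.astype(np.float32)
    wsum2 = float(np.sum(w2d.astype(np.float64) ** 2))

    acc = np.zeros((n_t, n_x // 2 + 1), dtype=np.float64)
    for s in range(n_seg):
        seg = np.asarray(vals[s * n_t : (s + 1) * n_t], dtype=np.float32)
        if remove_segment_mean:
            seg = seg - seg.mean(dtype=np.float64)
        spec2 = rfft2(seg * w2d)
        acc += np.abs(spec2).astype(np.float64) ** 2
    acc /= n_seg
    # density normalization: sum(P * d_fm * d_omega) == windowed mean square
    acc *= dt * dx / wsum2
    # fold the Omega < 0 half-plane (Hermitian partner) onto Omega > 0
    acc[:, 1:] *= 2.0
    if n_x % 2 == 0:
        acc[:, -1] /= 2.0
    power = np.fft.fftshift(acc, axes=0)
    fm_axis = np.fft.fftshift(np.fft.fftfreq(n_t, dt))
    omega_axis = np.arange(n_x // 2 + 1) / (n_x * dx)
    return ModulationPowerSpectrum(
        power=power,
        fm_axis=fm_axis,
        omega_axis=omega_axis,
        omega_unit=_OMEGA_UNIT[rep.channel_unit],
        source=rep.source,
        n_segments=n_seg,
        dc_removed=remove_segment_mean,
    )


def mask_static_band(mps: ModulationPowerSpectrum, n_rows: int = 2) -> ModulationPowerSpectrum:
    """Zero the temporal-modulation rows ``|f_m| <= n_rows * d_fm``.

    Modulations slower than the segment-length resolution (the DC bin and its
    window mainlobe) measure a segment's static spectral profile rather than
    resolvable modulation; they are excluded before contour and entropy
    computation so static power does not dominate the normalization.
    """
    power = mps.power.copy()
    power[np.abs(mps.fm_axis) <= (n_rows + 0.5) * mps.d_fm] = 0.0
    return ModulationPowerSpectrum(
        power=power,
        fm_axis=mps.fm_axis,
        omega_axis=mps.omega_axis,
        omega_unit=mps.omega_unit,
        source=mps.source,
        n_segments=mps.n_segments,
        dc_removed=True,
    )


def power_contour(mps: ModulationPowerSpectrum, fraction: float = 0.9) -> ModulationRange:
    """Axis extents of the smallest-threshold super-level set holding ``fraction`` of power.

    The threshold is the smallest power value whose super-level set contains
    at least ``fraction`` of the total; the returned range is the bounding box
    (max ``|f_m|``, max ``Omega``) of that set.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    p = mps.power.ravel()
    total = p.sum()
    if total <= 0:
        raise ValueError("MPS has no power")
    order = np.argsort(p)[::-1]
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, fraction * total))
    thresh = p[order[min(k, p.size - 1)]]
    mask = mps.power >= thresh
    fm_mask = mask.any(axis=1)
    om_mask = mask.any(axis=0)
    return ModulationRange(
        fm_max=float(np.max(np.abs(mps.fm_axis[fm_mask]))),
        omega_max=float(np.max(mps.omega_axis[om_mask])),
        contour_fraction=fraction,
    )


def restrict_mps(
    mps: ModulationPowerSpectrum, mrange: ModulationRange
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sub-grid of ``mps.power`` with ``|f_m| <= fm_max`` and ``Omega <= omega_max``.

    Returns ``(power, fm, omega)``; raises if the restriction is empty.
    """
    fm_sel = np.abs(mps.fm_axis) <= mrange.fm_max + 1e-12
    om_sel = mps.omega_axis <= mrange.omega_max + 1e-12
    if not fm_sel.any() or not om_sel.any():
        raise ValueError("modulation range does not overlap the MPS axes")
    return mps.power[np.ix_(fm_sel, om_sel)], mps.fm_axis[fm_sel], mps.omega_axis[om_sel]


def mps_marginals(mps: ModulationPowerSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sum temporal (over f_m) and spectral (over Omega) marginals."""
    temporal = mps.power.sum(axis=1)
    spectral = mps.power.sum(axis=0)
    return temporal / temporal.sum(), spectral / spectral.sum()


def mps_to_dataframe(mps: ModulationPowerSpectrum) -> pd.DataFrame:
    """Long-format export (one row per bin) for plotting or delimited-text dumps."""
    fm, om = np.meshgrid(mps.fm_axis, mps.omega_axis, indexing="ij")
    return pd.DataFrame(
        {
            "fm_hz": fm.ravel(),
            f"omega_{mps.omega_unit.replace('/', '_per_')}": om.ravel(),
            "power": mps.power.ravel(),
        }
    )
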