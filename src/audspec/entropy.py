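"""Spectral and modulation entropy, spectrum-slope fitting and standardization.

Entropy here measures how evenly a sound's power is spread across the
channels of a filterbank: the per-channel power distribution is normalized to
unit sum, its Shannon entropy is computed, and the result is divided by the
capacity ``log2(N)`` of the ``N``-channel decomposition.  A value of 1 means
the representation is perfectly whitened (every filter carries equal power);
concentrated power gives values near 0.  The same construction applied to
the two-dimensional modulation power spectrum over a bounded modulation
range yields the modulation entropy, with marginal (temporal-only and
spectral-only) variants.

Spectrum slopes are ordinary least-squares fits of the dB power spectrum
against the representation's native frequency axis (kHz for the Fourier
bank, octaves above 100 Hz for the cochlear bank); ensembles of slopes are
standardized by their sample standard deviation so filterbanks with
different axis units can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mps import ModulationPowerSpectrum, ModulationRange, restrict_mps

__all__ = [
    "SpectrumEntropyResult",
    "ModulationEntropyResult",
    "SlopeFit",
    "power_spectrum",
    "spectral_entropy",
    "modulation_entropy",
    "fit_spectrum_slope",
    "standardize_slopes",
]


def power_spectrum(rep, trim_edges_s: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel time-averaged power of a spectrogram-like representation.

    Returns ``(power, native_axis)`` where the axis is the representation's
    ``channel_positions`` (kHz or octaves).  ``trim_edges_s`` drops that many
    seconds from each end before averaging (filter edge transients).
    """
    vals = rep.values
    if vals.size == 0:
        raise ValueError("empty representation")
    k = int(round(trim_edges_s * rep.frame_rate))
    if 2 * k >= vals.shape[0]:
        k = 0
    vals = vals[k : vals.shape[0] - k if k else vals.shape[0]]
    power = np.mean(np.asarray(vals, dtype=np.float64) ** 2, axis=0)
    return power, np.asarray(rep.channel_positions, dtype=float)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


@dataclass(frozen=True)
class SpectrumEntropyResult:
    """Normalized spectral entropy ``H / log2(N)`` with its ingredients."""

    entropy: float
    raw_entropy: float
    n_channels: int


def spectral_entropy(power: np.ndarray) -> SpectrumEntropyResult:
    """Normalized Shannon entropy of a per-channel power distribution.

    Power is unit-sum normalized and treated as a probability distribution;
    ``0 * log 0`` is taken as 0.  Invariant to global power scaling.
    """
    power = np.asarray(power, dtype=np.float64)
    if power.size < 2:
        raise ValueError("need at least two channels")
    if np.any(power < 0) or power.sum() <= 0:
        raise ValueError("power must be non-negative with positive total")
    p = power / power.sum()
    h = _entropy_bits(p)
    return SpectrumEntropyResult(
        entropy=h / np.log2(power.size), raw_entropy=h, n_channels=power.size
    )


@dataclass(frozen=True)
class ModulationEntropyResult:
    """Total and marginal modulation entropies over a restricted range."""

    entropy: float
    temporal_marginal_entropy: float
    spectral_marginal_entropy: float
    n_temporal: int
    n_spectral: int
    range: ModulationRange


def modulation_entropy(
    mps: ModulationPowerSpectrum, mrange: ModulationRange
) -> ModulationEntropyResult:
    """Normalized entropy of the MPS restricted to ``|f_m| <= fm_max``, ``Omega <= omega_max``.

    The restricted bin grid (M temporal x L spectral bins) is unit-sum
    normalized; the total entropy is divided by ``log2(L*M)`` and the
    marginals by ``log2(M)`` / ``log2(L)``.  The MPS should be estimated with
    the segment mean removed so the DC bin does not dominate the
    normalization (see :func:`audspec.mps.welch_mps`).
    """
    power, fm, om = restrict_mps(mps, mrange)
    total = power.sum()
    if total <= 0:
        raise ValueError("restricted MPS has no power")
    p = power / total
    n_m, n_l = p.shape
    h_total = _entropy_bits(p.ravel()) / np.log2(n_m * n_l)
    pt = p.sum(axis=1)
    ps = p.sum(axis=0)
    h_t = _entropy_bits(pt) / np.log2(n_m) if n_m > 1 else 1.0
    h_s = _entropy_bits(ps) / np.log2(n_l) if n_l > 1 else 1.0
    return ModulationEntropyResult(
        entropy=h_total,
        temporal_marginal_entropy=h_t,
        spectral_marginal_entropy=h_s,
        n_temporal=n_m,
        n_spectral=n_l,
        range=mrange,
    )


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of the dB power spectrum against the native frequency axis."""

    slope: float  # dB per kHz (fourier) or dB per octave (cochlear)
    intercept: float
    axis_unit: str
    r_value: float


def fit_spectrum_slope(power: np.ndarray, axis: np.ndarray, axis_unit: str = "kHz") -> SlopeFit:
    """Least-squares line through ``10 log10(power)`` vs the native axis."""
    power = np.asarray(power, dtype=np.float64)
    axis = np.asarray(axis, dtype=np.float64)
    good = power > 0
    if good.sum() < 2:
        raise ValueError("need at least two channels with positive power")
    res = stats.linregress(axis[good], 10.0 * np.log10(power[good]))
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        axis_unit=axis_unit,
        r_value=float(res.rvalue),
    )


def standardize_slopes(slopes) -> np.ndarray:
    """Divide an ensemble of slopes by its sample (n-1) standard deviation."""
    arr = np.asarray(
        [s.slope if isinstance(s, SlopeFit) else float(s) for s in slopes], dtype=float
    )
    if arr.size < 2:
        raise ValueError("need at least two slopes")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("slope ensemble has zero standard deviation")
    return arr / sd
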