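"""Bandwidth-scaling gain predictions: how filter bandwidths whiten outputs.

A filter that integrates sound power over a bandwidth ``B(f)`` boosts its
output by ``10 log10 B(f)`` relative to a unit-bandwidth filter.  Because
cochlear (ERB) bandwidths grow with characteristic frequency, this gain
rises with frequency and counteracts the falling power spectra of natural
sounds; the same argument in the modulation domain (constant-Q STRFs with
bandwidths ``|fm0|`` and ``Omega0``) predicts the flattening of the midbrain
modulation power spectrum.  A Greenwood frequency-position map with uniform
hair-cell density provides an additional, anatomical gain: high-frequency
octaves occupy more of the cochlear spiral and therefore recruit more hair
cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cochlear import erb_bandwidth
from .midbrain import STRFGrid
from .mps import ModulationPowerSpectrum

__all__ = [
    "GainCurve",
    "CochlearMapSpec",
    "bandwidth_gain",
    "predict_cochlear_spectrum",
    "predict_midbrain_mps",
    "greenwood_position",
    "hair_cell_count",
    "hair_cell_gain_db",
]


@dataclass(frozen=True)
class GainCurve:
    """Gain in dB (defined up to an additive constant) along an axis."""

    axis: np.ndarray
    gain_db: np.ndarray


def bandwidth_gain(cfs) -> GainCurve:
    """ERB bandwidth gain ``10 log10 b(f)``, referenced to the first CF."""
    cfs = np.asarray(cfs, dtype=float)
    if np.any(cfs <= 0):
        raise ValueError("characteristic frequencies must be positive")
    g = 10.0 * np.log10(erb_bandwidth(cfs))
    return GainCurve(axis=cfs, gain_db=g - g[0])


def _align_offset(pred_db: np.ndarray, target_db: np.ndarray) -> np.ndarray:
    """Least-squares additive offset making ``pred`` comparable to ``target``."""
    return pred_db + float(np.mean(target_db - pred_db))


def predict_cochlear_spectrum(
    fourier_db: np.ndarray,
    fourier_freqs_hz: np.ndarray,
    cfs_hz: np.ndarray,
    measured_cochlear_db: np.ndarray | None = None,
) -> np.ndarray:
    """Predict the cochlear power spectrum as Fourier spectrum + bandwidth gain.

    The Fourier dB spectrum is interpolated at the cochlear CFs (linear in
    log-frequency), the ERB gain is added, and (if a measured cochlear
    spectrum is given) a least-squares additive offset aligns the two, since
    the gain is defined only up to a constant.
    """
    cfs_hz = np.asarray(cfs_hz, dtype=float)
    fourier_freqs_hz = np.asarray(fourier_freqs_hz, dtype=float)
    if cfs_hz.min() < fourier_freqs_hz.min() - 1e-9 or cfs_hz.max() > fourier_freqs_hz.max() + 1e-9:
        raise ValueError("cochlear CFs fall outside the Fourier spectrum range")
    interp_db = np.interp(np.log2(cfs_hz), np.log2(fourier_freqs_hz), np.asarray(fourier_db, float))
    pred = interp_db + bandwidth_gain(cfs_hz).gain_db
    if measured_cochlear_db is not None:
        pred = _align_offset(pred, np.asarray(measured_cochlear_db, dtype=float))
    return pred


def predict_midbrain_mps(
    mps_c: ModulationPowerSpectrum,
    grid: STRFGrid,
    measured_db: np.ndarray | None = None,
) -> np.ndarray:
    """Predict the midbrain MPS (dB) as cochlear MPS + modulation-bandwidth gain.

    Per grid filter the gain is ``10 log10(|fm0| * Omega0)`` (the constant-Q
    bandwidth product); the cochlear MPS is bilinearly interpolated in dB at
    the filter centers.  Returns an array indexed ``[fm0, omega0]``.
    """
    if mps_c.omega_unit != "cyc/oct":
        raise ValueError("prediction requires a cochlear-source MPS (cyc/oct)")
    fm0s = np.asarray(grid.fm0_values, dtype=float)
    om0s = np.asarray(grid.omega0_values, dtype=float)
    logp = 10.0 * np.log10(np.maximum(mps_c.power, np.finfo(float).tiny))
    pred = np.empty((fm0s.size, om0s.size))
    for j, om in enumerate(om0s):
        col_idx = np.interp(om, mps_c.omega_axis, np.arange(mps_c.omega_axis.size))
        j0 = int(np.floor(col_idx))
        j1 = min(j0 + 1, mps_c.omega_axis.size - 1)
        wj = col_idx - j0
        col = (1 - wj) * logp[:, j0] + wj * logp[:, j1]
        pred[:, j] = np.interp(fm0s, mps_c.fm_axis, col)
    pred += 10.0 * np.log10(np.abs(fm0s))[:, None]
    pred += 10.0 * np.log10(om0s)[None, :]
    if measured_db is not None:
        pred = _align_offset(pred, np.asarray(measured_db, dtype=float))
    return pred


@dataclass(frozen=True)
class CochlearMapSpec:
    """Greenwood frequency-position map ``f(x) = A (10**(a x) - k)`` for the human cochlea."""

    A: float = 165.4  # Hz
    a: float = 0.06  # per mm
    k: float = 0.88
    length: float = 35.0  # mm
    hair_cell_density: float = 100.0  # per mm

    def frequency_at(self, x_mm: float) -> float:
        return self.A * (10.0 ** (self.a * x_mm) - self.k)


def greenwood_position(f, spec: CochlearMapSpec = CochlearMapSpec()):
    """Distance from the apex (mm) at which the map places frequency ``f`` Hz."""
    f = np.asarray(f, dtype=float)
    f_lo = spec.frequency_at(0.0)
    f_hi = spec.frequency_at(spec.length)
    if np.any(f <= f_lo) or np.any(f > f_hi):
        raise ValueError(f"frequency outside the map range ({f_lo:.1f}, {f_hi:.1f}] Hz")
    return np.log10(f / spec.A + spec.k) / spec.a


def hair_cell_count(f_lo: float, f_hi: float, spec: CochlearMapSpec = CochlearMapSpec()) -> int:
    """Hair cells between two frequencies: density times spanned length, rounded."""
    if not f_lo < f_hi:
        raise ValueError("require f_lo < f_hi")
    span = greenwood_position(f_hi, spec) - greenwood_position(f_lo, spec)
    return int(round(spec.hair_cell_density * float(span)))


def hair_cell_gain_db(
    band_lo: tuple[float, float],
    band_hi: tuple[float, float],
    spec: CochlearMapSpec = CochlearMapSpec(),
) -> float:
    """Output-power gain ``10 log10(count_hi / count_lo)`` between two bands."""
    c_lo = hair_cell_count(*band_lo, spec)
    c_hi = hair_cell_count(*band_hi, spec)
    if c_lo == 0 or c_hi == 0:
        raise ValueError("band contains no hair cells")
    return 10.0 * np.log10(c_hi / c_lo)
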