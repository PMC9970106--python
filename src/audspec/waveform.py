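"""Mono pressure waveform container shared by every decomposition stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FS = 44100.0


@dataclass
class Waveform:
    """A sampled mono pressure signal.

    Parameters
    ----------
    samples : ndarray
        Pressure samples in arbitrary units.
    fs : float
        Sampling rate in Hz.
    meta : dict
        Free-form provenance (category label, generator seed, parameters).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("waveform samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


def peak_normalize(samples: np.ndarray, peak: float = 0.99) -> np.ndarray:
    """Scale ``samples`` so that ``max |s|`` equals ``peak`` (no-op for silence)."""
    m = np.max(np.abs(samples)) if samples.size else 0.0
    if m == 0:
        return samples
    return samples * (peak / m)
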