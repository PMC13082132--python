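"""In-memory containers for image stacks and single-spot time traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict

import numpy as np

__all__ = ["HyperspectralStack", "TimeLapseStack", "IntensityTrace"]


@dataclass
class HyperspectralStack:
    """Image cube indexed (y, x, wavenumber) with a calibrated cm^-1 axis."""

    data: np.ndarray                 # (ny, nx, n_bands), float32
    wavenumbers: np.ndarray          # cm^-1, strictly increasing
    pixel_size: float                # nm
    metadata: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("hyperspectral data must be 3D (y, x, band)")
        if self.wavenumbers.ndim != 1 or len(self.wavenumbers) != self.data.shape[2]:
            raise ValueError("wavenumber axis length must match spectral dimension")
        if len(self.wavenumbers) > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self):
        return self.data.shape

    def band(self, index: int) -> np.ndarray:
        return self.data[:, :, index]

    def band_nearest(self, wavenumber: float) -> int:
        """Index of the band closest to the requested wavenumber."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))


@dataclass
class TimeLapseStack:
    """Image cube indexed (y, x, t) sampled at a fixed frame interval."""

    data: np.ndarray                 # (ny, nx, n_frames), float32
    frame_interval: float            # s
    pixel_size: float                # nm
    metadata: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("time-lapse data must be 3D (y, x, t)")
        if self.data.shape[2] < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self):
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) * self.frame_interval

    def frame(self, index: int) -> np.ndarray:
        return self.data[:, :, index]


@dataclass
class IntensityTrace:
    """Per-frame intensity of one spot on a uniform time grid."""

    times: np.ndarray                # s
    intensities: np.ndarray          # detector units
    frame_interval: float            # s
    spot_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if len(self.times) < 2:
            raise ValueError("trace must have length >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.times)
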