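"""In-memory containers: 1D spectra, off-resonance stacks and correlation maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Spectrum1D", "OffResonanceDataset", "CorrelationMap"]


@dataclass
class Spectrum1D:
    """A processed 1D 1H spectrum with calibrated axes.

    ``data`` is complex (absorption in the real part when properly phased);
    ``axis_ppm``/``axis_hz`` are ascending and share its length.
    """

    data: np.ndarray
    axis_ppm: np.ndarray
    axis_hz: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.axis_ppm = np.asarray(self.axis_ppm, dtype=float)
        self.axis_hz = np.asarray(self.axis_hz, dtype=float)
        if not (len(self.data) == len(self.axis_ppm) == len(self.axis_hz)):
            raise ValueError("spectrum data and axes must share one length")


@dataclass
class OffResonanceDataset:
    """A (difference) off-resonance stack: the network input.

    ``data`` has shape ``(n_h, n_offsets, n_b1)`` and holds the real part of
    the processed 1H spectra; ``h_axis_ppm`` ascends, ``offsets_ppm`` is the
    13C decoupler-position axis, ``b1_list`` is ordered high -> low.
    ``scale`` is the pre-normalization global maximum (|value|), kept so that
    quantitative comparisons between stacks remain possible after each has
    been scaled to a global maximum of 1.
    """

    data: np.ndarray
    h_axis_ppm: np.ndarray
    offsets_ppm: np.ndarray
    b1_list: tuple
    normalized: bool = False
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("off-resonance data must be (n_h, n_offsets, n_b1)")
        self.h_axis_ppm = np.asarray(self.h_axis_ppm, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.b1_list = tuple(float(b) for b in self.b1_list)
        n_h, n_off, n_b1 = self.data.shape
        if len(self.h_axis_ppm) != n_h or len(self.offsets_ppm) != n_off:
            raise ValueError("axis lengths inconsistent with data shape")
        if len(self.b1_list) != n_b1:
            raise ValueError("b1_list length inconsistent with data shape")
        if self.normalized:
            m = float(np.max(np.abs(self.data)))
            if not np.isclose(m, 1.0, rtol=1e-6):
                raise ValueError(f"normalized flag set but global max is {m}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def normalize(self) -> "OffResonanceDataset":
        """Return a copy scaled so the global |max| is 1 (scale recorded)."""
        m = float(np.max(np.abs(self.data)))
        if m == 0.0:
            raise ValueError("cannot normalize an all-zero stack")
        return OffResonanceDataset(
            data=self.data / m,
            h_axis_ppm=self.h_axis_ppm,
            offsets_ppm=self.offsets_ppm,
            b1_list=self.b1_list,
            normalized=True,
            scale=self.scale * m,
            meta=dict(self.meta),
        )


@dataclass
class CorrelationMap:
    """A 2D 1H-13C correlation map, optionally with a point-wise sigma map."""

    data: np.ndarray
    h_axis_ppm: np.ndarray
    c_axis_ppm: np.ndarray
    sigma: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("correlation map must be 2D (n_h, n_c)")
        self.h_axis_ppm = np.asarray(self.h_axis_ppm, dtype=float)
        self.c_axis_ppm = np.asarray(self.c_axis_ppm, dtype=float)
        n_h, n_c = self.data.shape
        if len(self.h_axis_ppm) != n_h or len(self.c_axis_ppm) != n_c:
            raise ValueError("axis lengths inconsistent with map shape")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma)
            if self.sigma.shape != self.data.shape:
                raise ValueError("sigma map must match the map shape")

    @property
    def shape(self) -> tuple:
        return self.data.shape
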