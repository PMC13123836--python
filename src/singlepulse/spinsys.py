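"""Spin systems and acquisition schemes for single-pulse off-resonance decoupling.

A :class:`SpinSystem` is one isolated 1H-13C pair (a 13CHD2 methyl probe in a
deuterated background): chemical shifts, the one-bond scalar coupling, and the
three transverse relaxation rates that enter the evolution of the eight
product-operator coherences.  The single-quantum 13C rate does not appear
anywhere in the dynamics of the detected 1H signal and is deliberately not a
field of this type.

An :class:`AcquisitionScheme` describes how the off-resonance experiment is
recorded: static field (through the 1H base frequency), CW decoupling field
strengths, the grid of 13C decoupler offsets, sweep width, acquisition time
and zero-fill size.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

#: gamma(13C)/gamma(1H); converts ppm <-> Hz between the two channels.
GAMMA_RATIO_CH = 0.25144953

__all__ = ["SpinSystem", "AcquisitionScheme", "GAMMA_RATIO_CH"]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass
class SpinSystem:
    """One isolated 1H-13C spin pair.

    Parameters
    ----------
    wh, wc:
        1H and 13C chemical shifts in ppm.
    j_hc:
        One-bond scalar coupling 1J(HC) in Hz (~125 Hz for methyls).
    r2_h, r2_mq, r2_aph:
        Transverse relaxation rates (s^-1) of the 1H single-quantum
        coherences, the four multiple-quantum terms, and the two 1H-13Cz
        antiphase terms, respectively.
    i0:
        Starting magnetization (arbitrary positive units); sets the peak
        intensity in the target correlation map.
    """

    wh: float
    wc: float
    j_hc: float = 125.0
    r2_h: float = 25.0
    r2_mq: float = 25.0
    r2_aph: float = 25.0
    i0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("wh", "wc", "j_hc", "r2_h", "r2_mq", "r2_aph", "i0"):
            setattr(self, name, _require_finite(name, getattr(self, name)))
        if self.j_hc <= 0:
            raise ValueError(f"j_hc must be > 0, got {self.j_hc}")
        for name in ("r2_h", "r2_mq", "r2_aph"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.i0 <= 0:
            raise ValueError(f"i0 must be > 0, got {self.i0}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        return cls(**d)


def _default_offsets() -> np.ndarray:
    # 200 decoupler positions spanning 30 ppm over the methyl 13C region.
    return np.linspace(-2.0, 28.0, 200)


@dataclass
class AcquisitionScheme:
    """Acquisition scheme for a single-pulse off-resonance series.

    ``f_h`` is the 1H base frequency in MHz (700 MHz <-> 16.4 T).  The 13C
    base frequency is ``f_h * gamma_ratio`` (~176 MHz).  Times are in
    seconds, shifts and sweep widths in ppm, B1 fields in Hz.

    ``reference_mode`` selects the reference ("coupled") spectrum that is
    subtracted from every off-resonance spectrum: ``"b1_zero"`` computes it
    with the decoupler off, ``"far_offset"`` with the decoupler at
    ``reference_offset_ppm`` (the experimental choice, -50 ppm by default).
    """

    f_h: float = 700.0
    gamma_ratio: float = GAMMA_RATIO_CH
    carrier_h: float = 0.5
    sw_h: float = 5.0
    t_max: float = 0.064
    n_zf: int = 512
    b1_list: tuple = (220.0, 110.0)
    offsets_c: np.ndarray = field(default_factory=_default_offsets)
    reference_mode: str = "b1_zero"
    reference_offset_ppm: float = -50.0

    def __post_init__(self) -> None:
        for name in ("f_h", "carrier_h", "sw_h", "t_max"):
            _require_finite(name, getattr(self, name))
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.f_h <= 0 or self.sw_h <= 0:
            raise ValueError("f_h and sw_h must be > 0")
        self.b1_list = tuple(float(b) for b in self.b1_list)
        if any(b <= 0 for b in self.b1_list):
            raise ValueError("all B1 values must be > 0")
        self.offsets_c = np.asarray(self.offsets_c, dtype=float)
        d = np.diff(self.offsets_c)
        if self.offsets_c.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("offsets_c must be strictly monotone")
        self.n_zf = int(self.n_zf)
        if self.n_zf < self.n_points:
            raise ValueError(
                f"n_zf={self.n_zf} smaller than the {self.n_points} acquired points"
            )
        if self.reference_mode not in ("b1_zero", "far_offset"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")

    # ---- derived quantities -------------------------------------------------

    @property
    def f_c(self) -> float:
        """13C base frequency, MHz."""
        return self.f_h * self.gamma_ratio

    @property
    def sw_h_hz(self) -> float:
        return self.sw_h * self.f_h

    @property
    def dt(self) -> float:
        """Dwell time: 1/(1H sweep width in Hz)."""
        return 1.0 / self.sw_h_hz

    @property
    def n_points(self) -> int:
        """Acquired complex points: times 0 ... t_max in steps of the dwell."""
        return int(math.floor(self.t_max * self.sw_h_hz)) + 1

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dt

    def h_axis_hz(self, n: int | None = None) -> np.ndarray:
        """Ascending 1H frequency axis (Hz, relative to the carrier)."""
        n = self.n_zf if n is None else int(n)
        return np.fft.fftshift(np.fft.fftfreq(n, d=self.dt))

    def h_axis_ppm(self, n: int | None = None) -> np.ndarray:
        """Ascending 1H chemical-shift axis, ppm."""
        return self.carrier_h + self.h_axis_hz(n) / self.f_h

    def omega_h(self, wh_ppm: float) -> float:
        """1H offset from the carrier, Hz."""
        return (wh_ppm - self.carrier_h) * self.f_h

    def omega_c(self, wc_ppm: float, nu_rf_ppm: float) -> float:
        """13C offset from the decoupler position, Hz."""
        return (wc_ppm - nu_rf_ppm) * self.f_c

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["offsets_c"] = self.offsets_c.tolist()
        d["b1_list"] = list(self.b1_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionScheme":
        d = dict(d)
        if "offsets_c" in d:
            d["offsets_c"] = np.asarray(d["offsets_c"], dtype=float)
        if "b1_list" in d:
            d["b1_list"] = tuple(d["b1_list"])
        return cls(**d)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---- config-file round trips ------------------------------------------------


def load_spins(path) -> list[SpinSystem]:
    """Read a spin-system list from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw["spins"]
    return [SpinSystem.from_dict(d) for d in raw]


def save_spins(spins: Sequence[SpinSystem], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"spins": [s.to_dict() for s in spins]}, fh, sort_keys=False)


def load_scheme(path) -> AcquisitionScheme:
    with open(path) as fh:
        return AcquisitionScheme.from_dict(yaml.safe_load(fh))


def save_scheme(scheme: AcquisitionScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh, sort_keys=False)
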