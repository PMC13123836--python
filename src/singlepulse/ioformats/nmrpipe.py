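"""Minimal NMRPipe file codec (float32 single-file 1D / 2D).

Implements the subset of the NMRPipe header needed to exchange processed
1D spectra, pseudo-2D off-resonance series and 2D correlation maps:
the 512-word float32 header with the standard parameter locations
(sizes, sweep widths, observe frequencies, carriers, FT flags), followed
by the data plane.  Axis calibration follows the NMRPipe convention that
ORIG is the frequency of the last (most upfield) point of the spectrum.

Off-resonance series need metadata the NMRPipe header cannot carry
(decoupler offset list, B1); those travel in a JSON sidecar next to the
file (see :mod:`singlepulse.processing`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_pipe", "read_pipe"]

# fdatap.h word indices
FDMAGIC = 0
FDFLTFORMAT = 1
FDFLTORDER = 2
FDDIMCOUNT = 9
FDF2SW = 100
FDF2OBS = 119
FDF2CAR = 66
FDF2ORIG = 101
FDF2FTFLAG = 220
FDF2QUADFLAG = 56
FDF2CENTER = 79
FDSIZE = 99
FDSPECNUM = 219
FDQUADFLAG = 106
FDTRANSPOSED = 221
FDF1SW = 229
FDF1OBS = 218
FDF1CAR = 67
FDF1ORIG = 249
FDF1FTFLAG = 222
FDF1QUADFLAG = 55
FDF1CENTER = 80
FDPIPEFLAG = 57

_FLTORDER = np.float32(2.345)


def _axis_words(prefix: str) -> dict:
    if prefix == "f2":
        return {"sw": FDF2SW, "obs": FDF2OBS, "car": FDF2CAR,
                "orig": FDF2ORIG, "ft": FDF2FTFLAG, "quad": FDF2QUADFLAG,
                "center": FDF2CENTER}
    return {"sw": FDF1SW, "obs": FDF1OBS, "car": FDF1CAR,
            "orig": FDF1ORIG, "ft": FDF1FTFLAG, "quad": FDF1QUADFLAG,
            "center": FDF1CENTER}


def _set_axis(hdr: np.ndarray, prefix: str, size: int, sw: float,
              obs: float, car_ppm: float, ft: bool) -> None:
    w = _axis_words(prefix)
    center = size // 2 + 1
    hdr[w["sw"]] = sw
    hdr[w["obs"]] = obs
    hdr[w["car"]] = car_ppm
    hdr[w["center"]] = center
    hdr[w["orig"]] = obs * car_ppm - sw * (size - center) / size
    hdr[w["ft"]] = 1.0 if ft else 0.0
    hdr[w["quad"]] = 1.0  # real data


def _axis_ppm(hdr: np.ndarray, prefix: str, size: int) -> np.ndarray:
    """Descending (downfield-first) ppm axis of a stored dimension."""
    w = _axis_words(prefix)
    sw, obs, orig = float(hdr[w["sw"]]), float(hdr[w["obs"]]), float(hdr[w["orig"]])
    hz = orig + (size - 1 - np.arange(size)) * sw / size
    return hz / obs


def write_pipe(
    path,
    data: np.ndarray,
    axes: list[dict],
) -> None:
    """Write a real float32 NMRPipe file.

    ``data`` is 1D (size,) or 2D (n_rows, size) with the direct dimension
    last.  ``axes`` lists one dict per dimension, direct dimension first:
    ``{"sw": Hz, "obs": MHz, "car": ppm, "ft": bool}``.  For pseudo-2D
    series the indirect axis may be a bare index axis (obs=1, sw=n_rows).
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim not in (1, 2):
        raise ValueError("only 1D and 2D NMRPipe data are supported")
    if len(axes) != data.ndim:
        raise ValueError("one axis dict per data dimension required")
    hdr = np.zeros(512, dtype=np.float32)
    hdr[FDMAGIC] = 0.0
    hdr[FDFLTORDER] = _FLTORDER
    hdr[FDDIMCOUNT] = float(data.ndim)
    hdr[FDQUADFLAG] = 1.0
    hdr[FDTRANSPOSED] = 0.0
    hdr[FDPIPEFLAG] = 0.0
    size = data.shape[-1]
    hdr[FDSIZE] = float(size)
    _set_axis(hdr, "f2", size, axes[0]["sw"], axes[0]["obs"],
              axes[0]["car"], axes[0].get("ft", True))
    if data.ndim == 2:
        hdr[FDSPECNUM] = float(data.shape[0])
        _set_axis(hdr, "f1", data.shape[0], axes[1]["sw"], axes[1]["obs"],
                  axes[1]["car"], axes[1].get("ft", True))
    else:
        hdr[FDSPECNUM] = 1.0
    with open(Path(path), "wb") as fh:
        fh.write(hdr.tobytes())
        fh.write(data.tobytes())


def read_pipe(path) -> tuple[np.ndarray, dict]:
    """Read a float32 NMRPipe file written by :func:`write_pipe`.

    Returns ``(data, info)`` where ``info`` holds per-axis calibration
    including the descending ppm axes (``axis_f2_ppm``, ``axis_f1_ppm``).
    """
    raw = Path(path).read_bytes()
    hdr = np.frombuffer(raw[: 512 * 4], dtype=np.float32).copy()
    if not np.isclose(hdr[FDFLTORDER], _FLTORDER, atol=1e-3):
        hdr_sw = hdr.byteswap()
        if np.isclose(hdr_sw[FDFLTORDER], _FLTORDER, atol=1e-3):
            hdr = hdr_sw
            data = np.frombuffer(raw[512 * 4:], dtype=">f4").astype(np.float32)
        else:
            raise ValueError(f"{path} is not an NMRPipe file (bad byte-order mark)")
    else:
        data = np.frombuffer(raw[512 * 4:], dtype="<f4").astype(np.float32)
    ndim = int(hdr[FDDIMCOUNT])
    size = int(hdr[FDSIZE])
    nrows = max(1, int(hdr[FDSPECNUM]))
    if ndim == 1:
        data = data[:size]
    else:
        data = data[: size * nrows].reshape(nrows, size)
    info = {
        "ndim": ndim,
        "sw_f2": float(hdr[FDF2SW]),
        "obs_f2": float(hdr[FDF2OBS]),
        "car_f2": float(hdr[FDF2CAR]),
        "axis_f2_ppm": _axis_ppm(hdr, "f2", size),
    }
    if ndim == 2:
        info.update(
            sw_f1=float(hdr[FDF1SW]),
            obs_f1=float(hdr[FDF1OBS]),
            car_f1=float(hdr[FDF1CAR]),
            axis_f1_ppm=_axis_ppm(hdr, "f1", nrows),
        )
    return data, info
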