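"""Minimal UCSF (Sparky) 2D spectrum codec.

UCSF files are big-endian: a 180-byte file header ("UCSF NMR", dimension
count, one real component, format version 2), one 128-byte axis header per
dimension (slowest axis first: nucleus name, point count, tile size,
spectrometer frequency in MHz, sweep width in Hz, center in ppm), then the
data as float32 tiles.  Whole-axis tiles are written (a single tile), which
every UCSF reader accepts.

The Sparky axis convention maps index i (0-based, downfield first) to
``ppm(i) = center + (n/2 - i) * sw / (n * obs)``.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from ..containers import CorrelationMap

__all__ = ["write_ucsf", "read_ucsf"]


def _axis_header(nucleus: str, npoints: int, tile: int, obs: float,
                 sw: float, center: float) -> bytes:
    buf = bytearray(128)
    buf[0:6] = nucleus.encode().ljust(6, b"\x00")
    struct.pack_into(">i", buf, 8, npoints)
    struct.pack_into(">i", buf, 16, tile)
    struct.pack_into(">f", buf, 20, obs)
    struct.pack_into(">f", buf, 24, sw)
    struct.pack_into(">f", buf, 28, center)
    return bytes(buf)


def write_ucsf(cmap: CorrelationMap, path, f_h: float = 700.0,
               gamma_ratio: float = 0.25144953) -> None:
    """Write a correlation map (and a sigma sibling if present) as UCSF.

    Axis w1 is 13C (indirect), w2 is 1H (direct); both stored downfield
    first per the Sparky convention.  ``f_h`` is the 1H base frequency in
    MHz used to express the axes.
    """
    if cmap.h_axis_ppm.size < 2 or cmap.c_axis_ppm.size < 2:
        raise ValueError("map axes required for UCSF export")
    _write_plane(cmap.data, cmap.h_axis_ppm, cmap.c_axis_ppm, path,
                 f_h, gamma_ratio)
    if cmap.sigma is not None:
        p = Path(path)
        _write_plane(cmap.sigma, cmap.h_axis_ppm, cmap.c_axis_ppm,
                     p.with_name(p.stem + "_sigma" + p.suffix),
                     f_h, gamma_ratio)


def _write_plane(data, h_ppm, c_ppm, path, f_h, gamma_ratio) -> None:
    n_h, n_c = data.shape
    f_c = f_h * gamma_ratio
    # store downfield-first: reverse the ascending internal axes
    plane = np.asarray(data, dtype=np.float32)[::-1, ::-1]
    # (w1, w2) = (13C, 1H): transpose so 1H is the fast axis
    plane = np.ascontiguousarray(plane.T)
    dh = h_ppm[1] - h_ppm[0]
    dc = c_ppm[1] - c_ppm[0]
    sw_h = n_h * dh * f_h
    sw_c = n_c * dc * f_c
    # Sparky center: ppm at index n/2 of the downfield-first axis
    center_h = h_ppm[::-1][n_h // 2] + 0.0
    center_c = c_ppm[::-1][n_c // 2] + 0.0
    head = bytearray(180)
    head[0:8] = b"UCSF NMR"
    head[10] = 2          # dimensions
    head[11] = 1          # real components
    head[13] = 2          # format version
    with open(Path(path), "wb") as fh:
        fh.write(bytes(head))
        fh.write(_axis_header("13C", n_c, n_c, f_c, sw_c, center_c))
        fh.write(_axis_header("1H", n_h, n_h, f_h, sw_h, center_h))
        fh.write(plane.astype(">f4").tobytes())


def read_ucsf(path) -> CorrelationMap:
    """Read a 2D UCSF file back into a correlation map (ascending axes)."""
    raw = Path(path).read_bytes()
    if raw[0:8] != b"UCSF NMR":
        raise ValueError(f"{path} is not a UCSF file")
    ndim = raw[10]
    if ndim != 2:
        raise ValueError(f"only 2D UCSF supported, got {ndim} dimensions")
    axes = []
    off = 180
    for _ in range(2):
        nuc = raw[off:off + 6].split(b"\x00")[0].decode()
        npts = struct.unpack_from(">i", raw, off + 8)[0]
        tile = struct.unpack_from(">i", raw, off + 16)[0]
        obs = struct.unpack_from(">f", raw, off + 20)[0]
        sw = struct.unpack_from(">f", raw, off + 24)[0]
        center = struct.unpack_from(">f", raw, off + 28)[0]
        axes.append(dict(nucleus=nuc, n=npts, tile=tile, obs=obs, sw=sw,
                         center=center))
        off += 128
    n1, n2 = axes[0]["n"], axes[1]["n"]
    if axes[0]["tile"] != n1 or axes[1]["tile"] != n2:
        raise ValueError("tiled UCSF layouts other than whole-axis tiles "
                         "are not supported")
    plane = np.frombuffer(raw[off:off + 4 * n1 * n2], dtype=">f4").reshape(n1, n2)

    def ppm_axis(a):
        i = np.arange(a["n"])
        return a["center"] + (a["n"] / 2.0 - i) * a["sw"] / (a["n"] * a["obs"])

    c_desc = ppm_axis(axes[0])
    h_desc = ppm_axis(axes[1])
    data = np.ascontiguousarray(plane.T[::-1, ::-1]).astype(np.float32)
    return CorrelationMap(
        data=data,
        h_axis_ppm=h_desc[::-1].copy(),
        c_axis_ppm=c_desc[::-1].copy(),
    )
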