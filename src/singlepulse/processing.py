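"""Ingesting off-resonance series and assembling network-ready stacks.

A :class:`RawSeries` is one B1 channel of a single-pulse experiment: one
record (time-domain FID or processed spectrum) per 13C decoupler offset,
plus the reference record (far off-resonance or no decoupling) and the
acquisition metadata.  :func:`build_input_stack` processes both channels,
subtracts the processed reference spectrum from every offset spectrum,
stacks the channels (high B1 first) and scales the joint stack to a global
maximum of 1 — recording the scale, which downstream quantitative mixture
analysis needs.

By linearity of phasing, apodization, zero-filling and the Fourier
transform, subtracting reference FIDs in the time domain and subtracting
reference spectra after processing are equivalent; the tests pin this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .containers import OffResonanceDataset
from .sim import _process_fids, simulate_fid_series
from .spinsys import AcquisitionScheme, SpinSystem

__all__ = [
    "RawSeries", "ProcessingParams", "read_series", "write_series",
    "build_input_stack", "coadd", "series_from_simulation",
]

_REQUIRED_META = ("f_h", "sw_h", "t_max", "offsets_ppm", "b1_hz",
                  "carrier_h", "domain")


@dataclass
class ProcessingParams:
    """Spectral processing applied to each record before subtraction."""

    phase0: float = 0.0
    phase1: float = 0.0
    apodize: bool = True
    n_zf: int = 512

    def __post_init__(self) -> None:
        if self.phase1 != 0.0:
            raise NotImplementedError(
                "first-order phase correction is not supported for "
                "single-pulse FIDs (no evolution delay to correct for)"
            )


@dataclass
class RawSeries:
    """One B1 channel of an off-resonance experiment."""

    data: np.ndarray            # (n_offsets, n_points), complex or real
    reference: np.ndarray       # (n_points,)
    domain: str                 # "time" | "freq"
    f_h: float                  # MHz
    sw_h: float                 # ppm
    t_max: float                # s
    carrier_h: float            # ppm
    offsets_ppm: np.ndarray
    b1_hz: float
    reference_mode: str = "far_offset"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.reference = np.asarray(self.reference)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("series data must be (n_offsets, n_points)")
        if self.data.shape[0] != self.offsets_ppm.size:
            raise ValueError(
                f"series has {self.data.shape[0]} records but metadata "
                f"declares {self.offsets_ppm.size} offsets"
            )
        if self.reference.shape != (self.data.shape[1],):
            raise ValueError("reference record length must match the records")
        if self.domain not in ("time", "freq"):
            raise ValueError(f"unknown domain {self.domain!r}")

    def scheme(self, n_zf: int) -> AcquisitionScheme:
        return AcquisitionScheme(
            f_h=self.f_h,
            carrier_h=self.carrier_h,
            sw_h=self.sw_h,
            t_max=self.t_max,
            n_zf=n_zf,
            b1_list=(self.b1_hz,),
            offsets_c=self.offsets_ppm,
        )


def series_from_simulation(
    spins: Sequence[SpinSystem],
    scheme: AcquisitionScheme,
    b1: float,
) -> RawSeries:
    """Simulate a raw (time-domain) series for one B1 channel."""
    fids, ref = simulate_fid_series(spins, scheme, b1)
    return RawSeries(
        data=fids,
        reference=ref,
        domain="time",
        f_h=scheme.f_h,
        sw_h=scheme.sw_h,
        t_max=scheme.t_max,
        carrier_h=scheme.carrier_h,
        offsets_ppm=scheme.offsets_c.copy(),
        b1_hz=b1,
        reference_mode=scheme.reference_mode,
        meta={"kind": "synthetic"},
    )


# ---- series file IO ---------------------------------------------------------


def write_series(series: RawSeries, path, fmt: str = "array_container") -> None:
    """Write a series; metadata goes to a JSON sidecar in either format."""
    path = Path(path)
    meta = {
        "f_h": series.f_h,
        "sw_h": series.sw_h,
        "t_max": series.t_max,
        "carrier_h": series.carrier_h,
        "offsets_ppm": series.offsets_ppm.tolist(),
        "b1_hz": series.b1_hz,
        "domain": series.domain,
        "reference_mode": series.reference_mode,
        "meta": series.meta,
    }
    if fmt == "array_container":
        np.savez(
            path.with_suffix(".npz"),
            data=series.data,
            reference=series.reference,
        )
    elif fmt == "nmrpipe":
        from .ioformats.nmrpipe import write_pipe

        if series.domain != "freq" and np.iscomplexobj(series.data):
            raise ValueError(
                "NMRPipe export of complex time-domain series is not "
                "supported; export the array container or process first"
            )
        axes = [
            {"sw": series.sw_h * series.f_h, "obs": series.f_h,
             "car": series.carrier_h, "ft": series.domain == "freq"},
            {"sw": float(series.offsets_ppm.size), "obs": 1.0, "car": 0.0,
             "ft": False},
        ]
        write_pipe(path.with_suffix(".ft2"), np.real(series.data), axes)
        write_pipe(path.with_suffix(".ref.ft1"), np.real(series.reference),
                   axes[:1])
    else:
        raise ValueError(f"unknown series format {fmt!r}")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh)


def read_series(path, fmt: str = "array_container") -> RawSeries:
    """Read a series written by :func:`write_series`."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in _REQUIRED_META:
        if key not in meta:
            raise KeyError(f"series metadata is missing required key {key!r}")
    if fmt == "array_container":
        with np.load(path.with_suffix(".npz")) as z:
            data, reference = z["data"], z["reference"]
    elif fmt == "nmrpipe":
        from .ioformats.nmrpipe import read_pipe

        data, _ = read_pipe(path.with_suffix(".ft2"))
        reference, _ = read_pipe(path.with_suffix(".ref.ft1"))
    else:
        raise ValueError(f"unknown series format {fmt!r}")
    return RawSeries(
        data=data,
        reference=reference,
        domain=meta["domain"],
        f_h=meta["f_h"],
        sw_h=meta["sw_h"],
        t_max=meta["t_max"],
        carrier_h=meta["carrier_h"],
        offsets_ppm=np.asarray(meta["offsets_ppm"]),
        b1_hz=meta["b1_hz"],
        reference_mode=meta.get("reference_mode", "far_offset"),
        meta=meta.get("meta", {}),
    )


# ---- stack assembly ---------------------------------------------------------


def _process_series(series: RawSeries, params: ProcessingParams) -> np.ndarray:
    """Per-offset difference spectra (real part), (n_offsets, n_zf)."""
    scheme = series.scheme(params.n_zf)
    if series.domain == "time":
        spec = _process_fids(
            series.data, scheme, apodize=params.apodize, phase=params.phase0
        ).real
        ref = _process_fids(
            series.reference[None], scheme, apodize=params.apodize,
            phase=params.phase0,
        ).real[0]
    else:
        if series.data.shape[1] != params.n_zf:
            raise ValueError(
                "frequency-domain records must already have n_zf points"
            )
        spec = np.real(series.data)
        ref = np.real(series.reference)
    return spec - ref[None, :]


def build_input_stack(
    series_hi: RawSeries,
    series_lo: RawSeries,
    params: Optional[ProcessingParams] = None,
) -> OffResonanceDataset:
    """Process two B1 channels into a normalized difference stack.

    Channel order is fixed high B1 then low B1.  The joint stack is scaled
    to a global |max| of 1 with the scale recorded; an all-zero stack is
    returned unnormalized with a flag in its metadata.
    """
    params = params or ProcessingParams()
    if series_hi.b1_hz == series_lo.b1_hz:
        raise ValueError(
            "cannot order channels: both series have the same B1"
        )
    if series_hi.b1_hz < series_lo.b1_hz:
        series_hi, series_lo = series_lo, series_hi
    if not np.allclose(series_hi.offsets_ppm, series_lo.offsets_ppm):
        raise ValueError("B1 channels have different decoupler offset lists")
    for attr in ("f_h", "sw_h", "carrier_h"):
        if not np.isclose(getattr(series_hi, attr), getattr(series_lo, attr)):
            raise ValueError(f"B1 channels disagree on {attr}")
    d_hi = _process_series(series_hi, params)
    d_lo = _process_series(series_lo, params)
    stack = np.stack([d_hi.T, d_lo.T], axis=-1)  # (n_zf, n_offsets, 2)
    scheme = series_hi.scheme(params.n_zf)
    ds = OffResonanceDataset(
        data=stack,
        h_axis_ppm=scheme.h_axis_ppm(),
        offsets_ppm=series_hi.offsets_ppm.copy(),
        b1_list=(series_hi.b1_hz, series_lo.b1_hz),
        normalized=False,
        scale=1.0,
        meta={"kind": series_hi.meta.get("kind", "experimental")},
    )
    if np.max(np.abs(stack)) == 0.0:
        ds.meta["all_zero"] = True
        return ds
    return ds.normalize()


def coadd(
    a: OffResonanceDataset,
    b: OffResonanceDataset,
    ratio: float,
) -> OffResonanceDataset:
    """Mix two stacks as a + ratio*b on their pre-normalization scales.

    Emulates a sample that combines the two components with the second
    scaled by ``ratio``; the result is renormalized and its scale recorded
    so fitted intensities remain comparable across mixtures.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("stacks must share shapes to be coadded")
    if not (
        np.allclose(a.h_axis_ppm, b.h_axis_ppm)
        and np.allclose(a.offsets_ppm, b.offsets_ppm)
        and np.allclose(a.b1_list, b.b1_list)
    ):
        raise ValueError("stacks must share axes and B1 lists to be coadded")
    raw = a.data * a.scale + ratio * b.data * b.scale
    ds = OffResonanceDataset(
        data=raw,
        h_axis_ppm=a.h_axis_ppm,
        offsets_ppm=a.offsets_ppm,
        b1_list=a.b1_list,
        normalized=False,
        scale=1.0,
        meta={"kind": "coadd", "ratio": ratio},
    )
    return ds.normalize()
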