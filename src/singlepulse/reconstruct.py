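"""Monte-Carlo-dropout reconstruction of correlation maps.

Twenty (by default) stochastic forward passes with dropout active in all
but the last hidden layer give an ensemble of predicted maps; the
point-wise mean is the reconstructed map and the point-wise SD, scaled by
the calibration factor 1.4, is its uncertainty.  The raw passes are kept
for downstream intensity-error propagation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .containers import CorrelationMap, OffResonanceDataset
from .nn.estimator import CorrelationMapper

__all__ = ["McConfig", "mc_reconstruct", "write_map", "read_map"]


@dataclass
class McConfig:
    """Monte-Carlo dropout settings.

    ``sigma_factor`` converts the ensemble SD into the reported
    uncertainty (calibration factor 1.4); ``seed`` makes reconstructions
    reproducible (the dropout stream also folds in the model weights and
    the input, so different inputs never share masks).
    """

    n_passes: int = 20
    sigma_factor: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_passes < 2:
            raise ValueError("n_passes must be >= 2")
        if self.sigma_factor <= 0:
            raise ValueError("sigma_factor must be > 0")


def _mc_seed(est: CorrelationMapper, ds: OffResonanceDataset, seed: int) -> int:
    """Seed derived from (model weights, input, user seed)."""
    h = zlib.crc32(np.ascontiguousarray(ds.data, dtype=np.float32).tobytes())
    for k in sorted(est.model_.params):
        h = zlib.crc32(est.model_.params[k].tobytes(), h)
    return int((h ^ (seed * 0x9E3779B1)) % (2 ** 31))


def mc_reconstruct(
    est: CorrelationMapper,
    ds: OffResonanceDataset,
    cfg: McConfig | None = None,
) -> CorrelationMap:
    """Reconstruct one normalized stack into a map with uncertainties.

    The input must already be normalized to a global maximum of 1 —
    normalization is the caller's declared processing step and is never
    applied silently here.
    """
    cfg = cfg or McConfig()
    if not ds.normalized:
        raise ValueError(
            "input stack is not normalized; call .normalize() first "
            "(silent rescaling is deliberately not performed)"
        )
    X = ds.data[None].astype(np.float32)
    passes = est.sample_predict(
        X, n_passes=cfg.n_passes, random_state=_mc_seed(est, ds, cfg.seed)
    )[:, 0]                                   # (n_passes, n_H, n_off)
    mean = passes.mean(axis=0)
    sigma = cfg.sigma_factor * passes.std(axis=0, ddof=0)
    return CorrelationMap(
        data=mean,
        h_axis_ppm=ds.h_axis_ppm.copy(),
        c_axis_ppm=ds.offsets_ppm.copy(),
        sigma=sigma,
        meta={
            "n_passes": cfg.n_passes,
            "sigma_factor": cfg.sigma_factor,
            "seed": cfg.seed,
            "input_scale": ds.scale,
            "passes": passes,
        },
    )


def write_map(cmap: CorrelationMap, path, fmt: str = "array_container") -> None:
    """Write a map (sigma written as a sibling file where applicable)."""
    if cmap.h_axis_ppm.size < 2 or cmap.c_axis_ppm.size < 2:
        raise ValueError("map axes required for export")
    if fmt == "array_container":
        from .ioformats.container import save_map

        save_map(cmap, path)
    elif fmt == "ucsf":
        from .ioformats.ucsf import write_ucsf

        write_ucsf(cmap, path)
    elif fmt == "nmrpipe_ft2":
        from .ioformats.nmrpipe import write_pipe

        f_h = 700.0
        f_c = f_h * 0.25144953
        n_h, n_c = cmap.data.shape
        dh = cmap.h_axis_ppm[1] - cmap.h_axis_ppm[0]
        dc = cmap.c_axis_ppm[1] - cmap.c_axis_ppm[0]
        # carrier chosen so the codec's ORIG convention reproduces the axes
        axes = [
            {"sw": n_h * dh * f_h, "obs": f_h,
             "car": float(cmap.h_axis_ppm[-1] - (n_h // 2) * dh), "ft": True},
            {"sw": n_c * dc * f_c, "obs": f_c,
             "car": float(cmap.c_axis_ppm[-1] - (n_c // 2) * dc), "ft": True},
        ]
        # direct dim last, downfield first on both axes
        write_pipe(path, cmap.data[::-1, ::-1].T, axes)
        if cmap.sigma is not None:
            from pathlib import Path

            p = Path(path)
            write_pipe(p.with_name(p.stem + "_sigma" + p.suffix),
                       cmap.sigma[::-1, ::-1].T, axes)
    else:
        raise ValueError(f"unknown map format {fmt!r}")


def read_map(path, fmt: str = "array_container") -> CorrelationMap:
    if fmt == "array_container":
        from .ioformats.container import load_map

        return load_map(path)
    if fmt == "ucsf":
        from .ioformats.ucsf import read_ucsf

        return read_ucsf(path)
    raise ValueError(f"unknown map format {fmt!r}")
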