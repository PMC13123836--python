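"""The package's native array container: a .npy file plus a JSON sidecar.

The sidecar carries the axes, units, B1 list, normalization state and
provenance metadata; the .npy holds the bare array.  Round trips are
bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..containers import CorrelationMap, OffResonanceDataset

__all__ = ["save_dataset", "load_dataset", "save_map", "load_map"]


def _paths(path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    return path.with_suffix(".npy"), path.with_suffix(".json")


def save_dataset(ds: OffResonanceDataset, path) -> None:
    npy, meta = _paths(path)
    np.save(npy, ds.data)
    with open(meta, "w") as fh:
        json.dump(
            {
                "kind": "offresonance_dataset",
                "h_axis_ppm": ds.h_axis_ppm.tolist(),
                "offsets_ppm": ds.offsets_ppm.tolist(),
                "b1_hz": list(ds.b1_list),
                "normalized": ds.normalized,
                "scale": ds.scale,
                "meta": ds.meta,
            },
            fh,
        )


def load_dataset(path) -> OffResonanceDataset:
    npy, meta = _paths(path)
    data = np.load(npy)
    with open(meta) as fh:
        m = json.load(fh)
    if m.get("kind") != "offresonance_dataset":
        raise ValueError(f"{meta} does not describe an off-resonance dataset")
    return OffResonanceDataset(
        data=data,
        h_axis_ppm=np.asarray(m["h_axis_ppm"]),
        offsets_ppm=np.asarray(m["offsets_ppm"]),
        b1_list=tuple(m["b1_hz"]),
        normalized=m["normalized"],
        scale=m["scale"],
        meta=m.get("meta", {}),
    )


def save_map(cmap: CorrelationMap, path) -> None:
    npy, meta = _paths(path)
    np.save(npy, cmap.data)
    if cmap.sigma is not None:
        np.save(npy.with_name(npy.stem + "_sigma.npy"), cmap.sigma)
    with open(meta, "w") as fh:
        json.dump(
            {
                "kind": "correlation_map",
                "h_axis_ppm": cmap.h_axis_ppm.tolist(),
                "c_axis_ppm": cmap.c_axis_ppm.tolist(),
                "has_sigma": cmap.sigma is not None,
                "meta": cmap.meta,
            },
            fh,
        )


def load_map(path) -> CorrelationMap:
    npy, meta = _paths(path)
    data = np.load(npy)
    with open(meta) as fh:
        m = json.load(fh)
    if m.get("kind") != "correlation_map":
        raise ValueError(f"{meta} does not describe a correlation map")
    sigma = None
    if m.get("has_sigma"):
        sigma = np.load(npy.with_name(npy.stem + "_sigma.npy"))
    return CorrelationMap(
        data=data,
        h_axis_ppm=np.asarray(m["h_axis_ppm"]),
        c_axis_ppm=np.asarray(m["c_axis_ppm"]),
        sigma=sigma,
        meta=m.get("meta", {}),
    )
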