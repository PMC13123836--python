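"""Randomized training data: difference stacks paired with Gaussian target maps.

Each training example is generated by (i) drawing global acquisition
parameters (field, B1 pair, sweep widths, FID phase) with small jitters,
(ii) drawing 1..n_peaks_max spin pairs with methyl-like shifts, couplings
and relaxation rates, (iii) simulating the two-B1 difference off-resonance
stack, normalizing it to a global maximum of 1, adding Gaussian noise and
rescaling back to 1, and (iv) rendering the noise-free target map with a 2D
Gaussian per spin (amplitude I0, 1H FWHM max(R2H/pi, floor), fixed 13C
FWHM).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .containers import CorrelationMap, OffResonanceDataset
from .sim import simulate_offres_dataset
from .spinsys import AcquisitionScheme, SpinSystem

__all__ = [
    "GeneratorConfig",
    "TrainingExample",
    "sample_example",
    "build_target_map",
    "write_shards",
    "iter_shards",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GeneratorConfig:
    """Parameter ranges for the synthetic-data generator.

    Defaults emulate 13CHD2 methyl probes at 16.4 T with CW decoupling at
    ~220/110 Hz, 200 offsets over 30 ppm and a ~5 ppm 1H sweep.  All ranges
    are (low, high) and sampled uniformly.  ``reduced()`` gives the
    256 x 100 grid used for desk-scale training, with target linewidths
    scaled to preserve the full-scale width in pixels.
    """

    f_h: float = 700.0
    b0_jitter: float = 0.01
    b1_nominal: tuple = (220.0, 110.0)
    b1_jitter: float = 0.03
    sw_h_range: tuple = (4.75, 5.25)
    carrier_h: float = 0.5
    offsets_span_range: tuple = (29.0, 31.0)
    offsets_center: float = 13.0
    offsets_center_jitter: float = 0.5
    n_offsets: int = 200
    n_zf: int = 512
    t_max: float = 0.064
    wh_window: tuple = (-0.7, 1.6)
    wc_window: tuple = (-1.0, 27.0)
    j_range: tuple = (120.0, 130.0)
    r2h_range: tuple = (5.0, 120.0)
    r2mq_range: tuple = (2.0, 120.0)
    r2aph_range: tuple = (5.0, 150.0)
    i0_range: tuple = (0.05, 1.0)
    fid_phase_range: tuple = (-30.0, 30.0)
    noise_max_range: tuple = (0.0, 0.05)
    n_peaks_max: int = 10
    h_fwhm_min_hz: float = 20.0
    c_fwhm_hz: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sw_h_range", "offsets_span_range", "wh_window", "wc_window",
            "j_range", "r2h_range", "r2mq_range", "r2aph_range", "i0_range",
            "fid_phase_range", "noise_max_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered (low, high)")
        if self.n_peaks_max < 1:
            raise ValueError("n_peaks_max must be >= 1")

    @classmethod
    def reduced(cls, **overrides) -> "GeneratorConfig":
        """Desk-scale preset: 256 x 100 grid, linewidths kept at the same
        fraction of a pixel as on the full 512 x 200 grid."""
        kw = dict(
            n_zf=256,
            n_offsets=100,
            h_fwhm_min_hz=40.0,
            c_fwhm_hz=60.0,
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def nominal_scheme(self) -> AcquisitionScheme:
        """The jitter-free acquisition scheme at the configured midpoints."""
        return AcquisitionScheme(
            f_h=self.f_h,
            carrier_h=self.carrier_h,
            sw_h=0.5 * (self.sw_h_range[0] + self.sw_h_range[1]),
            t_max=self.t_max,
            n_zf=self.n_zf,
            b1_list=self.b1_nominal,
            offsets_c=np.linspace(
                self.offsets_center - 15.0, self.offsets_center + 15.0,
                self.n_offsets,
            ),
        )

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class TrainingExample:
    """A paired (input stack, target map) example plus the generating truth."""

    input: OffResonanceDataset
    target: CorrelationMap
    spins: list
    scheme: AcquisitionScheme
    seed: int | None = None


def _draw_scheme(cfg: GeneratorConfig, rng: np.random.Generator) -> AcquisitionScheme:
    f_h = cfg.f_h * (1.0 + rng.uniform(-cfg.b0_jitter, cfg.b0_jitter))
    b1s = tuple(
        b * (1.0 + rng.uniform(-cfg.b1_jitter, cfg.b1_jitter))
        for b in cfg.b1_nominal
    )
    sw_h = rng.uniform(*cfg.sw_h_range)
    span = rng.uniform(*cfg.offsets_span_range)
    center = cfg.offsets_center + rng.uniform(
        -cfg.offsets_center_jitter, cfg.offsets_center_jitter
    )
    offsets = np.linspace(center - span / 2.0, center + span / 2.0, cfg.n_offsets)
    return AcquisitionScheme(
        f_h=f_h,
        carrier_h=cfg.carrier_h,
        sw_h=sw_h,
        t_max=cfg.t_max,
        n_zf=cfg.n_zf,
        b1_list=b1s,
        offsets_c=offsets,
    )


def _draw_spins(
    cfg: GeneratorConfig,
    scheme: AcquisitionScheme,
    n_peaks: int,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> list[SpinSystem]:
    h_axis = scheme.h_axis_ppm()
    h_lo, h_hi = h_axis[0], h_axis[-1]
    c_lo, c_hi = scheme.offsets_c[0], scheme.offsets_c[-1]
    spins = []
    for _ in range(n_peaks):
        for attempt in range(max_retries):
            wh = rng.uniform(*cfg.wh_window)
            wc = rng.uniform(*cfg.wc_window)
            # resample (not clip) draws falling off the realized axes
            if h_lo < wh < h_hi and c_lo < wc < c_hi:
                break
        else:
            raise ValueError(
                "could not draw a shift inside the spectral axes; check that "
                "wh_window/wc_window lie within the acquisition windows"
            )
        spins.append(
            SpinSystem(
                wh=wh,
                wc=wc,
                j_hc=rng.uniform(*cfg.j_range),
                r2_h=rng.uniform(*cfg.r2h_range),
                r2_mq=rng.uniform(*cfg.r2mq_range),
                r2_aph=rng.uniform(*cfg.r2aph_range),
                i0=rng.uniform(*cfg.i0_range),
            )
        )
    return spins


def build_target_map(
    spins: Sequence[SpinSystem],
    scheme: AcquisitionScheme,
    h_fwhm_min_hz: float = 20.0,
    c_fwhm_hz: float = 30.0,
) -> CorrelationMap:
    """Render the noise-free target map: one 2D Gaussian per spin.

    Peak amplitude is I0; the 1H FWHM is max(R2H/pi, ``h_fwhm_min_hz``) and
    the 13C FWHM is fixed (no 13C linewidth information survives in the
    input).  Gaussians are evaluated at pixel centers; overlapping peaks sum.
    """
    h_ppm = scheme.h_axis_ppm()
    c_ppm = scheme.offsets_c
    h_hz_per_ppm = scheme.f_h
    c_hz_per_ppm = scheme.f_c
    data = np.zeros((h_ppm.size, c_ppm.size))
    for s in spins:
        if not (h_ppm[0] <= s.wh <= h_ppm[-1]) or not (c_ppm[0] <= s.wc <= c_ppm[-1]):
            raise ValueError(f"spin at ({s.wh}, {s.wc}) ppm lies outside the map axes")
        fwhm_h = max(s.r2_h / np.pi, h_fwhm_min_hz)
        sig_h = fwhm_h * FWHM_TO_SIGMA / h_hz_per_ppm  # ppm
        sig_c = c_fwhm_hz * FWHM_TO_SIGMA / c_hz_per_ppm
        gh = np.exp(-0.5 * ((h_ppm - s.wh) / sig_h) ** 2)
        gc = np.exp(-0.5 * ((c_ppm - s.wc) / sig_c) ** 2)
        data += s.i0 * np.outer(gh, gc)
    return CorrelationMap(data=data, h_axis_ppm=h_ppm, c_axis_ppm=c_ppm.copy())


def sample_example(
    cfg: GeneratorConfig,
    rng: np.random.Generator | int | None = None,
) -> TrainingExample:
    """Draw one training example (deterministic for a given rng state/seed)."""
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    scheme = _draw_scheme(cfg, rng)
    n_peaks = int(rng.integers(1, cfg.n_peaks_max + 1))
    spins = _draw_spins(cfg, scheme, n_peaks, rng)
    phase = rng.uniform(*cfg.fid_phase_range)
    noise_amp = rng.uniform(*cfg.noise_max_range)

    ds = simulate_offres_dataset(spins, scheme, apodize=True, phase=phase)
    ds.meta.update(fid_phase=phase, n_peaks=n_peaks)
    ds = ds.normalize()
    if noise_amp > 0:
        noisy = ds.data + rng.normal(0.0, noise_amp, size=ds.data.shape)
        ds = OffResonanceDataset(
            data=noisy,
            h_axis_ppm=ds.h_axis_ppm,
            offsets_ppm=ds.offsets_ppm,
            b1_list=ds.b1_list,
            normalized=False,
            scale=ds.scale,
            meta=dict(ds.meta, noise_amp=noise_amp),
        ).normalize()
    target = build_target_map(
        spins, scheme, h_fwhm_min_hz=cfg.h_fwhm_min_hz, c_fwhm_hz=cfg.c_fwhm_hz
    )
    return TrainingExample(
        input=ds, target=target, spins=spins, scheme=scheme, seed=seed
    )


def examples_to_arrays(
    examples: Sequence[TrainingExample],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into network arrays X (n, H, W, 2) and y (n, H, W)."""
    X = np.stack([ex.input.data for ex in examples]).astype(np.float32)
    y = np.stack([ex.target.data for ex in examples]).astype(np.float32)
    return X, y


# ---- shard IO ---------------------------------------------------------------


def write_shards(
    examples: Sequence[TrainingExample],
    path,
    shard_size: int = 32,
) -> list[Path]:
    """Write examples into npz shards with a JSON truth/config sidecar."""
    if len(examples) == 0:
        raise ValueError("cannot shard an empty example list")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = []
    for si, start in enumerate(range(0, len(examples), shard_size)):
        chunk = examples[start:start + shard_size]
        X, y = examples_to_arrays(chunk)
        truth = [
            {
                "spins": [s.to_dict() for s in ex.spins],
                "scheme": ex.scheme.to_dict(),
                "seed": ex.seed,
            }
            for ex in chunk
        ]
        meta = json.dumps(truth).encode()
        digest = hashlib.sha256(X.tobytes() + y.tobytes() + meta).hexdigest()
        fn = path / f"shard_{si:05d}.npz"
        np.savez(
            fn,
            inputs=X,
            targets=y,
            truth=np.frombuffer(meta, dtype=np.uint8),
            digest=np.array(digest),
        )
        files.append(fn)
    return files


def iter_shards(path) -> Iterator[tuple[np.ndarray, np.ndarray, list]]:
    """Yield (inputs, targets, truth) per shard, verifying content hashes."""
    path = Path(path)
    files = sorted(path.glob("shard_*.npz"))
    if not files:
        raise FileNotFoundError(f"no shards under {path}")
    for fn in files:
        with np.load(fn) as z:
            X, y = z["inputs"], z["targets"]
            meta = z["truth"].tobytes()
            digest = hashlib.sha256(X.tobytes() + y.tobytes() + meta).hexdigest()
            if digest != str(z["digest"]):
                raise IOError(f"corrupt shard {fn}: content hash mismatch")
            yield X, y, json.loads(meta.decode())
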