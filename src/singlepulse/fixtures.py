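"""Deterministic synthetic spin-system fixtures.

Two protein-like methyl spin lists used throughout the tests and the
worked examples:

* ``ff_like_spins`` — 14 well-dispersed ILV methyl probes emulating a small
  (~8 kDa) domain: narrow lines, moderate rates.
* ``t4l_like_spins`` — 60 methyl probes emulating a medium (~18 kDa)
  protein, drawn deterministically with regions of genuine overlap.

Positions are synthetic stand-ins with realistic methyl-region shifts; they
do not correspond to any real assignment.
"""

from __future__ import annotations

import numpy as np

from .spinsys import SpinSystem

__all__ = ["ff_like_spins", "t4l_like_spins", "mixture_grid_spins"]

# (wH ppm, wC ppm, J Hz, R2H, R2MQ, R2APH, I0)
_FF_TABLE = [
    (0.62, 13.1, 125.0, 18.0, 10.0, 22.0, 0.95),
    (0.71, 14.0, 125.5, 20.0, 12.0, 25.0, 0.80),
    (0.84, 12.4, 124.5, 16.0, 9.0, 20.0, 1.00),
    (0.07, 10.9, 125.0, 22.0, 13.0, 27.0, 0.70),
    (0.93, 16.8, 126.0, 19.0, 11.0, 24.0, 0.85),
    (0.55, 21.6, 124.0, 17.0, 10.0, 21.0, 0.90),
    (0.88, 23.3, 125.0, 21.0, 12.0, 26.0, 0.75),
    (0.80, 24.9, 125.5, 18.0, 10.0, 23.0, 0.88),
    (1.05, 22.4, 124.5, 20.0, 11.0, 24.0, 0.82),
    (0.34, 25.6, 125.0, 16.0, 9.0, 20.0, 0.93),
    (1.13, 19.7, 126.0, 23.0, 14.0, 28.0, 0.65),
    (0.25, 17.9, 124.0, 19.0, 11.0, 23.0, 0.78),
    (-0.12, 20.8, 125.0, 17.0, 10.0, 22.0, 0.86),
    (0.47, 9.6, 125.5, 21.0, 12.0, 25.0, 0.72),
]


def ff_like_spins() -> list[SpinSystem]:
    """The 14-methyl small-domain fixture."""
    return [
        SpinSystem(wh=h, wc=c, j_hc=j, r2_h=rh, r2_mq=rm, r2_aph=ra, i0=i)
        for h, c, j, rh, rm, ra, i in _FF_TABLE
    ]


def mixture_grid_spins(seed: int = 0) -> tuple[list[SpinSystem], list[SpinSystem]]:
    """Two interleaved grids of isolated methyl probes for mixture analysis.

    Returns ``(constant, scaled)`` components for coadded-dataset studies in
    which the second component's concentration is varied.  Design rules:
    peaks are well separated (no overlapping fit windows); the constant
    component carries the strongest amplitudes so it dominates the global
    normalization of every mixture (the normalization scale then cancels
    between mixtures, as when the constant sample is the more concentrated
    one); and the scaled component's amplitudes stay within the generator's
    trained intensity range at mixing ratios 0.5-1.5 while remaining well
    above the noise floor.
    """
    rng = np.random.default_rng(seed)

    def grid(wh0, wc0, i0_range):
        out = []
        for i in range(5):
            for j in range(6):
                out.append(SpinSystem(
                    wh=wh0 + i * 0.45 + rng.uniform(-0.04, 0.04),
                    wc=wc0 + j * 4.5 + rng.uniform(-0.4, 0.4),
                    j_hc=rng.uniform(123.0, 127.0),
                    r2_h=rng.uniform(18.0, 40.0),
                    r2_mq=rng.uniform(10.0, 25.0),
                    r2_aph=rng.uniform(20.0, 45.0),
                    i0=rng.uniform(*i0_range),
                ))
        return out

    constant = grid(-0.55, 0.5, (0.8, 1.0))
    scaled = grid(-0.35, 2.6, (0.35, 0.5))
    return constant, scaled


def t4l_like_spins(seed: int = 1918) -> list[SpinSystem]:
    """A 60-methyl medium-protein fixture (deterministic for a seed)."""
    rng = np.random.default_rng(seed)
    spins = []
    for _ in range(60):
        spins.append(
            SpinSystem(
                wh=float(rng.uniform(-0.4, 1.3)),
                wc=float(rng.uniform(9.0, 26.0)),
                j_hc=float(rng.uniform(123.0, 127.0)),
                r2_h=float(rng.uniform(20.0, 45.0)),
                r2_mq=float(rng.uniform(10.0, 30.0)),
                r2_aph=float(rng.uniform(25.0, 55.0)),
                i0=float(rng.uniform(0.4, 1.0)),
            )
        )
    return spins
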