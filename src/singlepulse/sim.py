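"""Liouvillian dynamics of a 1H-13C pair under CW 13C decoupling.

The evolution of the eight product-operator coherences
(Hx, Hy, 2HxCx, 2HyCx, 2HxCy, 2HyCy, 2HxCz, 2HyCz) is generated by an 8x8
real matrix ``L`` such that the state vector obeys ``dM/dt = -L M``.  ``L``
is the sum of a diagonal decay part (R2H on the single-quantum 1H terms,
R2MQ on the four multiple-quantum terms, R2APH on the two antiphase terms)
and an antisymmetric coherent part built from the 1H offset, the 13C offset
from the decoupler position, the decoupling field B1 (applied along x on
13C) and the scalar coupling.  Cross-correlated relaxation is not modelled,
and the single-quantum 13C rate never enters: the detected 1H signal does
not depend on it.

Sign conventions are fixed by physics, not typography: every eigenvalue of
``L`` has non-negative real part (the signal decays), and the detected
quadrature signal precesses at +Omega_H so that a standard complex FFT puts
the peak at the 1H chemical shift on an ascending axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import OffResonanceDataset, Spectrum1D
from .spinsys import AcquisitionScheme, SpinSystem

__all__ = [
    "Liouvillian8",
    "build_liouvillian",
    "propagate_fid",
    "synthesize_spectrum",
    "simulate_offres_dataset",
    "simulate_fid_series",
    "effective_splitting",
    "limiting_rate_oracle",
    "BASIS",
]

BASIS = ("Hx", "Hy", "2HxCx", "2HyCx", "2HxCy", "2HyCy", "2HxCz", "2HyCz")


@dataclass
class Liouvillian8:
    """The 8x8 decay generator plus its start vector.

    The detected FID is ``s(t) = d . exp(-L t) . v0`` with
    ``v0 = (I0, 0, ..., 0)``; the detection functional ``d`` is chosen at
    propagation time (quadrature Hx + i Hy by default, or the literal real
    Hx - Hy functional).
    """

    matrix: np.ndarray
    v0: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.matrix.shape != (8, 8) or self.v0.shape != (8,):
            raise ValueError("Liouvillian8 requires an 8x8 matrix and length-8 v0")


def _build_matrices(
    omega_h: np.ndarray,
    omega_c: np.ndarray,
    b1: np.ndarray,
    j_hc: np.ndarray,
    r2_h: np.ndarray,
    r2_mq: np.ndarray,
    r2_aph: np.ndarray,
) -> np.ndarray:
    """Vectorized construction of (n, 8, 8) decay generators."""
    (omega_h, omega_c, b1, j_hc, r2_h, r2_mq, r2_aph) = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float))
          for a in (omega_h, omega_c, b1, j_hc, r2_h, r2_mq, r2_aph))
    )
    n = omega_h.shape[0]
    wh = 2.0 * np.pi * omega_h
    wc = 2.0 * np.pi * omega_c
    w1 = 2.0 * np.pi * b1
    pj = np.pi * j_hc
    L = np.zeros((n, 8, 8), dtype=float)
    # single-quantum 1H block (couples to antiphase via J)
    L[:, 0, 0] = r2_h
    L[:, 0, 1] = wh
    L[:, 0, 7] = pj
    L[:, 1, 0] = -wh
    L[:, 1, 1] = r2_h
    L[:, 1, 6] = -pj
    # multiple-quantum block (1H and 13C offsets; B1 rotates Cy -> Cz)
    L[:, 2, 2] = r2_mq
    L[:, 2, 3] = wh
    L[:, 2, 4] = wc
    L[:, 3, 2] = -wh
    L[:, 3, 3] = r2_mq
    L[:, 3, 5] = wc
    L[:, 4, 2] = -wc
    L[:, 4, 4] = r2_mq
    L[:, 4, 5] = wh
    L[:, 4, 6] = w1
    L[:, 5, 3] = -wc
    L[:, 5, 4] = -wh
    L[:, 5, 5] = r2_mq
    L[:, 5, 7] = w1
    # antiphase block
    L[:, 6, 1] = pj
    L[:, 6, 4] = -w1
    L[:, 6, 6] = r2_aph
    L[:, 6, 7] = wh
    L[:, 7, 0] = -pj
    L[:, 7, 5] = -w1
    L[:, 7, 6] = -wh
    L[:, 7, 7] = r2_aph
    return L


def build_liouvillian(
    spin: SpinSystem,
    b1: float,
    nu_rf: float,
    scheme: AcquisitionScheme,
) -> Liouvillian8:
    """Build the 8x8 generator for one spin pair at one decoupler setting.

    ``b1`` is the CW decoupling field in Hz (0 turns the decoupler off);
    ``nu_rf`` is the decoupler position in ppm and defines the 13C rotating
    frame: the 13C offset entering the matrix is
    ``(wc - nu_rf) * f_h * gamma_ratio`` Hz.
    """
    for name, val in (("b1", b1), ("nu_rf", nu_rf)):
        if not math.isfinite(float(val)):
            raise ValueError(f"{name} must be finite, got {val!r}")
    if b1 < 0:
        raise ValueError(f"b1 must be >= 0, got {b1}")
    omega_h = scheme.omega_h(spin.wh)
    omega_c = scheme.omega_c(spin.wc, nu_rf)
    mat = _build_matrices(
        omega_h, omega_c, b1, spin.j_hc, spin.r2_h, spin.r2_mq, spin.r2_aph
    )[0]
    v0 = np.zeros(8)
    v0[0] = spin.i0
    return Liouvillian8(matrix=mat, v0=v0)


def _fid_from_matrices(
    mats: np.ndarray,
    i0: np.ndarray,
    times: np.ndarray,
    detection: str = "complex_quadrature",
) -> np.ndarray:
    """Closed-form FIDs for a batch of generators: s(t) = d.exp(-Lt).v0.

    A single eigendecomposition per generator gives
    ``s(t) = sum_k c_k exp(-lambda_k t)`` exactly (equivalent to repeated
    application of the one-dwell propagator, without accumulation error).
    Returns an (n, n_t) complex array.
    """
    lam, vec = np.linalg.eig(mats)  # (n, 8), (n, 8, 8)
    if detection == "complex_quadrature":
        d = np.zeros(8, dtype=complex)
        d[0], d[1] = 1.0, 1.0j
    elif detection == "literal_D":
        d = np.zeros(8, dtype=complex)
        d[0], d[1] = 1.0, -1.0
    else:
        raise ValueError(f"unknown detection mode {detection!r}")
    v0 = np.zeros((mats.shape[0], 8), dtype=complex)
    v0[:, 0] = i0
    amp = np.linalg.solve(vec, v0[..., None])[..., 0]  # V^-1 v0
    coef = (d @ vec) * amp  # (n, 8)
    phases = np.exp(-lam[..., None] * times[None, None, :])  # (n, 8, n_t)
    return np.einsum("nk,nkt->nt", coef, phases)


def propagate_fid(
    l8: Liouvillian8,
    time_grid: np.ndarray,
    detection: str = "complex_quadrature",
) -> np.ndarray:
    """Propagate one FID on a uniform time grid starting at 0.

    ``detection="complex_quadrature"`` (default) returns the complex signal
    whose FFT places the peak at +Omega_H; ``"literal_D"`` applies the real
    functional (1, -1, 0, ...) over the basis.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time_grid must be a 1D array with >= 2 points")
    if abs(t[0]) > 1e-15:
        raise ValueError("time_grid must start at 0")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-15):
        raise ValueError("time_grid must be uniformly spaced")
    return _fid_from_matrices(
        l8.matrix[None], np.asarray([l8.v0[0]]), t, detection
    )[0]


def _apodization(n: int) -> np.ndarray:
    """Cosine-square window over the acquired length."""
    return np.cos(0.5 * np.pi * np.arange(n) / (n - 1)) ** 2


def _process_fids(
    fids: np.ndarray,
    scheme: AcquisitionScheme,
    apodize: bool = True,
    phase: float = 0.0,
) -> np.ndarray:
    """Phase, apodize, zero-fill and FT along the last axis of ``fids``."""
    x = np.array(fids, dtype=complex)
    n = x.shape[-1]
    if phase:
        x = x * np.exp(1j * np.deg2rad(phase))
    if apodize:
        x = x * _apodization(n)
    x[..., 0] *= 0.5  # first-point scaling: halves the DC pedestal
    shape = x.shape[:-1] + (scheme.n_zf,)
    padded = np.zeros(shape, dtype=complex)
    padded[..., :n] = x
    return np.fft.fftshift(np.fft.fft(padded, axis=-1), axes=-1)


def synthesize_spectrum(
    fid: np.ndarray,
    scheme: AcquisitionScheme,
    apodize: bool = True,
    phase: float = 0.0,
) -> Spectrum1D:
    """Process one FID into a 1D spectrum with calibrated ppm/Hz axes."""
    fid = np.asarray(fid)
    if fid.ndim != 1:
        raise ValueError("fid must be 1D")
    if fid.size > scheme.n_zf:
        raise ValueError(
            f"n_zf={scheme.n_zf} smaller than the FID length {fid.size}"
        )
    if fid.size != scheme.n_points:
        raise ValueError(
            f"FID length {fid.size} != {scheme.n_points} acquired points"
        )
    data = _process_fids(fid[None], scheme, apodize=apodize, phase=phase)[0]
    return Spectrum1D(
        data=data,
        axis_ppm=scheme.h_axis_ppm(),
        axis_hz=scheme.h_axis_hz(),
    )


def _plus_block(
    omega_c: np.ndarray,
    b1: np.ndarray,
    j_hc: np.ndarray,
    r2_h: np.ndarray,
    r2_mq: np.ndarray,
    r2_aph: np.ndarray,
) -> np.ndarray:
    """4x4 complex generator of the (H+, 2H+Cx, 2H+Cy, 2H+Cz) coherences.

    The eight real coherences pair into four complex ones built on
    H+ = Hx + iHy; in that basis the evolution matrix is the real-basis
    dynamics with the 1H offset factored out as a uniform diagonal phase
    i*2*pi*Omega_H, which therefore never enters the eigenvectors.  This is
    what makes per-spin batching cheap: one 4x4 eigendecomposition per
    (spin, offset, B1), shared by every 1H position.
    """
    (omega_c, b1, j_hc, r2_h, r2_mq, r2_aph) = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float))
          for a in (omega_c, b1, j_hc, r2_h, r2_mq, r2_aph))
    )
    n = omega_c.shape[0]
    wc = 2.0 * np.pi * omega_c
    w1 = 2.0 * np.pi * b1
    pj = np.pi * j_hc
    m = np.zeros((n, 4, 4), dtype=complex)
    m[:, 0, 0] = -r2_h
    m[:, 0, 3] = 1j * pj
    m[:, 1, 1] = -r2_mq
    m[:, 1, 2] = -wc
    m[:, 2, 1] = wc
    m[:, 2, 2] = -r2_mq
    m[:, 2, 3] = -w1
    m[:, 3, 0] = 1j * pj
    m[:, 3, 2] = w1
    m[:, 3, 3] = -r2_aph
    return m


def _plus_fids(
    omega_h: np.ndarray,
    omega_c: np.ndarray,
    b1: np.ndarray,
    j_hc: np.ndarray,
    r2_h: np.ndarray,
    r2_mq: np.ndarray,
    r2_aph: np.ndarray,
    i0: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Quadrature FIDs s(t) = <H+>(t) for a batch of spin/decoupler settings.

    s(t) = exp(i 2 pi Omega_H t) * sum_k c_k exp(lambda_k t) with lambda, c
    from the 4x4 plus-block eigendecomposition; evaluated by iterated
    per-dwell multiplication (exact for a time-independent generator).
    """
    m = _plus_block(omega_c, b1, j_hc, r2_h, r2_mq, r2_aph)
    lam, vec = np.linalg.eig(m)
    e0 = np.zeros((m.shape[0], 4), dtype=complex)
    e0[:, 0] = 1.0
    vinv0 = np.linalg.solve(vec, e0[..., None])[..., 0]   # (n, 4) = V^-1 e0
    coef = vec[:, 0, :] * vinv0 * np.asarray(i0, dtype=float)[..., None]
    n_t = times.size
    dt = times[1] - times[0]
    step = np.exp(lam * dt)                               # (n, 4)
    wh_step = np.exp(2j * np.pi * np.atleast_1d(omega_h) * dt)
    out = np.empty((m.shape[0], n_t), dtype=complex)
    cur = coef.copy()
    phase = np.ones(m.shape[0], dtype=complex)
    for k in range(n_t):
        out[:, k] = cur.sum(axis=1) * phase
        cur *= step
        phase *= wh_step
    return out


def _difference_fids(
    spins: Sequence[SpinSystem],
    scheme: AcquisitionScheme,
    b1: float,
    detection: str = "complex_quadrature",
) -> tuple[np.ndarray, np.ndarray]:
    """Decoupled and reference FIDs for one B1 channel.

    Returns ``(fids, ref)`` where ``fids`` is (n_offsets, n_t): the sum over
    spins of the decoupled FIDs, and ``ref`` is (n_t,): the sum over spins of
    the reference FIDs (decoupler off, or far off-resonance, per the scheme).
    """
    offsets = scheme.offsets_c
    times = scheme.time_grid()
    n_off = offsets.size
    n_spin = len(spins)
    wh = np.array([scheme.omega_h(s.wh) for s in spins])
    j = np.array([s.j_hc for s in spins])
    r2h = np.array([s.r2_h for s in spins])
    r2mq = np.array([s.r2_mq for s in spins])
    r2aph = np.array([s.r2_aph for s in spins])
    i0 = np.array([s.i0 for s in spins])
    wc_ppm = np.array([s.wc for s in spins])

    # decoupled: every (spin, offset) pair
    om_c = (wc_ppm[:, None] - offsets[None, :]) * scheme.f_c  # (n_spin, n_off)
    rep = lambda a: np.repeat(a, n_off)
    fids = _plus_fids(
        rep(wh), om_c.ravel(), b1, rep(j), rep(r2h), rep(r2mq), rep(r2aph),
        rep(i0), times,
    )
    fids = fids.reshape(n_spin, n_off, -1)

    # reference: decoupler off (offset irrelevant) or far off-resonance
    if scheme.reference_mode == "b1_zero":
        ref_b1, ref_off = 0.0, 0.0
    else:
        ref_b1, ref_off = b1, scheme.reference_offset_ppm
    om_c_ref = (wc_ppm - ref_off) * scheme.f_c
    ref = _plus_fids(wh, om_c_ref, ref_b1, j, r2h, r2mq, r2aph, i0, times)

    if detection == "literal_D":
        # Hx - Hy from the quadrature signal
        fids = fids.real - fids.imag
        ref = ref.real - ref.imag
    elif detection != "complex_quadrature":
        raise ValueError(f"unknown detection mode {detection!r}")
    return fids.sum(axis=0), ref.sum(axis=0)


def simulate_fid_series(
    spins: Sequence[SpinSystem],
    scheme: AcquisitionScheme,
    b1: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw time-domain series for one B1: per-offset FIDs and the reference FID."""
    if len(spins) == 0:
        raise ValueError("need at least one spin system")
    return _difference_fids(spins, scheme, b1)


def simulate_offres_dataset(
    spins: Sequence[SpinSystem],
    scheme: AcquisitionScheme,
    apodize: bool = True,
    phase: float = 0.0,
    normalize: bool = False,
) -> OffResonanceDataset:
    """Simulate the difference off-resonance stack for a list of spin pairs.

    For every (offset, B1) pair the difference FID (decoupled minus
    reference) is processed into a spectrum; the real parts are stacked into
    an (n_zf, n_offsets, n_b1) array.  Superposition over spins holds exactly
    before normalization.
    """
    if len(spins) == 0:
        raise ValueError("need at least one spin system")
    n_off = scheme.offsets_c.size
    stack = np.empty((scheme.n_zf, n_off, len(scheme.b1_list)))
    for k, b1 in enumerate(scheme.b1_list):
        fids, ref = _difference_fids(spins, scheme, b1)
        diff = fids - ref[None, :]
        spec = _process_fids(diff, scheme, apodize=apodize, phase=phase)
        stack[:, :, k] = spec.real.T
    ds = OffResonanceDataset(
        data=stack,
        h_axis_ppm=scheme.h_axis_ppm(),
        offsets_ppm=scheme.offsets_c.copy(),
        b1_list=scheme.b1_list,
        normalized=False,
        scale=1.0,
        meta={"kind": "synthetic", "scheme_hash": scheme.content_hash()},
    )
    return ds.normalize() if normalize else ds


# ---- closed-form oracles ----------------------------------------------------


def effective_splitting(j_hc: float, b1: float, delta: float) -> float:
    """Effective 1H doublet splitting under off-resonance CW decoupling.

    ``J * |delta| / sqrt(delta**2 + b1**2)`` with ``delta = nuC - nuRF`` in
    Hz.  Collapses to 0 on resonance and approaches J far off resonance; a
    good oracle whenever ``b1`` is large compared to J/2.
    """
    if b1 <= 0:
        raise ValueError("b1 must be > 0")
    return j_hc * abs(delta) / math.hypot(delta, b1)


def limiting_rate_oracle(spin: SpinSystem, b1: float) -> dict:
    """Limiting lineshape parameters of the decoupled 1H signal.

    Far off resonance each doublet component has linewidth ~R2H/pi (Hz);
    exactly on resonance the collapsed singlet decays at
    ``R2H - (R2H - R2MQ) / (1 + (2 B1 / J)**2)`` (s^-1).
    """
    far_linewidth = spin.r2_h / math.pi
    onres_rate = spin.r2_h - (spin.r2_h - spin.r2_mq) / (
        1.0 + (2.0 * b1 / spin.j_hc) ** 2
    )
    return {"far_linewidth": far_linewidth, "onres_rate": onres_rate}
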