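"""Spin-pair simulator: structure, closed forms and spectral oracles."""

import numpy as np
import pytest

from singlepulse import (
    AcquisitionScheme,
    SpinSystem,
    build_liouvillian,
    effective_splitting,
    limiting_rate_oracle,
    propagate_fid,
    simulate_offres_dataset,
    synthesize_spectrum,
)
from singlepulse.sim import _plus_fids

SQ_IDX = (0, 1, 6, 7)   # Hx, Hy, 2HxCz, 2HyCz
MQ_IDX = (2, 3, 4, 5)


def local_maxima(y, frac=0.5):
    m = y.max()
    return [
        i for i in range(1, len(y) - 1)
        if y[i] > frac * m and y[i] >= y[i - 1] and y[i] > y[i + 1]
    ]


def doublet_separation(spin, b1, nu_rf, scheme, apodize=False):
    """Separation of the two strongest maxima, parabolic sub-bin refined."""
    l8 = build_liouvillian(spin, b1, nu_rf, scheme)
    fid = propagate_fid(l8, scheme.time_grid())
    sp = synthesize_spectrum(fid, scheme, apodize=apodize)
    y = sp.data.real
    idx = local_maxima(y)
    if len(idx) < 2:
        return 0.0, len(idx)
    df = sp.axis_hz[1] - sp.axis_hz[0]

    def refine(i):
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        return sp.axis_hz[i] + (0.0 if denom == 0 else
                                (y[i - 1] - y[i + 1]) / (2 * denom) * df)

    return refine(idx[-1]) - refine(idx[0]), len(idx)


class TestLiouvillian:
    def test_b1_zero_block_decouples(self, small_scheme, one_spin):
        l8 = build_liouvillian(one_spin, 0.0, 5.0, small_scheme)
        for i in SQ_IDX:
            for j in MQ_IDX:
                assert l8.matrix[i, j] == 0.0
                assert l8.matrix[j, i] == 0.0

    def test_eigenvalues_never_grow(self, small_scheme):
        rng = np.random.default_rng(7)
        for _ in range(20):
            spin = SpinSystem(
                wh=rng.uniform(-0.5, 1.5), wc=rng.uniform(0, 26),
                j_hc=rng.uniform(120, 130), r2_h=rng.uniform(0, 100),
                r2_mq=rng.uniform(0, 100), r2_aph=rng.uniform(0, 150),
                i0=rng.uniform(0.1, 1.0),
            )
            l8 = build_liouvillian(spin, rng.uniform(0, 300),
                                   rng.uniform(-5, 30), small_scheme)
            assert np.linalg.eigvals(l8.matrix).real.min() > -1e-9

    def test_free_precession_oscillation(self, small_scheme):
        # rates 0, J -> 0, B1 = 0: pure undamped oscillation at Omega_H
        spin = SpinSystem(wh=small_scheme.carrier_h + 100 / small_scheme.f_h,
                          wc=13.0, j_hc=1e-9, r2_h=0, r2_mq=0, r2_aph=0)
        l8 = build_liouvillian(spin, 0.0, 13.0, small_scheme)
        t = small_scheme.time_grid()
        fid = propagate_fid(l8, t)
        assert np.allclose(np.abs(fid), 1.0, atol=1e-8)
        assert np.allclose(fid, np.exp(2j * np.pi * 100 * t), atol=1e-6)

    def test_equal_rates_slowest_detectable_mode(self, small_scheme):
        spin = SpinSystem(wh=0.5, wc=13.0, j_hc=125.0, r2_h=25.0,
                          r2_mq=25.0, r2_aph=25.0)
        l8 = build_liouvillian(spin, 110.0, 13.0, small_scheme)
        rates = np.linalg.eigvals(l8.matrix).real
        assert np.min(rates) == pytest.approx(25.0, rel=1e-9)

    def test_rejects_nonfinite(self, small_scheme, one_spin):
        with pytest.raises(ValueError, match="nu_rf"):
            build_liouvillian(one_spin, 110.0, float("nan"), small_scheme)
        with pytest.raises(ValueError, match="wh"):
            SpinSystem(wh=float("inf"), wc=13.0)


class TestPropagation:
    def test_pure_exponential_closed_form(self, small_scheme):
        spin = SpinSystem(wh=small_scheme.carrier_h, wc=13.0, j_hc=1e-9,
                          r2_h=25.0, r2_mq=0, r2_aph=0)
        l8 = build_liouvillian(spin, 0.0, 13.0, small_scheme)
        t = small_scheme.time_grid()
        fid = propagate_fid(l8, t)
        assert fid[0] == pytest.approx(1.0)
        assert np.allclose(fid, np.exp(-25.0 * t), atol=1e-9)
        assert abs(fid[-1]) == pytest.approx(np.exp(-25.0 * 0.064), rel=1e-6)

    def test_linearity_in_i0(self, small_scheme, one_spin):
        t = small_scheme.time_grid()
        f1 = propagate_fid(
            build_liouvillian(one_spin, 110.0, 10.0, small_scheme), t
        )
        spin2 = SpinSystem(**{**one_spin.to_dict(), "i0": 2.0})
        f2 = propagate_fid(
            build_liouvillian(spin2, 110.0, 10.0, small_scheme), t
        )
        assert np.allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_coupled_reference_doublet(self, small_scheme, one_spin):
        # B1 = 0: 1H doublet separated by 1J(HC)
        sch = AcquisitionScheme(n_zf=16384)
        sep, n = doublet_separation(one_spin, 0.0, 0.0, sch)
        assert n == 2
        assert sep == pytest.approx(125.0, abs=1.0)

    def test_decay_bound_equal_rates(self, small_scheme, one_spin):
        l8 = build_liouvillian(one_spin, 110.0, 13.0, small_scheme)
        fid = propagate_fid(l8, small_scheme.time_grid())
        assert np.all(np.abs(fid) <= np.abs(fid[0]) + 1e-12)

    def test_rejects_nonuniform_grid(self, small_scheme, one_spin):
        l8 = build_liouvillian(one_spin, 110.0, 13.0, small_scheme)
        with pytest.raises(ValueError, match="uniform"):
            propagate_fid(l8, np.array([0.0, 0.001, 0.003]))

    def test_literal_detection_mode(self, small_scheme, one_spin):
        l8 = build_liouvillian(one_spin, 110.0, 10.0, small_scheme)
        t = small_scheme.time_grid()
        q = propagate_fid(l8, t, detection="complex_quadrature")
        d = propagate_fid(l8, t, detection="literal_D")
        assert np.allclose(np.asarray(d).imag, 0.0, atol=1e-12)
        assert np.allclose(np.real(d), q.real - q.imag, atol=1e-9)

    def test_plus_block_matches_full_liouvillian(self, small_scheme):
        """The 4x4 complex reduction reproduces the 8x8 real propagation."""
        rng = np.random.default_rng(11)
        t = small_scheme.time_grid()
        for _ in range(5):
            spin = SpinSystem(
                wh=rng.uniform(-0.5, 1.5), wc=rng.uniform(0, 26),
                j_hc=rng.uniform(120, 130), r2_h=rng.uniform(1, 100),
                r2_mq=rng.uniform(1, 100), r2_aph=rng.uniform(1, 150),
                i0=rng.uniform(0.1, 1.0),
            )
            b1 = rng.uniform(50, 300)
            nu = rng.uniform(-5, 30)
            f8 = propagate_fid(build_liouvillian(spin, b1, nu, small_scheme), t)
            f4 = _plus_fids(
                small_scheme.omega_h(spin.wh),
                small_scheme.omega_c(spin.wc, nu),
                b1, spin.j_hc, spin.r2_h, spin.r2_mq, spin.r2_aph,
                spin.i0, t,
            )[0]
            assert np.allclose(f8, f4, atol=1e-9)


class TestSpectrum:
    def test_zero_fid_zero_spectrum(self, small_scheme):
        fid = np.zeros(small_scheme.n_points, dtype=complex)
        sp = synthesize_spectrum(fid, small_scheme)
        assert np.all(sp.data == 0)
        assert len(sp.axis_ppm) == small_scheme.n_zf

    def test_impulse_flat_magnitude(self, small_scheme):
        fid = np.zeros(small_scheme.n_points, dtype=complex)
        fid[0] = 1.0
        sp = synthesize_spectrum(fid, small_scheme, apodize=False)
        mag = np.abs(sp.data)
        assert np.allclose(mag, mag[0], rtol=1e-9)

    def test_lorentzian_linewidth(self):
        # long acquisition so truncation cannot broaden the line
        sch = AcquisitionScheme(t_max=1.0, n_zf=65536)
        t = sch.time_grid()
        fid = np.exp(-25.0 * t).astype(complex)
        sp = synthesize_spectrum(fid, sch, apodize=False)
        y = sp.data.real
        m = int(np.argmax(y))
        half = y[m] / 2
        left = np.interp(half, y[: m + 1], sp.axis_hz[: m + 1])
        right = np.interp(half, y[m:][::-1], sp.axis_hz[m:][::-1])
        assert right - left == pytest.approx(25.0 / np.pi, rel=0.01)

    def test_rejects_wrong_length(self, small_scheme):
        with pytest.raises(ValueError, match="acquired points"):
            synthesize_spectrum(np.zeros(10, dtype=complex), small_scheme)


class TestOffResonanceDataset:
    def test_superposition(self, small_scheme):
        a = [SpinSystem(wh=0.3, wc=10.0)]
        b = [SpinSystem(wh=0.9, wc=20.0, r2_h=40.0)]
        ds_a = simulate_offres_dataset(a, small_scheme)
        ds_b = simulate_offres_dataset(b, small_scheme)
        ds_ab = simulate_offres_dataset(a + b, small_scheme)
        assert np.allclose(ds_ab.data, ds_a.data + ds_b.data, atol=1e-10)

    def test_x_pattern_centered_on_shifts(self, small_scheme, one_spin):
        ds = simulate_offres_dataset([one_spin], small_scheme)
        h_i, c_i, _ = np.unravel_index(np.argmax(ds.data), ds.data.shape)
        assert abs(ds.h_axis_ppm[h_i] - one_spin.wh) < 0.02
        assert abs(ds.offsets_ppm[c_i] - one_spin.wc) < 1.6  # one offset step

    def test_reference_subtraction_removes_far_streaks(self, one_spin):
        # at |nuC - nuRF| > 20 B1 the difference column is < 2% of the max
        b1 = 110.0
        scheme = AcquisitionScheme(
            n_zf=512,
            b1_list=(b1,),
            offsets_c=np.linspace(-2.0, 28.0, 41),
        )
        ds = simulate_offres_dataset([one_spin], scheme)
        f_c = scheme.f_c
        far = np.abs(scheme.offsets_c - one_spin.wc) * f_c > 20 * b1
        assert far.any()
        far_max = np.abs(ds.data[:, far, :]).max()
        assert far_max < 0.02 * np.abs(ds.data).max()

    def test_reference_is_offset_independent(self, small_scheme, one_spin):
        t = small_scheme.time_grid()
        refs = [
            propagate_fid(build_liouvillian(one_spin, 0.0, nu, small_scheme), t)
            for nu in (-50.0, 0.0, 13.0, 30.0)
        ]
        for r in refs[1:]:
            assert np.allclose(r, refs[0], atol=1e-12)

    def test_empty_spin_list_rejected(self, small_scheme):
        with pytest.raises(ValueError, match="at least one spin"):
            simulate_offres_dataset([], small_scheme)

    def test_normalization_flag(self, small_scheme, one_spin):
        ds = simulate_offres_dataset([one_spin], small_scheme, normalize=True)
        assert ds.normalized
        assert np.max(np.abs(ds.data)) == pytest.approx(1.0)
        assert ds.scale > 0


class TestOracles:
    @pytest.mark.parametrize("b1", [110.0, 220.0])
    @pytest.mark.parametrize("delta", [-800.0, -400.0, -200.0, 200.0, 400.0, 800.0])
    def test_splitting_matches_formula(self, b1, delta, one_spin):
        """Simulated separations track the effective-splitting closed form
        within one digital resolution element."""
        sch = AcquisitionScheme(n_zf=2048)
        resolution = sch.sw_h_hz / sch.n_zf
        predicted = effective_splitting(one_spin.j_hc, b1, delta)
        if predicted < 2 * resolution:
            pytest.skip("splitting below two resolution elements")
        nu_rf = one_spin.wc - delta / sch.f_c
        sep, n = doublet_separation(one_spin, b1, nu_rf, sch)
        assert n == 2
        assert abs(sep - predicted) < resolution

    def test_splitting_limits(self):
        assert effective_splitting(125.0, 110.0, 0.0) == 0.0
        assert effective_splitting(125.0, 110.0, 8800.0) == pytest.approx(
            125.0, abs=0.02
        )
        assert effective_splitting(125.0, 110.0, 110.0) == pytest.approx(
            125.0 / np.sqrt(2.0), rel=1e-12
        )

    def test_limiting_rates(self):
        spin = SpinSystem(wh=0.5, wc=13.0, j_hc=125.0, r2_h=25.0,
                          r2_mq=25.0, r2_aph=25.0)
        out = limiting_rate_oracle(spin, 110.0)
        assert out["far_linewidth"] == pytest.approx(25.0 / np.pi, rel=1e-12)
        assert out["onres_rate"] == pytest.approx(25.0)  # R2H == R2MQ
        spin2 = SpinSystem(wh=0.5, wc=13.0, j_hc=125.0, r2_h=40.0,
                           r2_mq=20.0, r2_aph=25.0)
        out2 = limiting_rate_oracle(spin2, 220.0)
        expected = 40.0 - (40.0 - 20.0) / (1.0 + (2 * 220.0 / 125.0) ** 2)
        assert out2["onres_rate"] == pytest.approx(expected, rel=1e-12)
        assert out2["onres_rate"] == pytest.approx(38.51, abs=0.02)
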