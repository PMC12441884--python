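"""Forward signal models: GPA sphere physics, composite models, exchange."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import spherical_jn

from mrcyt import (
    GAMMA,
    MicrostructureParams,
    build_ogse_cosine,
    build_pgse,
    cellularity,
    exchange_signal,
    hindered_signal,
    impulsed_signal,
    scale_to_b,
    sphere_eigenmodes,
    sphere_gpa_log_attenuation,
)
from mrcyt.errors import DegenerateBalanceError


def bisect_first_mode():
    """Independent bisection for the first root of j1'(alpha) = 0 in (1, 3)."""
    lo, hi = 1.0, 3.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if spherical_jn(1, lo, derivative=True) * spherical_jn(1, mid, derivative=True) < 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestEigenmodes:
    def test_first_root(self):
        em = sphere_eigenmodes(1, radius=5.0)
        assert em.alphas[0] == pytest.approx(bisect_first_mode(), abs=1e-10)
        assert em.alphas[0] == pytest.approx(2.0816, abs=1e-4)

    def test_roots_increasing_weights_positive(self):
        em = sphere_eigenmodes(20, radius=7.5)
        assert np.all(np.diff(em.alphas) > 0)
        assert np.all(em.weights > 0)
        assert np.all(np.diff(em.weights) < 0)  # strictly decreasing

    def test_weights_scale_with_radius_squared(self):
        w1 = sphere_eigenmodes(5, radius=4.0).weights
        w2 = sphere_eigenmodes(5, radius=8.0).weights
        np.testing.assert_allclose(w2, 4 * w1, rtol=1e-12)

    def test_weight_sum_is_position_variance(self):
        # sum B_n = R^2 / 5, the equilibrium variance along one axis
        em = sphere_eigenmodes(60, radius=7.5)
        assert em.weights.sum() == pytest.approx(7.5**2 / 5, rel=1e-4)


class TestSphereGPA:
    def test_zero_amplitude_gives_zero_attenuation(self):
        w = build_pgse(delta=12, Delta=74, amplitude=0)
        assert sphere_gpa_log_attenuation(15, 1.56, w) == 0.0

    def test_tiny_cell_motional_narrowing(self, protocol):
        for _, wf, b in protocol.scaled_acquisitions():
            if b > 0:
                assert abs(sphere_gpa_log_attenuation(0.1, 1.56, wf)) < 1e-3

    def test_matches_two_lobe_closed_form(self):
        """Murday-Cotts-type closed form for rectangular PGSE lobes."""
        delta, Delta = 12.0, 74.0
        w = scale_to_b(build_pgse(delta=delta, Delta=Delta, amplitude=40), 1.0)
        g = w.amplitude
        for d in (8.0, 15.0, 22.0):
            R = d / 2
            em = sphere_eigenmodes(40, R)
            kap = 1.56 * (em.alphas / R) ** 2
            # exp(-k Delta)(cosh(k delta)-1), written overflow-safe
            cross = (np.exp(-kap * (Delta - delta)) + np.exp(-kap * (Delta + delta))) / 2 \
                - np.exp(-kap * Delta)
            ln_cf = -(GAMMA**2) * g**2 * np.sum(
                em.weights / kap**2
                * 2 * (kap * delta - 1 + np.exp(-kap * delta) - cross)
            )
            ln_num = sphere_gpa_log_attenuation(d, 1.56, w, n_modes=40)
            assert ln_num == pytest.approx(ln_cf, rel=1e-6)
            assert ln_num < 0

    def test_matches_direct_double_sum(self):
        """Independent O(T^2) quadrature of the GPA double integral (OGSE)."""
        w = scale_to_b(build_ogse_cosine(50, 2, 60, dt=0.05), 0.5)
        d, D_in = 13.0, 1.56
        R = d / 2
        em = sphere_eigenmodes(20, R)
        kap = D_in * (em.alphas / R) ** 2
        g, dt = w.samples, w.dt
        t = (np.arange(g.size) + 0.5) * dt
        total = 0.0
        for k, B in zip(kap, em.weights):
            ker = np.exp(-k * np.abs(t[:, None] - t[None, :]))
            total += B * 0.5 * (g @ ker @ g) * dt * dt
        ln_cf = -(GAMMA**2) * total
        ln_num = sphere_gpa_log_attenuation(d, D_in, w)
        assert ln_num == pytest.approx(ln_cf, rel=2e-3)

    def test_high_frequency_limit_tends_to_intrinsic_diffusivity(self):
        """Apparent intracellular diffusivity from cosine OGSE approaches D_in
        as the frequency grows (surface correction decays like 1/sqrt(f))."""
        d, D_in, b = 10.0, 1.56, 0.05
        errs = []
        for f, n in ((100, 4), (500, 20), (3000, 120)):
            w = scale_to_b(
                build_ogse_cosine(f, n, 60, dt=min(0.002, 5.0 / f), g_max=np.inf), b
            )
            adc = -sphere_gpa_log_attenuation(d, D_in, w, n_modes=60) / b
            errs.append(abs(adc - D_in) / D_in)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.05


class TestHinderedSignal:
    def test_values_and_monotonicity(self):
        assert hindered_signal(2.0, 0.0) == 1.0
        assert hindered_signal(2.0, 1.0) == pytest.approx(np.exp(-2), rel=1e-12)
        b = np.linspace(0, 2, 9)
        assert np.all(np.diff(hindered_signal(1.1, b)) < 0)


class TestImpulsed:
    def test_v_in_zero_reduces_to_hindered(self, protocol):
        p = MicrostructureParams(d=12, v_in=0.0, D_ex=2.0, D_in=1.56)
        S = impulsed_signal(p, protocol)
        np.testing.assert_allclose(S, np.exp(-protocol.b_values * 2.0), rtol=1e-9)

    def test_tiny_cells_fully_intracellular_no_attenuation(self, protocol):
        p = MicrostructureParams(d=0.1, v_in=1.0, D_ex=2.0, D_in=1.56)
        np.testing.assert_allclose(impulsed_signal(p, protocol), 1.0, atol=1e-3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        d=st.floats(6, 25),
        v_in=st.floats(0.05, 0.95),
        D_ex=st.floats(0.5, 3.0),
        D_in=st.floats(0.8, 2.8),
    )
    def test_normalized_and_monotone_in_b(self, d, v_in, D_ex, D_in, protocol):
        p = MicrostructureParams(d=d, v_in=v_in, D_ex=D_ex, D_in=D_in)
        S = impulsed_signal(p, protocol)
        bvals = protocol.b_values
        for idx in protocol.sequence_groups().values():
            s, b = S[idx], bvals[idx]
            order = np.argsort(b)
            assert s[order][0] == pytest.approx(1.0, abs=1e-12)  # b = 0
            assert np.all(np.diff(s[order]) < 0)


class TestExchange:
    def test_reduces_to_impulsed_at_zero_exchange(self, protocol, rng):
        for _ in range(10):
            p = MicrostructureParams(
                d=rng.uniform(6, 25), v_in=rng.uniform(0.05, 0.95),
                D_ex=rng.uniform(0.5, 3.0), D_in=1.56, k_in=0.0,
            )
            np.testing.assert_allclose(
                exchange_signal(p, protocol), impulsed_signal(p, protocol),
                atol=1e-6,
            )

    def test_v_in_zero_is_pure_hindered(self, protocol):
        p = MicrostructureParams(d=12, v_in=0.0, D_ex=2.3, k_in=10.0)
        np.testing.assert_allclose(
            exchange_signal(p, protocol), np.exp(-protocol.b_values * 2.3),
            rtol=1e-9,
        )

    def test_matches_scipy_matrix_exponential(self, protocol):
        """Independent propagation with scipy.linalg.expm, step by step."""
        from mrcyt._kernels import gpa_step_sums
        from mrcyt.forward_models import _mode_kappas, _protocol_arrays

        proto = protocol.resampled(0.1)
        p = MicrostructureParams(d=14, v_in=0.58, D_ex=2.3, D_in=1.56, k_in=8.0)
        S = exchange_signal(p, proto)
        arrays = _protocol_arrays(proto)
        ki = 8.0e-3
        ko = ki * 0.58 / (1 - 0.58)
        for acq_index in (4, 11):  # strongest PGSE and OGSE-50 acquisitions
            i, amp2, _ = arrays.acqs[acq_index]
            wf = arrays.waveforms[i]
            kap, wt = _mode_kappas(14, 1.56, 20)
            r_in = amp2 * GAMMA**2 * gpa_step_sums(wf.g_unit, wf.dt, kap, wt) / wf.dt
            r_ex = amp2 * 2.3 * wf.q2_unit
            M = np.array([0.58, 0.42])
            for t in range(r_in.size):
                A = np.array([[-r_in[t] - ki, ko], [ki, -r_ex[t] - ko]])
                M = scipy.linalg.expm(A * wf.dt) @ M
            assert S[acq_index] == pytest.approx(float(M.sum()), abs=1e-5)

    def test_exchange_raises_attenuation_of_restricted_pool(self, protocol):
        """With exchange on, intracellular water samples the faster
        extracellular environment, so high-b signal drops less slowly than
        the hindered pool but the composite differs from the impermeable case."""
        base = MicrostructureParams(d=14, v_in=0.58, D_ex=2.3, D_in=1.56, k_in=0.0)
        fast = MicrostructureParams(d=14, v_in=0.58, D_ex=2.3, D_in=1.56, k_in=20.0)
        S0 = exchange_signal(base, protocol)
        S1 = exchange_signal(fast, protocol)
        b = protocol.b_values
        assert not np.allclose(S0[b > 0], S1[b > 0], atol=1e-4)

    def test_degenerate_balance_rejected(self, protocol):
        p = MicrostructureParams(d=14, v_in=1.0, D_ex=2.3, k_in=5.0)
        with pytest.raises(DegenerateBalanceError):
            exchange_signal(p, protocol)

    def test_variants_share_engine(self, protocol):
        p = MicrostructureParams(d=14, v_in=0.5, D_ex=2.3, k_in=8.0)
        np.testing.assert_array_equal(
            exchange_signal(p, protocol, variant="JOINT"),
            exchange_signal(p, protocol, variant="EXCHANGE"),
        )


class TestCellularity:
    def test_zero_volume_fraction(self):
        assert cellularity(0.0, 10.0) == 0.0

    def test_printed_formula_value(self):
        # 2 (3 v_in / (2 pi) * 100)^(2/3) / d^2 at v_in=0.38, d=15
        assert cellularity(0.38, 15.0) == pytest.approx(0.06138, abs=2e-5)

    def test_scaling_in_d_and_monotonicity(self):
        assert cellularity(0.4, 20.0) == pytest.approx(cellularity(0.4, 10.0) / 4)
        assert cellularity(0.6, 12.0) > cellularity(0.4, 12.0)

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            cellularity(0.4, 0.0)
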