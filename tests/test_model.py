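"""Closed-form signal model against its ODE oracle and basic physics."""

import numpy as np
import pytest

from ceasl import PhysioParams, delta_M, dM_dkb, ode_delta_M

from conftest import random_phys


class TestDeltaM:
    def test_zero_before_transit(self, phys, acq):
        assert delta_M(0.5, phys.with_(t_A=1.2), acq) == 0.0

    def test_zero_without_labelling(self, phys):
        from ceasl.model import signal

        t = np.linspace(0.1, 6, 50)
        out = signal(t, phys.f, phys.t_A, phys.k_b, phys.T1_b, phys.T1_e,
                     alpha=0.0)
        assert np.all(out == 0.0)

    def test_linear_in_f_alpha_m0(self, phys, acq):
        t = np.linspace(0.1, 6, 37)
        base = delta_M(t, phys, acq)
        assert np.array_equal(delta_M(t, phys.with_(f=120), acq), 2 * base)
        np.testing.assert_allclose(
            delta_M(t, phys, acq.with_(alpha=0.425)), base / 2, rtol=1e-15)
        np.testing.assert_allclose(
            delta_M(t, phys, acq.with_(M0=3.0)), 3 * base, rtol=1e-15)

    def test_continuity_at_branch_boundaries(self, rng, acq):
        eps = 1e-9
        for _ in range(200):
            p = random_phys(rng)
            for t0 in (p.t_A, p.t_A + acq.t_L):
                lo = delta_M(t0 - eps, p, acq)
                hi = delta_M(t0 + eps, p, acq)
                scale = max(abs(delta_M(t0 + 0.3, p, acq)), 1e-12)
                assert abs(hi - lo) < 1e-6 * scale

    def test_matches_ode_oracle_at_operating_point(self, phys, acq):
        t = np.linspace(0.05, 6.0, 121)
        cf = delta_M(t, phys, acq)
        ode = ode_delta_M(t, phys, acq)
        assert np.max(np.abs(cf - ode.values)) < 1e-6 * np.max(np.abs(cf))

    def test_oracle_equivalence_over_parameter_space(self, acq):
        # Latin-hypercube style coverage of the simulation ranges
        from scipy.stats import qmc

        sampler = qmc.LatinHypercube(d=5, seed=7)
        lo = np.array([10.0, 0.2, 0.0, 0.2, 0.8])
        hi = np.array([120.0, 2.2, 6.0, 1.65, 1.8])
        draws = qmc.scale(sampler.random(200), lo, hi)
        t = np.linspace(0.1, 6.0, 25)
        for f, t_a, k_b, t1b, t1e in draws:
            p = PhysioParams(f=f, t_A=t_a, k_b=k_b, T1_b=t1b, T1_e=t1e)
            cf = delta_M(t, p, acq)
            ode = ode_delta_M(t, p, acq)
            assert np.max(np.abs(cf - ode.values)) <= 1e-6 * max(
                np.max(np.abs(cf)), 1e-12)

    def test_no_exchange_decouples_tissue(self, phys, acq):
        t = np.linspace(0.1, 6, 40)
        p0 = phys.with_(k_b=0.0)
        a = delta_M(t, p0, acq)
        b = delta_M(t, p0.with_(T1_e=0.9), acq)
        np.testing.assert_array_equal(a, b)
        # and the ODE oracle keeps the extravascular compartment empty:
        # with k_b = 0 the total signal is the pure intravascular solution
        ode = ode_delta_M(t, p0, acq)
        np.testing.assert_allclose(ode.values, a, atol=1e-10 * np.max(a))

    def test_fast_exchange_decays_at_tissue_rate(self, phys, acq):
        # post-bolus log-slope approaches -R1_e for very large k_b
        p = phys.with_(k_b=150.0)
        t = np.array([4.5, 5.5])
        v = delta_M(t, p, acq)
        rate = -np.diff(np.log(v))[0] / np.diff(t)[0]
        assert abs(rate - 1 / p.T1_e) < 0.01 * (1 / p.T1_e)

    def test_degenerate_denominator_is_smooth(self, phys, acq):
        # J = R1_e at k_b = R1_e - R1_b: the closed form divides by zero
        # unless the series branch takes over
        kb_star = 1 / phys.T1_e - 1 / phys.T1_b
        t = np.linspace(0.1, 6, 60)
        v0 = delta_M(t, phys.with_(k_b=kb_star), acq)
        assert np.all(np.isfinite(v0))
        v1 = delta_M(t, phys.with_(k_b=kb_star * (1 + 1e-4)), acq)
        assert np.max(np.abs(v1 - v0)) < 1e-3 * np.max(np.abs(v0))

    def test_rejects_non_finite_input(self, phys, acq):
        with pytest.raises(ValueError):
            delta_M(np.nan, phys, acq)


class TestOdeOracle:
    def test_zero_before_transit(self, phys, acq):
        t = np.linspace(0.05, 1.0, 10)  # all before t_A = 1.2 s
        ode = ode_delta_M(t, phys, acq)
        np.testing.assert_allclose(ode.values, 0.0, atol=1e-14)

    def test_rejects_unsorted_grid(self, phys, acq):
        with pytest.raises(ValueError):
            ode_delta_M([2.0, 1.0], phys, acq)


class TestSensitivityFunction:
    def test_zero_when_compartments_identical(self, phys, acq):
        t = np.linspace(0.1, 6, 50)
        s = dM_dkb(t, phys.with_(T1_e=phys.T1_b), acq)
        np.testing.assert_allclose(s, 0.0, atol=1e-16)

    def test_zero_before_transit(self, phys, acq):
        assert dM_dkb(0.5, phys, acq) == 0.0

    @pytest.mark.parametrize("t1_b", [0.8, 1.65, 0.3])
    def test_matches_finite_differences(self, phys, acq, t1_b):
        t = np.linspace(1.3, 6.0, 48)
        p = phys.with_(T1_b=t1_b)
        h = 1e-5
        fd = (delta_M(t, p.with_(k_b=p.k_b + h), acq)
              - delta_M(t, p.with_(k_b=p.k_b - h), acq)) / (2 * h)
        an = dM_dkb(t, p, acq)
        mask = np.abs(fd) > 1e-10 * np.max(np.abs(fd))
        np.testing.assert_allclose(an[mask], fd[mask], rtol=1e-4)

    def test_sign_with_slow_tissue_relaxation(self, acq):
        # label retained longer in the slower-relaxing compartment: with
        # T1_e > T1_b, pushing water into tissue increases the late signal
        p = PhysioParams(T1_b=0.8, T1_e=1.5)
        t = np.linspace(p.t_A + 0.5, 6.0, 30)
        assert np.all(dM_dkb(t, p, acq) >= 0)

    def test_finite_difference_gate_in_degenerate_region(self, phys, acq):
        kb_star = 1 / phys.T1_e - 1 / phys.T1_b
        t = np.linspace(1.5, 5.0, 20)
        p = phys.with_(k_b=kb_star)
        h = 1e-5
        fd = (delta_M(t, p.with_(k_b=kb_star + h), acq)
              - delta_M(t, p.with_(k_b=max(kb_star - h, 0)), acq)) / (2 * h)
        np.testing.assert_allclose(dM_dkb(t, p, acq), fd, rtol=1e-4)
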