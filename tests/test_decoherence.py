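"""Decoherence corrections: SHXF building blocks, SHEDC, A-FSSH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopdyn.decoherence import (AFSSH, SHXF, DecoherenceParams, StepContext,
                                afssh_collapse, afssh_rate,
                                afssh_step_moments, edc_apply, make_scheme,
                                quantum_momentum, shxf_xi)
from hopdyn.models import adiabatic_point


def normalized(*pops, phases=None):
    c = np.sqrt(np.asarray(pops, dtype=float)).astype(complex)
    if phases is not None:
        c = c * np.exp(1j * np.asarray(phases))
    return c


class TestQuantumMomentum:
    def test_zero_at_coincident_positions(self):
        R = np.array([1.3])
        aux = np.array([[1.3], [1.3]])
        Q = quantum_momentum(R, aux, np.array([0.4, 0.6]), sigma=0.5)
        np.testing.assert_array_equal(Q, [0.0])

    def test_half_half_displacement(self):
        delta = 0.8
        sigma = 0.3
        R = np.array([0.0])
        aux = np.array([[0.0], [-delta]])
        Q = quantum_momentum(R, aux, np.array([0.5, 0.5]), sigma)
        np.testing.assert_allclose(Q, [delta / (4 * sigma ** 2)], rtol=1e-14)

    def test_inverse_square_sigma_scaling(self):
        R = np.array([0.2])
        aux = np.array([[0.0], [0.5]])
        pops = np.array([0.7, 0.3])
        Q1 = quantum_momentum(R, aux, pops, 0.4)
        Q2 = quantum_momentum(R, aux, pops, 0.4 / np.sqrt(2))
        np.testing.assert_allclose(Q2, 2 * Q1, rtol=1e-14)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            quantum_momentum(np.array([0.0]), np.zeros((2, 1)),
                             np.array([0.5, 0.5]), 0.0)


class TestShxfXi:
    masses = np.array([2000.0])

    def test_zero_at_unit_population(self):
        C = normalized(1.0, 0.0)
        lam, xi = shxf_xi(C, np.array([0.7]), np.array([[0.2], [-0.4]]),
                          self.masses)
        np.testing.assert_array_equal(xi, np.zeros(2, dtype=complex))

    def test_zero_for_identical_accumulated_forces(self):
        C = normalized(0.3, 0.7)
        f = np.array([[0.25], [0.25]])
        lam, xi = shxf_xi(C, np.array([1.0]), f, self.masses)
        np.testing.assert_allclose(xi, 0.0, atol=1e-16)

    @given(st.floats(0.01, 0.99), st.floats(-2, 2), st.floats(-2, 2),
           st.floats(-3, 3))
    @settings(max_examples=100, deadline=None)
    def test_norm_neutral(self, p0, f0, f1, q):
        """sum_n d|C_n|^2/dt from the xi term alone vanishes identically."""
        C = normalized(p0, 1 - p0, phases=[0.3, -1.1])
        lam, xi = shxf_xi(C, np.array([q]), np.array([[f0], [f1]]),
                          self.masses)
        ddt_norm = np.sum(2 * lam * np.abs(C) ** 2)
        assert abs(ddt_norm) < 1e-14

    def test_population_flows_toward_aligned_force(self):
        """Population grows on the state whose accumulated force aligns
        with the quantum momentum."""
        C = normalized(0.5, 0.5)
        Q = np.array([1.0])
        f = np.array([[0.5], [-0.5]])      # state 0 aligned with Q
        lam, _ = shxf_xi(C, Q, f, self.masses)
        assert lam[0] > 0 and lam[1] < 0


class TestShxfAux:
    def _ctx(self, model, R, V, C, active):
        ap = adiabatic_point(model, R)
        return StepContext(model=model, masses=model.masses, dt=1.0,
                           R_start=R, V_start=V, R=R, V=V, C=C,
                           active=active, adiab_start=ap, adiab_end=ap)

    def test_no_spawn_below_threshold(self, flat_gap_model):
        scheme = SHXF(DecoherenceParams(scheme="shxf", sigma=0.3),
                      flat_gap_model)
        scheme.setup(1, 2, 1)
        C = normalized(1.0 - 1e-6, 1e-6)[None, :]
        ctx = self._ctx(flat_gap_model, np.zeros((1, 1)),
                        np.full((1, 1), 0.005), C, np.array([0]))
        assert scheme.electronic_rate(ctx) is None
        assert not scheme.alive.any()

    def test_spawn_speed_from_energy_partition(self, flat_gap_model):
        """Hop-down spawn: KE_aux = KE + eps_a - eps_n = 2 KE -> speed x sqrt2."""
        scheme = SHXF(DecoherenceParams(scheme="shxf", sigma=0.3),
                      flat_gap_model)
        scheme.setup(1, 2, 1)
        v = np.sqrt(2 * 0.01 / 2000.0)          # parent KE = 0.01
        C = normalized(0.01, 0.99)[None, :]
        ctx = self._ctx(flat_gap_model, np.zeros((1, 1)),
                        np.full((1, 1), v), C, np.array([1]))
        rate = scheme.electronic_rate(ctx)
        assert scheme.alive[0, 0]
        np.testing.assert_allclose(scheme.aux_V[0, 0, 0], v * np.sqrt(2),
                                   rtol=1e-12)
        assert rate is not None

    def test_forbidden_spawn_freezes(self, flat_gap_model):
        """Hop-up spawn with KE < gap: auxiliary frozen at zero velocity."""
        scheme = SHXF(DecoherenceParams(scheme="shxf", sigma=0.3),
                      flat_gap_model)
        scheme.setup(1, 2, 1)
        v = np.sqrt(2 * 0.005 / 2000.0)         # parent KE = 0.005 < 0.01
        C = normalized(0.99, 0.01)[None, :]
        ctx = self._ctx(flat_gap_model, np.zeros((1, 1)),
                        np.full((1, 1), v), C, np.array([0]))
        scheme.electronic_rate(ctx)
        assert scheme.alive[0, 1]
        assert scheme.aux_V[0, 1, 0] == 0.0
        assert scheme.n_frozen == 1

    def test_aux_position_advances_with_velocity(self, flat_gap_model):
        scheme = SHXF(DecoherenceParams(scheme="shxf", sigma=0.3),
                      flat_gap_model)
        scheme.setup(1, 2, 1)
        v = np.sqrt(2 * 0.01 / 2000.0)
        C = normalized(0.01, 0.99)[None, :]
        ctx = self._ctx(flat_gap_model, np.zeros((1, 1)),
                        np.full((1, 1), v), C, np.array([1]))
        scheme.electronic_rate(ctx)
        v_aux = scheme.aux_V[0, 0, 0]
        ctx2 = self._ctx(flat_gap_model, np.full((1, 1), v), np.full((1, 1), v),
                         C, np.array([1]))
        scheme.electronic_rate(ctx2)
        np.testing.assert_allclose(scheme.aux_R[0, 0, 0], v_aux * 1.0,
                                   rtol=1e-12)


class TestEDC:
    def test_spot_value_tau_20(self):
        """gap = T = alpha = 0.1 Ha -> tau = 20 a.u."""
        C = normalized(0.5, 0.5)
        out = edc_apply(C, active=0, energies=np.array([0.0, 0.1]),
                        T=0.1, alpha=0.1, dt=1.0)
        np.testing.assert_allclose(np.abs(out[1]) / np.abs(C[1]),
                                   np.exp(-1.0 / 20.0), rtol=1e-12)

    def test_alpha_zero_rate_independent_of_T(self):
        C = normalized(0.5, 0.5)
        a = edc_apply(C, 0, np.array([0.0, 0.05]), T=0.02, alpha=0.0, dt=1.0)
        b = edc_apply(C, 0, np.array([0.0, 0.05]), T=0.9, alpha=0.0, dt=1.0)
        np.testing.assert_allclose(np.abs(a[1]), np.abs(b[1]), rtol=1e-12)
        np.testing.assert_allclose(np.abs(a[1]) / np.abs(C[1]),
                                   np.exp(-0.05), rtol=1e-12)

    def test_renormalized_and_phase_preserved(self):
        C = normalized(0.4, 0.6, phases=[0.7, -0.2])
        out = edc_apply(C, 0, np.array([0.0, 0.2]), T=0.05, alpha=0.1, dt=2.0)
        assert abs(np.sum(np.abs(out) ** 2) - 1.0) < 1e-14
        np.testing.assert_allclose(np.angle(out[0]), np.angle(C[0]))

    def test_zero_gap_no_damping(self):
        C = normalized(0.4, 0.6)
        out = edc_apply(C, 0, np.array([0.1, 0.1]), T=0.05, alpha=0.1, dt=5.0)
        np.testing.assert_allclose(out, C)


class TestAFSSHMoments:
    masses = np.array([2000.0])

    def test_parallel_surfaces_keep_zero_moments(self):
        dR = np.zeros((1, 2, 1))
        dP = np.zeros((1, 2, 1))
        z = np.zeros((1, 2, 1))
        for _ in range(100):
            dR, dP = afssh_step_moments(dR, dP, z, z, self.masses, 1.0)
        assert np.all(dR == 0.0) and np.all(dP == 0.0)

    def test_constant_force_kinematics(self):
        dF = np.zeros((1, 2, 1))
        dF[0, 1, 0] = 1e-3
        dR = np.zeros((1, 2, 1))
        dP = np.zeros((1, 2, 1))
        n, dt = 200, 0.5
        for _ in range(n):
            dR, dP = afssh_step_moments(dR, dP, dF, dF, self.masses, dt)
        t = n * dt
        np.testing.assert_allclose(dP[0, 1, 0], 1e-3 * t, rtol=1e-12)
        np.testing.assert_allclose(dR[0, 1, 0],
                                   1e-3 * t ** 2 / (2 * self.masses[0]),
                                   rtol=1e-2)

    def test_sign_flip_linearity(self):
        dF = np.full((1, 2, 1), 2e-3)
        dRp, dPp = afssh_step_moments(np.zeros((1, 2, 1)), np.zeros((1, 2, 1)),
                                      dF, dF, self.masses, 1.0)
        dRm, dPm = afssh_step_moments(np.zeros((1, 2, 1)), np.zeros((1, 2, 1)),
                                      -dF, -dF, self.masses, 1.0)
        np.testing.assert_array_equal(dRm, -dRp)
        np.testing.assert_array_equal(dPm, -dPp)


class TestAFSSHRate:
    def test_zero_moments_no_collapse(self):
        rate, reset = afssh_rate(np.zeros((2, 1)), np.ones((2, 1)),
                                 np.array([0.0, 0.1]), np.ones((2, 1)))
        assert np.all(rate <= 0.0)

    def test_perpendicular_growth_vanishes(self):
        dR = np.array([[1.0, 0.0]])
        dF = np.array([[0.0, 2.0]])
        rate, reset = afssh_rate(dR, dF, np.array([0.0]), np.zeros((1, 2)))
        np.testing.assert_allclose(rate, 0.0, atol=1e-15)
        np.testing.assert_allclose(reset, 0.0, atol=1e-15)

    def test_growth_monotone_in_displacement(self):
        dF = np.array([[1e-3]])
        gap = np.array([0.0])
        d = np.zeros((1, 1))
        rates = [afssh_rate(np.array([[x]]), dF, gap, d)[0][0]
                 for x in (0.1, 0.5, 2.0)]
        assert rates[0] < rates[1] < rates[2]


class TestAFSSHCollapse:
    def test_nonpositive_rate_never_fires(self):
        C = normalized(0.6, 0.4)
        out, collapsed, _ = afssh_collapse(C, 0, np.array([0.0, -5.0]),
                                           np.zeros(2), 1.0,
                                           np.zeros(2), np.ones(2))
        assert not collapsed.any()
        np.testing.assert_array_equal(out, C)

    def test_collapse_restores_unit_active_population(self):
        C = normalized(0.6, 0.4)
        out, collapsed, _ = afssh_collapse(C, 0, np.array([0.0, 10.0]),
                                           np.zeros(2), 1.0,
                                           np.array([1.0, 0.0]), np.ones(2))
        assert collapsed[1]
        assert out[1] == 0.0
        np.testing.assert_allclose(np.abs(out[0]) ** 2, 1.0, rtol=1e-14)

    def test_threshold_rule(self):
        C = normalized(0.7, 0.3)
        rates = np.array([0.0, 0.5])
        fired, _, _ = afssh_collapse(C, 0, rates, np.zeros(2), 1.0,
                                     np.array([1.0, 0.4]), np.ones(2))
        missed, coll, _ = afssh_collapse(C, 0, rates, np.zeros(2), 1.0,
                                         np.array([1.0, 0.6]), np.ones(2))
        assert fired[1] == 0.0
        assert missed[1] != 0.0 and not coll.any()


class TestSchemeContract:
    def test_make_scheme_dispatch(self, flat_gap_model):
        for tag, cls in [("shxf", SHXF), ("edc", type(None)), ]:
            pass
        assert isinstance(make_scheme(None, flat_gap_model).metadata(), dict)
        with pytest.raises(ValueError):
            DecoherenceParams(scheme="bogus")
        with pytest.raises(ValueError):
            DecoherenceParams(scheme="shxf")    # sigma missing

    def test_schemes_differ_per_trajectory(self):
        """The three corrections act differently on identical seeds."""
        from hopdyn.benchmarks import recrossing_config
        from hopdyn.observables import run_from_config
        traces = {}
        for scheme in ("shxf", "edc", "afssh"):
            cfg = recrossing_config(scheme, samples=8, seed=21)
            cfg["dynamics"]["t_max"] = 3000.0
            _, rec, _ = run_from_config(cfg)
            traces[scheme] = rec.pops[:, :, 1]
        assert not np.allclose(traces["shxf"], traces["edc"])
        assert not np.allclose(traces["edc"], traces["afssh"])
        assert not np.allclose(traces["shxf"], traces["afssh"])

    def test_norm_preserved_by_all_schemes(self):
        from hopdyn.benchmarks import single_crossing_config
        from hopdyn.observables import run_from_config
        for scheme in ("shxf", "edc", "afssh"):
            cfg = single_crossing_config(15.0, scheme, samples=12, seed=4)
            cfg["dynamics"]["t_max"] = 2000.0
            _, rec, _ = run_from_config(cfg)
            norms = rec.pops.sum(axis=2)
            assert np.abs(norms - 1.0).max() < 1e-10
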