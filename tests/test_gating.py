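"""Chain gating model: rate laws, generator, equilibrium, propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from herggating.gating import (
    DegenerateSpectrumWarning, GatingScheme, RateLaw, build_scheme1,
    equilibrium_occupancy, generator_matrix, macroscopic_taus, rate_at,
    relax_piecewise,
)
from herggating.params import ModelParams


def two_state(kf=0.005, kb=0.005):
    return GatingScheme(("C", "O"), (RateLaw(kf, 0.0),), (RateLaw(kb, 0.0),),
                        frozenset({"O"}))


def chain_equilibrium_oracle(scheme, v):
    """Detailed-balance product formula, independent of the null-space path."""
    n = scheme.n_states
    weights = [1.0]
    for i in range(n - 1):
        k = scheme.forward[i].rate(v) / scheme.backward[i].rate(v)
        weights.append(weights[-1] * k)
    w = np.array(weights)
    return w / w.sum()


rates = st.floats(1e-4, 10.0, allow_nan=False, allow_infinity=False)
coeffs = st.floats(-0.06, 0.06, allow_nan=False, allow_infinity=False)


def random_chain(draw, n):
    fwd = tuple(RateLaw(draw(rates), draw(coeffs)) for _ in range(n - 1))
    bwd = tuple(RateLaw(draw(rates), draw(coeffs)) for _ in range(n - 1))
    labels = tuple(f"S{i}" for i in range(n))
    return GatingScheme(labels, fwd, bwd, frozenset({labels[-1]}))


class TestRateLaw:
    @pytest.mark.parametrize("prefactor,coeff,v,expected", [
        (1.0, 0.0, -300.0, 1.0),
        (1.0, 0.0, 55.0, 1.0),
        (2.0, 0.0125, 0.0, 2.0),
    ])
    def test_exponential_law(self, prefactor, coeff, v, expected):
        assert rate_at(RateLaw(prefactor, coeff), v) == pytest.approx(expected)

    def test_rate_doubles_every_ln2_over_coeff(self):
        law = RateLaw(0.3, 0.055)
        dv = np.log(2) / 0.055  # ~12.60 mV
        assert dv == pytest.approx(12.603, abs=0.001)
        for v in (-40.0, 0.0, 80.0):
            assert rate_at(law, v + dv) == pytest.approx(2 * rate_at(law, v))

    def test_invalid_rate_laws_rejected(self):
        with pytest.raises(ValueError):
            RateLaw(-1.0, 0.0125)
        with pytest.raises(ValueError):
            RateLaw(0.0, 0.0125)
        with pytest.raises(ValueError):
            RateLaw(1.0, np.inf)


class TestScheme1:
    def test_structure_and_fixed_coefficients(self):
        s = build_scheme1()
        assert s.states == ("C1", "C2", "O")
        assert s.conducting == frozenset({"O"})
        assert [law.voltage_coeff for law in s.forward] == [0.0125, 0.055]
        assert [law.voltage_coeff for law in s.backward] == [-0.025, -0.05]

    def test_unit_prefactors_give_unit_rates_at_0mV(self):
        s = build_scheme1(ModelParams(1.0, 1.0, 1.0, 1.0))
        for law in s.forward + s.backward:
            assert rate_at(law, 0.0) == pytest.approx(1.0)

    def test_negative_prefactor_rejected(self):
        with pytest.raises(ValueError):
            build_scheme1(ModelParams(-0.1, 1.0, 1.0, 1.0))

    def test_chain_invariants_enforced(self):
        with pytest.raises(ValueError):
            GatingScheme(("A",), (), (), frozenset({"A"}))
        with pytest.raises(ValueError):
            GatingScheme(("A", "B"), (RateLaw(1, 0),), (RateLaw(1, 0),),
                         frozenset())
        with pytest.raises(ValueError):
            GatingScheme(("A", "B"), (RateLaw(1, 0),), (RateLaw(1, 0),),
                         frozenset({"X"}))


class TestGenerator:
    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_columns_conserve_occupancy(self, data):
        n = data.draw(st.integers(2, 5))
        scheme = random_chain(data.draw, n)
        v = data.draw(st.floats(-160, 60))
        q = generator_matrix(scheme, v)
        scale = max(1.0, float(np.abs(q).max()))
        assert np.allclose(q.sum(axis=0), 0.0, atol=1e-12 * scale)
        off = q - np.diag(np.diag(q))
        assert np.all(off >= 0)

    def test_two_state_eigenvalues(self):
        q = generator_matrix(two_state(), 0.0)
        w = np.sort(np.linalg.eigvals(q).real)
        assert w == pytest.approx([-0.01, 0.0], abs=1e-14)

    def test_scheme1_off_diagonals_at_0mV_are_prefactors(self):
        p = ModelParams(0.3, 0.07, 0.02, 0.004)
        q = generator_matrix(build_scheme1(p), 0.0)
        assert q[1, 0] == pytest.approx(p.A1_0)
        assert q[0, 1] == pytest.approx(p.B1_0)
        assert q[2, 1] == pytest.approx(p.A2_0)
        assert q[1, 2] == pytest.approx(p.B2_0)


class TestEquilibrium:
    def test_symmetric_rates_give_uniform_occupancy(self):
        p = ModelParams(0.01, 0.01, 0.02, 0.02)
        occ = equilibrium_occupancy(build_scheme1(p), 0.0)
        assert occ == pytest.approx([1 / 3] * 3, abs=1e-12)
        occ2 = equilibrium_occupancy(two_state(), 0.0)
        assert occ2 == pytest.approx([0.5, 0.5], abs=1e-12)

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_nullspace_matches_detailed_balance_product(self, data):
        n = data.draw(st.integers(3, 5))
        scheme = random_chain(data.draw, n)
        v = data.draw(st.floats(-120, 50))
        occ = equilibrium_occupancy(scheme, v)
        oracle = chain_equilibrium_oracle(scheme, v)
        assert occ == pytest.approx(oracle, abs=1e-10)


class TestRelaxation:
    def test_stationary_start_stays_constant(self, wt_params):
        scheme = build_scheme1(wt_params)
        p0 = equilibrium_occupancy(scheme, -20.0)
        _, occ = relax_piecewise(scheme, p0, [(-20.0, 500.0)], dt=5.0)
        assert np.allclose(occ, p0, atol=1e-12)

    def test_two_state_relaxation_time_constant(self):
        scheme = two_state()
        t, occ = relax_piecewise(scheme, np.array([1.0, 0.0]),
                                 [(0.0, 600.0)], dt=1.0)
        expected = 0.5 + 0.5 * np.exp(-t / 100.0)
        assert occ[:, 0] == pytest.approx(expected, abs=1e-12)

    def test_occupancy_conserved_along_protocol(self, wt_params):
        scheme = build_scheme1(wt_params)
        p0 = equilibrium_occupancy(scheme, -90.0)
        _, occ = relax_piecewise(
            scheme, p0, [(-70.0, 100.0), (0.0, 4000.0), (-120.0, 1000.0)],
            dt=1.0)
        assert np.max(np.abs(occ.sum(axis=1) - 1.0)) <= 1e-9
        assert np.all(occ >= 0)

    def test_matches_fine_step_ode_oracle(self, wt_params):
        scheme = build_scheme1(wt_params)
        p0 = equilibrium_occupancy(scheme, -90.0)
        segments = [(20.0, 4000.0), (-70.0, 1000.0)]
        t, occ = relax_piecewise(scheme, p0, segments, dt=50.0)
        # independent oracle: stiff ODE integration segment by segment
        p = p0.copy()
        t0, sol_t, sol_y = 0.0, [0.0], [p0]
        for v, dur in segments:
            q = generator_matrix(scheme, v)
            res = solve_ivp(lambda _, y: q @ y, (0, dur), p,
                            t_eval=np.arange(50.0, dur + 1e-9, 50.0),
                            method="LSODA", rtol=1e-11, atol=1e-13)
            sol_t.extend((t0 + res.t).tolist())
            sol_y.extend(list(res.y.T))
            p = res.y[:, -1]
            t0 += dur
        assert np.allclose(t, sol_t)
        assert np.max(np.abs(occ - np.vstack(sol_y))) <= 1e-6

    def test_invalid_inputs_rejected(self, wt_params):
        scheme = build_scheme1(wt_params)
        p0 = equilibrium_occupancy(scheme, -90.0)
        with pytest.raises(ValueError):
            relax_piecewise(scheme, p0, [(0.0, -5.0)])
        with pytest.raises(ValueError):
            relax_piecewise(scheme, p0, [(np.nan, 10.0)])
        with pytest.raises(ValueError):
            relax_piecewise(scheme, np.array([0.9, 0.0, 0.0]), [(0.0, 10.0)])


class TestMacroscopicTaus:
    def test_two_state_single_tau(self):
        assert macroscopic_taus(two_state(), 0.0) == pytest.approx([100.0])

    def test_scheme1_has_two_positive_taus(self, wt_params):
        taus = macroscopic_taus(build_scheme1(wt_params), 0.0)
        assert taus.shape == (2,)
        assert np.all(taus > 0)
        assert taus[0] < taus[1]

    def test_noiseless_relaxation_fit_recovers_eigen_taus(self, wt_params):
        from herggating.fitting import fit_exponential
        scheme = build_scheme1(wt_params)
        p0 = equilibrium_occupancy(scheme, -90.0)
        t, occ = relax_piecewise(scheme, p0, [(20.0, 1500.0)], dt=1.0)
        p_open = occ @ scheme.conducting_mask().astype(float)
        fit = fit_exponential(t, p_open, 2)
        eigen = macroscopic_taus(scheme, 20.0)
        assert np.array(fit.taus) == pytest.approx(eigen, rel=1e-3)

    def test_degenerate_spectrum_warns(self):
        # a connected chain always has simple eigenvalues (it is similar
        # to a symmetric tridiagonal matrix), but two identical
        # relaxations coupled through a vanishing middle edge are
        # numerically degenerate
        eps = 1e-12
        scheme = GatingScheme(
            ("A", "B", "C", "D"),
            (RateLaw(1.0, 0.0), RateLaw(eps, 0.0), RateLaw(1.0, 0.0)),
            (RateLaw(1.0, 0.0), RateLaw(eps, 0.0), RateLaw(1.0, 0.0)),
            frozenset({"D"}))
        with pytest.warns(DegenerateSpectrumWarning):
            taus = macroscopic_taus(scheme, 0.0)
        assert np.all(taus > 0)

    def test_high_voltage_activation_rate_flattens(self, wt_params):
        """Far above V0.5 the low-sensitivity step becomes rate limiting:
        the local slope of ln(1/tau_slow) vs V falls monotonically towards
        the k1 coefficient."""
        scheme = build_scheme1(wt_params)
        v = np.arange(100.0, 260.0, 20.0)  # V0.5 + ~120 mV and above
        ln_rate = np.array([-np.log(macroscopic_taus(scheme, vi)[-1])
                            for vi in v])
        slopes = np.diff(ln_rate) / np.diff(v)
        assert np.all(np.diff(slopes) < 1e-9)  # monotone flattening
        assert slopes[-1] == pytest.approx(0.0125, rel=0.05)
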