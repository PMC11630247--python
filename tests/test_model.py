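import json

import numpy as np
import pytest
from scipy.linalg import expm

import sysmap as sm
from sysmap.errors import IntegrationError, ValidationError
from sysmap.model import integrate_batch

from conftest import theta_vector


def one_trait_model(theta, domain=(0.0, 2.0), x0=1.0, t1=10.0, order=None):
    order = len(theta) - 1 if order is None else order
    spec = sm.BasisSpec("legendre", order, domain)
    return sm.SystemModel(
        traits=("X",),
        independent={"X": sm.RateFunction(spec, theta)},
        dependent={},
        initial_state=[x0],
        time_domain=(0.0, t1),
    )


def two_trait_constant_coupling(cxy, cyx, domain=(-5.0, 5.0)):
    spec1 = sm.BasisSpec("legendre", 1, domain)
    zero = sm.RateFunction(spec1, [0.0, 0.0])
    return sm.SystemModel(
        traits=("X", "Y"),
        independent={"X": zero, "Y": zero},
        dependent={
            ("X", "Y"): sm.RateFunction(spec1, [cxy, 0.0]),
            ("Y", "X"): sm.RateFunction(spec1, [cyx, 0.0]),
        },
        initial_state=[1.0, 1.0],
        time_domain=(0.0, 100.0),
    )


class TestRateEval:
    def test_zero_coefficients_give_zero_rates(self):
        m = two_trait_constant_coupling(0.0, 0.0)
        assert sm.rate_eval(m, [0.3, -0.7]) == pytest.approx([0.0, 0.0])

    def test_linear_polynomial_identity(self):
        # f(X) = -0.1 X on [0, 1] is theta = [-0.05, -0.05] in Legendre terms
        spec = sm.BasisSpec("legendre", 1, (0.0, 1.0))
        m = sm.SystemModel(
            ("X",), {"X": sm.RateFunction(spec, [-0.05, -0.05])}, {}, [0.5], (0.0, 1.0)
        )
        assert sm.rate_eval(m, [0.5])[0] == pytest.approx(-0.05)

    def test_constant_cross_terms(self):
        m = two_trait_constant_coupling(0.2, -0.3)
        assert sm.rate_eval(m, [1.0, 1.0]) == pytest.approx([0.2, -0.3])

    def test_linearity_in_theta(self):
        rng = np.random.default_rng(5)
        spec = sm.BasisSpec("legendre", 3, (0.0, 2.0))
        t1, t2 = rng.normal(size=4), rng.normal(size=4)
        state = [0.7]

        def rate(theta):
            m = one_trait_model(theta)
            return sm.rate_eval(m, state)[0]

        assert rate(t1) + rate(t2) == pytest.approx(rate(t1 + t2), rel=1e-12)


class TestIntegrate:
    def test_exponential_decay_closed_form(self):
        # f(X) = -0.1 X on [0, 2]: X = u + 1 -> theta = [-0.1, -0.1]
        m = one_trait_model([-0.1, -0.1])
        sol = sm.integrate(m, np.array([10.0]), step=0.01)
        assert abs(sol[0, 0] - np.exp(-1.0)) < 1e-6

    def test_zero_model_stays_at_initial_state(self):
        m = two_trait_constant_coupling(0.0, 0.0)
        sol = sm.integrate(m, np.linspace(1.0, 50.0, 7))
        assert np.array_equal(sol, np.tile([1.0, 1.0], (7, 1)))

    def test_linear_cross_coupling_matches_matrix_exponential(self):
        # dX/dt = -0.1 Y, dY/dt = -0.1 X; with X0 = Y0 = 1 both equal e^{-0.1 t}
        spec1 = sm.BasisSpec("legendre", 1, (-5.0, 5.0))
        zero = sm.RateFunction(spec1, [0.0, 0.0])
        # -0.1 * state on [-5, 5]: state = 5u -> theta = [0, -0.5]
        dep = sm.RateFunction(spec1, [0.0, -0.5])
        m = sm.SystemModel(
            ("X", "Y"), {"X": zero, "Y": zero},
            {("X", "Y"): dep, ("Y", "X"): sm.RateFunction(spec1, [0.0, -0.5])},
            [1.0, 1.0], (0.0, 30.0),
        )
        times = np.linspace(1.0, 20.0, 8)
        sol = sm.integrate(m, times, step=0.01)
        A = np.array([[0.0, -0.1], [-0.1, 0.0]])
        oracle = np.stack([expm(A * t) @ np.ones(2) for t in times])
        assert np.abs(sol - oracle).max() < 1e-6
        assert sol[:, 0] == pytest.approx(np.exp(-0.1 * times), abs=1e-6)

    def test_fast_and_reference_paths_agree(self, baseline):
        import sysmap.model as M

        times = np.arange(0.0, 1440.0, 30.0)
        fast = sm.integrate(baseline, times)
        had = M._HAVE_NUMBA
        M._HAVE_NUMBA = False
        try:
            ref = sm.integrate(baseline, times)
        finally:
            M._HAVE_NUMBA = had
        assert np.abs(fast - ref).max() < 1e-12

    def test_non_finite_state_raises_integration_error(self):
        m = one_trait_model([np.nan, 0.0])
        with pytest.raises(IntegrationError):
            sm.integrate(m, np.array([1.0]))

    def test_times_outside_domain_rejected(self):
        m = one_trait_model([-0.1, -0.1], t1=10.0)
        with pytest.raises(ValidationError):
            sm.integrate(m, np.array([11.0]))


class TestDecompose:
    def test_additivity_is_exact_bitwise(self, baseline):
        times = np.arange(0.0, 6 * 1440.0, 180.0)
        for trait in baseline.traits:
            d = sm.decompose(baseline, times, trait)
            assert np.array_equal(d.net_interactive, d.full - d.independent_only)

    def test_zero_dependent_coefficients_give_zero_net_effect(self):
        m = two_trait_constant_coupling(0.0, 0.0)
        d = sm.decompose(m, np.linspace(1.0, 50.0, 5), "X")
        assert np.all(d.net_interactive == 0.0)
        assert np.array_equal(d.full, d.independent_only)

    def test_negative_drawdown_gives_nonpositive_net_effect_on_soil_water(self, baseline):
        # f_{VWC|TR} < 0 on the whole traversed TR range, so interaction can
        # only remove soil water relative to the isolated-soil trajectory
        times = np.arange(0.0, 6 * 1440.0, 60.0)
        lo, hi = 1.0, 4.0  # traversed TR range
        grid = np.linspace(lo, hi, 101)
        assert np.all(baseline.dependent[("VWC", "TR")](grid) < 0)
        d = sm.decompose(baseline, times, "VWC")
        assert np.all(d.net_interactive <= 1e-12)

    def test_unknown_trait_rejected(self, baseline):
        with pytest.raises(ValidationError):
            sm.decompose(baseline, [0.0, 1.0], "photosynthesis")


class TestInteractionScore:
    @pytest.mark.parametrize(
        "theta,expected_score,expected_label",
        [([0.2, 0.0], 0.2, "cooperation"), ([-0.2, 0.0], -0.2, "competition"),
         ([0.0, 1.0], 0.0, "neutral")],
    )
    def test_constant_and_odd_functions(self, theta, expected_score, expected_label):
        spec1 = sm.BasisSpec("legendre", 1, (-1.0, 1.0))
        zero = sm.RateFunction(spec1, [0.0, 0.0])
        m = sm.SystemModel(
            ("X", "Y"), {"X": zero, "Y": zero},
            {("X", "Y"): sm.RateFunction(spec1, theta),
             ("Y", "X"): zero},
            [0.0, 0.0], (0.0, 1.0),
        )
        score, label = sm.interaction_score(m, ("X", "Y"), (-1.0, 1.0))
        assert score == pytest.approx(expected_score, abs=1e-12)
        assert label == expected_label

    def test_degenerate_range_rejected(self, baseline):
        with pytest.raises(sm.SysmapError):
            sm.interaction_score(baseline, ("TR", "VWC"), (0.3, 0.3))


class TestSerialization:
    def test_json_round_trip_is_lossless(self, baseline):
        doc = baseline.to_json()
        m2 = sm.SystemModel.from_json(doc)
        assert m2.traits == baseline.traits
        assert np.array_equal(theta_vector(m2), theta_vector(baseline))
        assert np.array_equal(m2.initial_state, baseline.initial_state)
        assert m2.time_domain == baseline.time_domain
        # stable under a second round trip
        assert json.loads(m2.to_json()) == json.loads(doc)


class TestContainers:
    def test_vwc_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            sm.TraitTrajectory("s", "g", 1, "VWC", [0.0, 1.0], [0.5, 1.2])

    def test_times_must_increase(self):
        with pytest.raises(ValidationError):
            sm.TraitTrajectory("s", "g", 1, "TR", [0.0, 0.0], [1.0, 1.0])

    def test_samples_must_share_time_grid(self):
        a = sm.TraitTrajectory("s", "g", 1, "TR", [0.0, 3.0], [1.0, 1.0])
        b = sm.TraitTrajectory("s", "g", 1, "VWC", [0.0, 6.0], [0.4, 0.4])
        with pytest.raises(ValidationError):
            sm.TrajectorySet([a, b], ("TR", "VWC"))

    def test_batched_integration_matches_individual(self, baseline):
        m2 = sm.SystemModel(
            baseline.traits, baseline.independent, baseline.dependent,
            [2.5, 0.44], baseline.time_domain,
        )
        times = np.arange(0.0, 2880.0, 60.0)
        batch = integrate_batch([baseline, m2], times)
        assert np.abs(batch[0] - sm.integrate(baseline, times)).max() < 1e-12
        assert np.abs(batch[1] - sm.integrate(m2, times)).max() < 1e-12
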