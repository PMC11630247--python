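import numpy as np
import pytest

import sysmap as sm
from sysmap.basis import anchored_from_theta
from sysmap.covariance import CovarianceModel
from sysmap.errors import SingularDesignError, ValidationError
from sysmap.estimation import (
    FitResult,
    GradientMatcher,
    TrajectoryRefiner,
    collect_curves,
    exact_smoothed_curves,
    gradient_match,
    gradient_match_fit,
    gradient_match_pooled,
    loglik,
)
from sysmap.model import SystemModel
from sysmap.smoothing import SmoothedTrajectory

from conftest import DOMAINS, theta_vector


class TestGradientMatch:
    def test_exact_derivatives_recover_generating_coefficients(self, baseline):
        times = np.arange(0.0, 6 * 1440.0, 3.0)
        smoothed = exact_smoothed_curves(baseline, times)
        fitted = gradient_match_fit(smoothed, baseline.traits, domains=DOMAINS)
        assert np.abs(theta_vector(fitted) - theta_vector(baseline)).max() < 1e-8

    def test_zero_derivatives_give_zero_coefficients(self, baseline):
        times = np.arange(0.0, 6 * 1440.0, 9.0)
        smoothed = exact_smoothed_curves(baseline, times)
        for s in smoothed:
            s.derivs_hat = np.zeros_like(s.derivs_hat)
        fitted = gradient_match_fit(smoothed, baseline.traits, domains=DOMAINS)
        assert np.abs(theta_vector(fitted)).max() < 1e-12

    def test_constant_driver_makes_design_singular_with_named_columns(self):
        # a constant-valued driver trait contributes constant anchored
        # columns, collinear with the independent intercept
        t = np.arange(0.0, 300.0, 3.0)
        smoothed = [
            SmoothedTrajectory("s", "g", 1, "X", t, np.linspace(1, 2, t.size), np.full(t.size, 0.01)),
            SmoothedTrajectory("s", "g", 1, "Y", t, np.full(t.size, 5.0), np.zeros(t.size)),
        ]
        with pytest.raises(SingularDesignError) as exc:
            gradient_match_fit(
                smoothed, ("X", "Y"),
                domains={"X": (0.0, 3.0), "Y": (0.0, 10.0)},
            )
        assert exc.value.columns  # collinear columns are reported by name

    def test_noisy_pipeline_recovers_within_ten_percent(self, baseline):
        cfg = sm.ScenarioConfig(
            diurnal_amplitude=0.0, noise_sd={"TR": 0.15, "VWC": 0.015},
            n_snps=2, seed=42,
        )
        traj, _, _ = sm.simulate_population(cfg)
        m = GradientMatcher(domains=DOMAINS).fit(traj)
        rel = np.linalg.norm(theta_vector(m.model_) - theta_vector(baseline))
        rel /= np.linalg.norm(theta_vector(baseline))
        assert rel < 0.10

    def test_estimator_is_sklearn_compatible(self):
        m = GradientMatcher(indep_order=4)
        assert m.get_params()["indep_order"] == 4
        m.set_params(dep_order=3)
        assert m.dep_order == 3


class TestPooledFit:
    def test_per_line_interaction_coefficients_track_causal_truth(self):
        from sysmap.simulator import CausalEffect, K_RELAX

        eff = -0.2 * 3.25 * K_RELAX
        cfg = sm.ScenarioConfig(
            n_snps=20, seed=3, diurnal_amplitude=0.0,
            noise_sd={"TR": 0.0, "VWC": 0.0},
            causal_snps=[CausalEffect("S0001", ("TR", "VWC"), 0, eff)],
        )
        traj, G, truth = sm.simulate_population(cfg)
        means = sm.genotype_mean_curves(traj)
        smoothed = sm.smooth_trajectories(means)
        curves = collect_curves(smoothed, ("TR", "VWC"))
        pooled = gradient_match_pooled(curves, ("TR", "VWC"), domains=DOMAINS)
        dos = G.codes[:, 0]
        est = np.array([
            pooled["per_line"][g][("dep", "TR", "VWC")][0] for g in pooled["lines"]
        ])
        true = np.array([
            anchored_from_theta(
                SystemModel.from_dict(truth.genotype_models[g]).dependent[("TR", "VWC")].theta,
                SystemModel.from_dict(truth.genotype_models[g]).dependent[("TR", "VWC")].basis,
            )[0]
            for g in pooled["lines"]
        ])
        # dosage classes separate and estimates track the generating values
        assert np.corrcoef(est, true)[0, 1] > 0.99
        spread = true.max() - true.min()
        assert spread > 0
        assert np.abs(est - true).max() < 0.15 * spread

    def test_vary_flag_validation(self):
        with pytest.raises(ValidationError):
            gradient_match_pooled([], ("TR", "VWC"), vary="nothing")


@pytest.fixture(scope="module")
def noiseless_pair():
    cfg = sm.ScenarioConfig(
        n_genotypes=1, n_replicates=1, n_snps=2, seed=9,
        diurnal_amplitude=0.0, noise_sd={"TR": 0.0, "VWC": 0.0},
    )
    traj, _, truth = sm.simulate_population(cfg)
    true_model = SystemModel.from_dict(truth.genotype_models["G01"])
    return traj, true_model


class TestLoglikAndRefinement:
    def test_loglik_closed_form_and_variance_monotonicity(self, noiseless_pair):
        traj, true_model = noiseless_pair
        covs = {t: CovarianceModel("iid", 1e-4) for t in true_model.traits}
        ll = loglik(true_model, traj, covs)
        # residuals are only integrator error (~1e-9), so the closed form
        # for zero residuals applies to 1e-6 relative accuracy
        N = sum(tr.values.size for tr in traj.trajectories)
        assert ll == pytest.approx(-(N / 2) * np.log(2 * np.pi * 1e-4), rel=1e-6)
        covs2 = {t: CovarianceModel("iid", 2e-4) for t in true_model.traits}
        assert loglik(true_model, traj, covs2) < ll

    def test_refinement_never_degrades_and_stays_at_optimum(self, noiseless_pair):
        traj, true_model = noiseless_pair
        r = TrajectoryRefiner(cov_kind="iid", thin_minutes=60.0, maxiter=40)
        r.fit(traj, true_model)
        thin = r._thin(traj)
        ll0 = loglik(true_model, thin, r.result_.covariance)
        assert r.loglik_ >= ll0 - 1e-9
        moved = np.abs(theta_vector(r.model_) - theta_vector(true_model)).max()
        assert moved < 1e-6

    def test_refinement_improves_a_perturbed_warm_start(self, noiseless_pair):
        traj, true_model = noiseless_pair
        bad = SystemModel.from_dict(true_model.to_dict())
        bad.independent["TR"].theta[0] *= 1.2
        r = TrajectoryRefiner(cov_kind="iid", thin_minutes=120.0, maxiter=60)
        r.fit(traj, bad)
        thin = r._thin(traj)
        assert r.loglik_ > loglik(bad, thin, r.result_.covariance) - 1e-9
        # refined fit sits far closer to the data than the perturbed start
        k = list(true_model.traits).index("TR")
        bad_resid = np.sqrt(np.mean(
            (thin.get("G01_R1", "TR").values
             - sm.integrate(bad, thin.get("G01_R1", "TR").times)[:, k]) ** 2
        ))
        assert r.result_.residual_summary["TR"] < 0.25 * bad_resid

    def test_fit_result_requires_more_observations_than_parameters(self, baseline):
        with pytest.raises(ValidationError):
            FitResult(
                model=baseline, loglik=0.0,
                covariance={t: CovarianceModel("iid", 1.0) for t in baseline.traits},
                n_obs=10, residual_summary={},
            )
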