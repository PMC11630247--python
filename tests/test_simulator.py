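import numpy as np
import pytest

import sysmap as sm
from sysmap.errors import ConfigRejectionError, InsufficientSpanError
from sysmap.estimation import exact_smoothed_curves, gradient_match_fit
from sysmap.model import SystemModel
from sysmap.simulator import CausalEffect, K_RELAX, diurnal_factor

from conftest import DOMAINS, theta_vector


class TestSimulatePopulation:
    def test_default_design_dimensions(self, default_sim):
        traj, G, truth = default_sim
        assert len(traj.sample_ids) == 160  # 32 genotypes x 5 replicates
        assert len(traj) == 320  # x 2 traits
        tr = traj.trajectories[0]
        assert tr.times.size == 2880  # 6 days x 24 h x 60 min / 3 min
        assert G.codes.shape == (32, 200)
        assert set(np.unique(G.codes)) <= {0.0, 1.0, 2.0}

    def test_same_seed_reproduces_byte_identically(self):
        cfg = dict(n_genotypes=3, n_replicates=2, days=2, grid_minutes=30.0,
                   n_snps=8, seed=13)
        t1, g1, tr1 = sm.simulate_population(sm.ScenarioConfig(**cfg))
        t2, g2, tr2 = sm.simulate_population(sm.ScenarioConfig(**cfg))
        for a, b in zip(t1.trajectories, t2.trajectories):
            assert np.array_equal(a.values, b.values)
        assert np.array_equal(g1.codes, g2.codes)
        assert tr1.to_json() == tr2.to_json()

    def test_earlier_pots_unchanged_when_replicates_grow(self):
        base = dict(n_genotypes=3, days=2, grid_minutes=30.0, n_snps=8, seed=13)
        t2, _, _ = sm.simulate_population(sm.ScenarioConfig(n_replicates=2, **base))
        t4, _, _ = sm.simulate_population(sm.ScenarioConfig(n_replicates=4, **base))
        for sid in t2.sample_ids:
            a, b = t2.get(sid, "TR"), t4.get(sid, "TR")
            assert np.array_equal(a.values, b.values)

    def test_noise_free_replicates_identical_and_round_trip_recovers_truth(self):
        cfg = sm.ScenarioConfig(
            n_genotypes=2, n_replicates=3, n_snps=4, seed=21,
            noise_sd={"TR": 0.0, "VWC": 0.0}, diurnal_amplitude=0.0,
        )
        traj, _, truth = sm.simulate_population(cfg)
        a = traj.get("G01_R1", "TR").values
        for r in (2, 3):
            assert np.array_equal(a, traj.get(f"G01_R{r}", "TR").values)
        # round-trip oracle: the generating rate field is recovered from the
        # generator's own noise-free curves to well below 1e-6
        times = traj.trajectories[0].times
        model = SystemModel.from_dict(truth.genotype_models["G01"])
        fitted = gradient_match_fit(
            exact_smoothed_curves(model, times), model.traits, domains=DOMAINS
        )
        assert np.abs(theta_vector(fitted) - theta_vector(model)).max() < 1e-6

    def test_causal_effects_shift_named_coefficient_additively(self):
        eff = -0.1 * 3.25 * K_RELAX
        cfg = sm.ScenarioConfig(
            n_genotypes=8, n_replicates=1, days=2, grid_minutes=30.0, n_snps=6,
            seed=3, causal_snps=[CausalEffect("S0003", ("TR", "VWC"), 0, eff)],
        )
        traj, G, truth = sm.simulate_population(cfg)
        from sysmap.basis import anchored_from_theta

        base = sm.default_baseline_model(days=2)
        base_free = anchored_from_theta(
            base.dependent[("TR", "VWC")].theta, base.dependent[("TR", "VWC")].basis
        )
        for g, gid in enumerate([f"G{i + 1:02d}" for i in range(8)]):
            m = SystemModel.from_dict(truth.genotype_models[gid])
            free = anchored_from_theta(
                m.dependent[("TR", "VWC")].theta, m.dependent[("TR", "VWC")].basis
            )
            dose = G.codes[g, 2]
            assert free[0] == pytest.approx(base_free[0] + eff * dose, rel=1e-12)

    def test_overwhelming_effect_rejected_before_generation(self):
        cfg = sm.ScenarioConfig(
            n_genotypes=8, n_replicates=1, days=2, grid_minutes=30.0, n_snps=6,
            seed=3, causal_snps=[CausalEffect("S0003", ("TR", "VWC"), 0, 50 * 3.25 * K_RELAX)],
        )
        with pytest.raises(ConfigRejectionError):
            sm.simulate_population(cfg)

    def test_diurnal_factor_shape(self):
        t = np.array([0.0, 360.0, 720.0, 1080.0, 1200.0])
        f = diurnal_factor(t, 0.6)
        assert f[0] == pytest.approx(1.0)  # midnight: no transpiration boost
        assert f[1] == pytest.approx(1.0)  # 06:00 day start
        assert f[2] == pytest.approx(1.6)  # solar noon
        assert f[4] == pytest.approx(1.0)  # 20:00, after dusk clamp


class TestDrydownCheck:
    def test_default_scenario_shows_two_phase_pattern(self, default_sim):
        traj, _, _ = default_sim
        report = sm.qualitative_drydown_check(traj)
        assert report.passed, report.summary()

    def test_rewetting_is_flagged_as_vwc_violation(self, small_sim):
        traj, _, _ = small_sim
        modified = []
        for tr in traj.trajectories:
            v = tr.values.copy()
            if tr.trait == "VWC":
                v[v.size // 2:] = np.clip(v[v.size // 2:] + 0.08, 0, 1)  # rewetting step
            modified.append(
                sm.TraitTrajectory(tr.sample_id, tr.genotype_id, tr.replicate,
                                   tr.trait, tr.times, v, tr.unit)
            )
        report = sm.qualitative_drydown_check(
            sm.TrajectorySet(modified, traj.traits, traj.grid_minutes)
        )
        assert not report.passed
        assert any("VWC increases" in m for msgs in report.violations.values() for m in msgs)

    def test_decoupled_transpiration_fails_phase_check(self):
        # constant soil water and monotonically fading TR: no initial rise
        times = np.arange(0.0, 4 * 1440.0, 30.0)
        trajs = []
        for r in (1, 2):
            trajs += [
                sm.TraitTrajectory(f"s{r}", "g1", r, "TR", times,
                                   3.0 * np.exp(-times / 2880.0)),
                sm.TraitTrajectory(f"s{r}", "g1", r, "VWC", times,
                                   np.full(times.size, 0.4)),
            ]
        report = sm.qualitative_drydown_check(sm.TrajectorySet(trajs, ("TR", "VWC")))
        assert not report.passed
        assert any("peaks on day 1" in m for msgs in report.violations.values() for m in msgs)

    def test_short_span_rejected(self):
        times = np.arange(0.0, 2 * 1440.0, 30.0)
        trajs = [
            sm.TraitTrajectory("s", "g", 1, "TR", times, np.linspace(3, 2, times.size)),
            sm.TraitTrajectory("s", "g", 1, "VWC", times, np.linspace(0.4, 0.3, times.size)),
        ]
        with pytest.raises(InsufficientSpanError):
            sm.qualitative_drydown_check(sm.TrajectorySet(trajs, ("TR", "VWC")))
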