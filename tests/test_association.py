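import numpy as np
import pytest

import sysmap as sm
from sysmap.association import (
    GenotypeMatrix,
    InteractionScan,
    _manova_lrt,
    _merge_small_classes,
    bh_fdr,
)
from sysmap.errors import ValidationError


class TestBHFDR:
    def test_step_up_by_hand(self):
        # thresholds at alpha 0.05 over m=4: 0.0125, 0.025, 0.0375, 0.05
        q, reject = bh_fdr([0.001, 0.02, 0.04, 0.8], alpha=0.05)
        assert list(reject) == [True, True, False, False]
        assert q == pytest.approx([0.004, 0.04, 0.0533333333, 0.8])

    def test_all_ones_never_rejected(self):
        q, reject = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()
        assert q == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_value_identity(self):
        q, reject = bh_fdr([0.03], alpha=0.05)
        assert q[0] == pytest.approx(0.03)
        assert reject[0]

    def test_nan_excluded_from_universe(self):
        q, reject = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not reject[1]
        # the NaN does not count toward m: q of 0.01 is 0.01 * 2 / 1
        assert q[0] == pytest.approx(0.02)

    def test_q_values_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_appending_certain_nulls_never_shrinks_q(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50) ** 2
        q0, _ = bh_fdr(p)
        q1, _ = bh_fdr(np.concatenate([p, np.ones(25)]))
        assert np.all(q1[:50] >= q0 - 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5], alpha=1.5)
        with pytest.raises(ValidationError):
            bh_fdr([1.5])
        q, reject = bh_fdr([])
        assert q.size == 0 and reject.size == 0


class TestClassMerging:
    def test_small_class_merges_into_nearest_dosage(self):
        dos = np.array([0] * 10 + [1] * 2 + [2] * 5, dtype=float)
        labels = _merge_small_classes(dos, 3)
        assert set(labels) == {0.0, 2.0}
        assert (labels == 0.0).sum() == 12

    def test_single_remaining_class_is_untestable(self):
        dos = np.array([0] * 10 + [2] * 1, dtype=float)
        assert _merge_small_classes(dos, 3) is None

    def test_large_classes_untouched(self):
        dos = np.array([0] * 5 + [1] * 5 + [2] * 5, dtype=float)
        labels = _merge_small_classes(dos, 3)
        assert set(labels) == {0.0, 1.0, 2.0}


class TestManovaLRT:
    def test_statistic_invariant_to_class_relabeling(self):
        rng = np.random.default_rng(0)
        B = rng.normal(size=(30, 4))
        labels = np.repeat([0.0, 1.0, 2.0], 10)
        swapped = labels.copy()
        swapped[labels == 0.0], swapped[labels == 2.0] = 2.0, 0.0
        a, b = _manova_lrt(B, labels), _manova_lrt(B, swapped)
        assert a[0] == pytest.approx(b[0])
        assert a[1] == b[1]

    def test_statistic_nonnegative_and_df(self):
        rng = np.random.default_rng(1)
        B = rng.normal(size=(32, 4))
        labels = np.repeat([0.0, 1.0], 16)
        stat, df, p, _ = _manova_lrt(B, labels)
        assert stat >= 0
        assert df == 4
        assert 0 <= p <= 1

    def test_insufficient_lines_returns_none(self):
        B = np.random.default_rng(2).normal(size=(6, 4))
        labels = np.repeat([0.0, 1.0], 3)
        assert _manova_lrt(B, labels) is None


@pytest.fixture(scope="module")
def scanned(default_sim):
    traj, G, truth = default_sim
    est = InteractionScan().fit(traj, G)
    return est, G


class TestScan:
    def test_table_covers_every_snp(self, scanned):
        est, G = scanned
        t = est.result_.table
        assert len(t) == G.n_snps
        assert set(t.columns) >= {
            "snp_id", "chrom", "pos", "n", "n_classes", "df", "lrt", "p", "q",
            "tested", "delta_TR_VWC", "delta_VWC_TR",
        }
        tested = t[t.tested]
        assert (tested.lrt >= -1e-9).all()
        assert tested.p.between(0, 1).all()
        assert (tested.q >= tested.p - 1e-12).all()

    def test_monomorphic_snp_marked_untested_not_fatal(self, default_sim):
        traj, G, _ = default_sim
        codes = G.codes.copy()
        codes[:, 0] = 0.0  # monomorphic
        codes[:, 1] = np.nan  # entirely missing
        G2 = GenotypeMatrix(G.sample_ids, G.snp_ids, codes, G.positions)
        est = InteractionScan().fit(traj, G2)
        t = est.result_.table.set_index("snp_id")
        assert not t.loc["S0001", "tested"]
        assert not t.loc["S0002", "tested"]
        assert np.isnan(t.loc["S0001", "p"])

    def test_sample_intersection_is_used(self, default_sim, caplog):
        import logging

        traj, G, _ = default_sim
        G2 = GenotypeMatrix(
            G.sample_ids[:20] + ["ghost1", "ghost2"], G.snp_ids,
            np.vstack([G.codes[:20], np.zeros((2, G.n_snps))]), G.positions,
        )
        with caplog.at_level(logging.WARNING):
            est = InteractionScan().fit(traj, G2)
        assert len(est.line_ids_) == 20
        assert "intersection" in caplog.text

    def test_empty_overlap_is_an_error(self, default_sim):
        traj, G, _ = default_sim
        G2 = GenotypeMatrix(["x1", "x2"], G.snp_ids, np.zeros((2, G.n_snps)), None)
        with pytest.raises(ValidationError):
            InteractionScan().fit(traj, G2)

    def test_permutation_p_bounds_and_strong_signal(self):
        from sysmap.simulator import CausalEffect, K_RELAX

        cfg = sm.ScenarioConfig(
            n_snps=30, seed=5,
            causal_snps=[CausalEffect("S0001", ("TR", "VWC"), 0, -0.25 * 3.25 * K_RELAX)],
        )
        traj, G, _ = sm.simulate_population(cfg)
        est = InteractionScan().fit(traj, G)
        p = est.permutation_p(G, "S0001", n_perm=100, seed=1)
        # a huge observed statistic exceeds every permuted one: best case
        assert p == pytest.approx(1 / 101)
        with pytest.raises(ValidationError):
            est.permutation_p(G, "S0001", n_perm=50, seed=1)

    def test_rejections_consistent_with_direct_bh(self, scanned):
        est, _ = scanned
        t = est.result_.table
        q, reject = bh_fdr(t.p.to_numpy(), alpha=est.result_.alpha)
        tested = t.tested.to_numpy()
        assert np.allclose(t.q.to_numpy()[tested], q[tested], equal_nan=True)
        assert np.array_equal(t.reject.to_numpy(), reject)
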