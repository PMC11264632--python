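import numpy as np
import pytest

from gutscape.assembly import (NullModelConfig, PROCESSES, beta_mntd, bnti,
                               bnti_matrix, classify_process,
                               compare_fractions, partition_assembly,
                               patristic_matrix, rc_bray, rc_bray_matrix)
from gutscape.data_model import FeatureTable


class TestBetaMNTD:
    def test_identical_communities_zero(self, toy_tree):
        x = [3, 1, 0]
        assert beta_mntd(x, x, toy_tree, ["A", "B", "C"]) == pytest.approx(0.0)

    def test_hand_patristic_value(self, toy_tree):
        # x={A}, y={C}: d(A,C) = 1+1+2 = 4
        got = beta_mntd([5, 0, 0], [0, 0, 7], toy_tree, ["A", "B", "C"])
        assert got == pytest.approx(4.0)

    def test_unweighted_equals_weighted_for_equal_abundances(self, toy_tree):
        x, y = [2, 2, 0], [0, 2, 2]
        w = beta_mntd(x, y, toy_tree, ["A", "B", "C"], abundance_weighted=True)
        u = beta_mntd(x, y, toy_tree, ["A", "B", "C"], abundance_weighted=False)
        assert w == pytest.approx(u)

    def test_empty_sample_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            beta_mntd([0, 0, 0], [1, 0, 0], toy_tree, ["A", "B", "C"])


class TestBNTI:
    def test_star_tree_degenerate_null_errors(self):
        from skbio import TreeNode
        import io
        star = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1);"))
        with pytest.raises(ValueError, match="zero"):
            bnti([5, 1, 0, 0], [0, 0, 3, 2], star, ["A", "B", "C", "D"],
                 NullModelConfig(n_randomizations=100, seed=0))

    def test_seed_determinism(self, small_drift_study):
        table = small_drift_study.table.filter_samples(
            small_drift_study.table.sample_ids[:6])
        cfg = NullModelConfig(n_randomizations=200, seed=17)
        z1 = bnti_matrix(table, small_drift_study.tree, cfg)
        z2 = bnti_matrix(table, small_drift_study.tree, cfg)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_pairwise_matches_matrix_entry(self, small_drift_study):
        table = small_drift_study.table.filter_samples(
            small_drift_study.table.sample_ids[:2])
        cfg = NullModelConfig(n_randomizations=200, seed=3)
        z = bnti_matrix(table, small_drift_study.tree, cfg)
        x, y = table.counts[:, 0], table.counts[:, 1]
        single = bnti(x, y, small_drift_study.tree, table.taxon_ids, cfg)
        assert single == pytest.approx(float(z.iloc[0, 1]))


class TestRaupCrick:
    def test_rc_in_range(self, small_drift_study):
        table = small_drift_study.table.filter_samples(
            small_drift_study.table.sample_ids[:8])
        rc = rc_bray_matrix(table, NullModelConfig(200, seed=0))
        vals = rc.to_numpy()
        assert (vals >= -1).all() and (vals <= 1).all()

    def test_identical_samples_from_diverse_pool_near_minus_one(self):
        """Two identical samples are far more similar than null assemblies
        drawn from a diverse regional pool."""
        rng = np.random.default_rng(0)
        pool = rng.integers(1, 50, (30, 6))
        pool[:, 1] = pool[:, 0]  # make samples 0 and 1 identical
        table = FeatureTable(pool, [f"t{i}" for i in range(30)],
                             [f"s{i}" for i in range(6)])
        rc = rc_bray_matrix(table, NullModelConfig(500, seed=1))
        assert rc.iloc[0, 1] < -0.95

    def test_pairwise_wrapper_by_ids(self, small_drift_study):
        table = small_drift_study.table.filter_samples(
            small_drift_study.table.sample_ids[:5])
        cfg = NullModelConfig(200, seed=2)
        full = rc_bray_matrix(table, cfg)
        ids = (table.sample_ids[0], table.sample_ids[3])
        got = rc_bray(None, None, table, cfg, sample_ids=ids)
        assert got == pytest.approx(float(full.loc[ids[0], ids[1]]))

    def test_empty_pool_rejected(self):
        table = FeatureTable(np.zeros((3, 2), dtype=int), list("abc"),
                             ["x", "y"])
        with pytest.raises(ValueError):
            rc_bray_matrix(table)


class TestClassifyProcess:
    @pytest.mark.parametrize("b,r,expected", [
        (-3.1, 0.2, "homogeneous_selection"),
        (2.5, -0.99, "variable_selection"),   # selection takes precedence
        (0.5, 0.2, "drift"),
        (1.0, 0.99, "dispersal_limitation"),
        (1.0, -0.99, "homogenizing_dispersal"),
        (-2.0, 0.0, "drift"),                  # boundary falls inward
        (2.0, 0.0, "drift"),
        (0.0, 0.95, "drift"),
        (0.0, -0.95, "drift"),
    ])
    def test_thresholds(self, b, r, expected):
        assert classify_process(b, r) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_process(float("nan"), 0.0)

    def test_total_over_grid(self):
        for b in np.linspace(-4, 4, 17):
            for r in np.linspace(-1, 1, 21):
                assert classify_process(b, r) in PROCESSES


@pytest.fixture(scope="module")
def drift_partition(small_drift_study):
    return partition_assembly(small_drift_study.table,
                              small_drift_study.tree,
                              small_drift_study.metadata,
                              NullModelConfig(200, seed=0))


class TestPartitionAssembly:
    @pytest.fixture
    def result(self, drift_partition):
        return drift_partition

    def test_fractions_sum_to_one(self, result):
        for frac in result.fractions.values():
            if frac.n_pairs:
                assert sum(frac.fractions.values()) == pytest.approx(1.0)

    def test_pair_counting_identity(self, result):
        n = result.fractions["all_pairs"].n_pairs
        assert n == (result.fractions["within_site"].n_pairs
                     + result.fractions["between_site"].n_pairs)
        n_samples = len(set(result.pairs["sample_a"]) |
                        set(result.pairs["sample_b"]))
        assert n == n_samples * (n_samples - 1) // 2

    def test_labels_consistent_with_scores(self, result):
        for _, row in result.pairs.iterrows():
            assert row["process"] == classify_process(row["bnti"], row["rc"])


class TestCompareFractions:
    def _fractions(self, counts, condition):
        from gutscape.assembly import ProcessFractions
        n = sum(counts.values())
        return ProcessFractions(condition,
                                {p: counts.get(p, 0) / n for p in PROCESSES},
                                {p: counts.get(p, 0) for p in PROCESSES}, n)

    def test_identical_fractions_p_one_delta_zero(self):
        f = self._fractions({"drift": 60, "variable_selection": 40}, "a")
        out = compare_fractions(f, f)
        assert (out["delta"] == 0).all()
        np.testing.assert_allclose(out["p"], 1.0)

    def test_hand_chi_square(self):
        f1 = self._fractions({"drift": 550, "variable_selection": 450}, "b")
        f2 = self._fractions({"drift": 410, "variable_selection": 590}, "c")
        out = compare_fractions(f1, f2)
        assert out.loc["drift", "chi2"] == pytest.approx(38.7, abs=0.2)
        assert out.loc["drift", "p"] < 1e-9

    def test_deltas_sum_to_zero(self):
        f1 = self._fractions({"drift": 30, "variable_selection": 50,
                              "homogenizing_dispersal": 20}, "b")
        f2 = self._fractions({"drift": 70, "dispersal_limitation": 30}, "c")
        out = compare_fractions(f1, f2)
        assert out["delta"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_empty_condition_rejected(self):
        f1 = self._fractions({"drift": 10}, "b")
        from gutscape.assembly import ProcessFractions
        empty = ProcessFractions("c", {p: 0.0 for p in PROCESSES},
                                 {p: 0 for p in PROCESSES}, 0)
        with pytest.raises(ValueError):
            compare_fractions(f1, empty)
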