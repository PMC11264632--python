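import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from gutscape.diversity import bray_curtis
from gutscape.env_assoc import (cca, cca_permutation_test, ddr_fit, env_table,
                                envfit, glm_alpha, haversine_km,
                                marginal_adonis_screen, standardize,
                                vif_screen)


@pytest.fixture(scope="module")
def random_env():
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.normal(size=(40, 6)),
                        columns=["latitude", "elevation",
                                 "annual_mean_temperature",
                                 "annual_precipitation",
                                 "population_density", "human_footprint"],
                        index=[f"s{i}" for i in range(40)])


class TestVIF:
    def test_orthogonal_covariates_vif_one(self):
        # columns orthogonal to each other AND to the intercept: QR of
        # [1 | random], drop the constant column
        rng = np.random.default_rng(1)
        mat = np.column_stack([np.ones(30), rng.normal(size=(30, 4))])
        q, _ = np.linalg.qr(mat)
        env = pd.DataFrame(q[:, 1:], columns=list("abcd"))
        out = vif_screen(env)
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-8)

    def test_duplicated_covariate_infinite(self, random_env):
        env = random_env.copy()
        env["dup"] = env["latitude"]
        out = vif_screen(env)
        assert out.loc["latitude", "vif"] == np.inf
        assert out.loc["dup", "vif"] == np.inf
        assert not out.loc["dup", "pass"]

    def test_affine_rescaling_invariance(self, random_env):
        v1 = vif_screen(random_env)["vif"]
        scaled = random_env * 13.5 + 7.0
        v2 = vif_screen(scaled)["vif"]
        np.testing.assert_allclose(v1, v2, rtol=1e-8)

    def test_default_threshold_is_ten(self, random_env):
        out = vif_screen(random_env)
        assert (out["pass"] == (out["vif"] < 10)).all()


class TestAdonisScreen:
    def test_r2_in_unit_interval(self, small_drift_study, random_env):
        dm = bray_curtis(small_drift_study.table)
        env = env_table(small_drift_study.metadata.loc[list(dm.ids)])
        out = marginal_adonis_screen(dm, env, n_perm=99, seed=0)
        assert ((out["R2"] >= 0) & (out["R2"] <= 1)).all()
        assert (out["p"] >= 1 / 100).all()

    def test_constant_covariate_rejected(self, small_drift_study):
        dm = bray_curtis(small_drift_study.table)
        env = env_table(small_drift_study.metadata.loc[list(dm.ids)])
        env["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            marginal_adonis_screen(dm, env, n_perm=49)


class TestGLM:
    def test_intercept_only_poisson_closed_form(self):
        # a covariate independent of y leaves the fitted intercept at
        # log(mean) up to the (tiny) slope leakage
        rng = np.random.default_rng(2)
        y = rng.poisson(20, size=200)
        x = rng.normal(0, 1e-6, 200)
        fit = glm_alpha(y, x, "poisson")
        assert fit.params["intercept"] == pytest.approx(np.log(y.mean()),
                                                        abs=1e-3)

    def test_poisson_slope_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 500)
        y = rng.poisson(np.exp(3.0 - 0.3 * x))
        fit = glm_alpha(y, x, "poisson")
        assert fit.slope == pytest.approx(-0.3, abs=0.05)

    def test_gaussian_family_for_continuous_index(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 100)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.1, 100)
        fit = glm_alpha(y, x, "gaussian")
        assert fit.slope == pytest.approx(1.5, abs=0.1)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            glm_alpha([1, 2, 3], [1, 2, 3], "poisson")


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km(30, 100, 30, 100) == 0.0

    def test_one_degree_longitude_at_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(
            2 * np.pi * 6371 / 360, rel=1e-6)

    def test_symmetry(self):
        assert haversine_km(10, 20, 30, 40) == pytest.approx(
            haversine_km(30, 40, 10, 20))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(95, 0, 0, 0)


class TestDDR:
    def test_hand_ols(self):
        """Fit on (distance, similarity) = (0,1),(1,0.5),(2,0)."""
        import numpy.polynomial  # noqa: F401
        slope, intercept = np.polyfit([0, 1, 2], [1, 0.5, 0], 1)
        assert slope == pytest.approx(-0.5)
        assert intercept == pytest.approx(1.0)

    def test_dispersal_limited_regime_negative_slope(self):
        from gutscape.synthetic import SimulationConfig, simulate_study
        detected = 0
        for seed in range(5):
            cfg = SimulationConfig(n_taxa=80, n_sites=6,
                                   samples_per_site=(4, 4), depth=800,
                                   regime="dispersal_limited", seed=seed)
            st = simulate_study(cfg)
            dm = bray_curtis(st.table)
            out = ddr_fit(dm, st.metadata, n_perm=199, seed=seed)
            detected += (out["slope"] < 0) and (out["p"] <= 0.05)
        assert detected >= 4

    def test_colocated_samples_rejected(self, toy_table, toy_metadata):
        meta = toy_metadata.copy()
        meta[["latitude", "longitude"]] = 30.0, 100.0
        dm = bray_curtis(toy_table)
        with pytest.raises(ValueError):
            ddr_fit(dm, meta)


@pytest.fixture(scope="module")
def occupied_table(small_drift_study):
    """Drift-study table restricted to taxa observed at least once."""
    table = small_drift_study.table
    keep = [t for t, s in zip(table.taxon_ids, table.counts.sum(axis=1))
            if s > 0]
    return table.filter_taxa(keep)


class TestCCA:
    def test_single_constraint_single_axis(self, small_drift_study,
                                           occupied_table):
        table = occupied_table
        env = env_table(small_drift_study.metadata.loc[table.sample_ids])
        res = cca(table, env[["annual_mean_temperature"]])
        assert len(res.eigenvalues) == 1

    def test_total_inertia_is_chi_square_over_grand_total(self,
                                                          small_drift_study,
                                                          occupied_table):
        table = occupied_table
        env = env_table(small_drift_study.metadata.loc[table.sample_ids])
        res = cca(table, env)
        y = table.counts.T.astype(float)
        tot = y.sum()
        exp = np.outer(y.sum(axis=1), y.sum(axis=0)) / tot
        chi2 = ((y - exp) ** 2 / exp).sum()
        assert res.total_inertia == pytest.approx(chi2 / tot, rel=1e-10)

    def test_constrained_at_most_total(self, small_drift_study,
                                       occupied_table):
        table = occupied_table
        env = env_table(small_drift_study.metadata.loc[table.sample_ids])
        res = cca(table, env)
        assert 0 < res.constrained_inertia <= res.total_inertia + 1e-12

    def test_permutation_p_floor(self, small_drift_study, occupied_table):
        table = occupied_table
        env = env_table(small_drift_study.metadata.loc[table.sample_ids])
        res = cca(table, env)
        out = cca_permutation_test(res, n_perm=99, seed=0)
        assert out["p"] >= 1 / 100

    def test_more_constraints_than_samples_rejected(self, toy_table,
                                                    toy_metadata):
        env = env_table(toy_metadata)
        with pytest.raises(ValueError):
            cca(toy_table, env)


class TestEnvfit:
    @pytest.fixture
    def scores(self):
        rng = np.random.default_rng(7)
        return pd.DataFrame(rng.normal(size=(50, 2)), columns=["A1", "A2"],
                            index=[f"s{i}" for i in range(50)])

    def test_covariate_equal_to_axis_r2_one(self, scores):
        env = pd.DataFrame({"v": scores["A1"]}, index=scores.index)
        out = envfit(scores, env, n_perm=99, seed=0)
        assert out.loc["v", "r2"] == pytest.approx(1.0)
        assert abs(out.loc["v", "dir_A1"]) == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_covariate_r2_near_zero(self, scores):
        rng = np.random.default_rng(8)
        v = rng.normal(size=50)
        a = scores.to_numpy()
        a = a - a.mean(axis=0)  # envfit centres the axes before fitting
        v = v - v.mean()
        v = v - a @ np.linalg.lstsq(a, v, rcond=None)[0]  # residualize
        env = pd.DataFrame({"v": v}, index=scores.index)
        out = envfit(scores, env, n_perm=99, seed=0)
        assert out.loc["v", "r2"] == pytest.approx(0.0, abs=1e-10)

    def test_direction_unit_norm_and_p_floor(self, scores):
        rng = np.random.default_rng(9)
        env = pd.DataFrame({"v": rng.normal(size=50),
                            "w": scores["A1"] + rng.normal(0, 0.2, 50)},
                           index=scores.index)
        out = envfit(scores, env, n_perm=999, seed=0)
        for var in out.index:
            norm = np.hypot(out.loc[var, "dir_A1"], out.loc[var, "dir_A2"])
            assert norm == pytest.approx(1.0, abs=1e-9)
        assert (out["p"] >= 1 / 1000).all()
        assert out.loc["w", "p"] == pytest.approx(0.001)


class TestCCAAgainstVegan:
    def test_inertia_and_eigenvalues_match_vegan(self, tmp_path):
        """Independent oracle: vegan::cca on the same tiny table."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 40, (12, 10))
        counts[counts.sum(axis=1) == 0, 0] = 1
        from gutscape.data_model import FeatureTable
        table = FeatureTable(counts, [f"t{i}" for i in range(12)],
                             [f"s{i}" for i in range(10)])
        env = pd.DataFrame({"a": rng.normal(size=10),
                            "b": rng.normal(size=10)},
                           index=table.sample_ids)
        res = cca(table, env)
        ypath, epath = tmp_path / "Y.csv", tmp_path / "E.csv"
        pd.DataFrame(counts.T, index=table.sample_ids,
                     columns=table.taxon_ids).to_csv(ypath)
        env.to_csv(epath)
        script = (
            'suppressMessages(library(vegan));'
            f'Y <- read.csv("{ypath}", row.names=1);'
            f'E <- as.data.frame(scale(read.csv("{epath}", row.names=1)));'
            'm <- cca(Y ~ a + b, data=E);'
            'cat(m$tot.chi, m$CCA$tot.chi, m$CCA$eig, sep="\\n")'
        )
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True, check=True)
        vals = [float(v) for v in proc.stdout.split()]
        assert res.total_inertia == pytest.approx(vals[0], rel=1e-5)
        assert res.constrained_inertia == pytest.approx(vals[1], rel=1e-5)
        np.testing.assert_allclose(res.eigenvalues, vals[2:], rtol=1e-5)


def test_standardize_reversible(random_env):
    z = standardize(random_env)
    back = z * random_env.std(ddof=1) + random_env.mean()
    pd.testing.assert_frame_equal(back, random_env, check_exact=False)
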