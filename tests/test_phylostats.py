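"""Brownian simulation, phylogenetic tests, signal, modes and mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import statsmodels.api as sm

from iridisim.phylostats import (
    _lambda_grid,
    average_duplicates,
    critical_bandwidth,
    excess_mass_stat,
    fit_plumage_lmm,
    fit_sim_effects,
    load_tree,
    mode_test,
    pagels_lambda,
    phylo_anova,
    phylo_pairwise_t,
    simulate_bm,
    tree_vcv,
)
from iridisim.synth import gen_tree


class TestTreeVcv:
    def test_two_tip_tree_shared_stem(self):
        tree = load_tree("((a:2.0,b:2.0):3.0);")
        taxa, C = tree_vcv(tree)
        i, j = taxa.index("a"), taxa.index("b")
        assert C[i, i] == pytest.approx(5.0)
        assert C[i, j] == pytest.approx(3.0)

    def test_star_tree_diagonal(self, star_tree_40):
        _, C = tree_vcv(star_tree_40)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C - np.diag(np.diag(C)), 0.0)

    def test_degenerate_tree_rejected(self):
        with pytest.raises(ValueError):
            tree_vcv(load_tree("(a:0.0,b:0.0);"))


class TestSimulateBM:
    def test_same_seed_identical(self, yule_tree_64):
        a = simulate_bm(yule_tree_64, 1.0, seed=5)
        b = simulate_bm(yule_tree_64, 1.0, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_star_tree_tips_iid(self, star_tree_40):
        X = simulate_bm(star_tree_40, 2.0, seed=1, n_traits=2000).to_numpy()
        S = np.cov(X)
        assert np.diag(S).mean() == pytest.approx(2.0, rel=0.1)
        off = S[~np.eye(40, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_two_tip_covariance_analytic(self):
        tree = load_tree("((a:1.0,b:1.0):2.0);")
        X = simulate_bm(tree, 1.5, seed=2, n_traits=4000).to_numpy()
        S = np.cov(X)
        assert S[0, 1] == pytest.approx(1.5 * 2.0, rel=0.15)

    def test_invalid_rate(self, star_tree_40):
        with pytest.raises(ValueError):
            simulate_bm(star_tree_40, 0.0)


class TestPhyloAnova:
    def test_star_tree_matches_classical_anova(self, star_tree_40, rng):
        x = pd.Series(rng.standard_normal(40), index=[f"t{i}" for i in range(40)])
        g = pd.Series(["a"] * 20 + ["b"] * 20, index=x.index)
        res = phylo_anova(star_tree_40, x, g, n_sim=4000, seed=3)
        p_classic = sps.f.sf(res.F_obs, res.df_between, res.df_within)
        assert res.p_sim == pytest.approx(p_classic, abs=0.03)

    def test_extreme_separation_attains_minimum_p(self, yule_tree_64):
        taxa, _ = tree_vcv(yule_tree_64)
        g = pd.Series(np.where(np.arange(64) % 2 == 0, "a", "b"), index=taxa)
        x = pd.Series(np.where(g == "a", 0.0, 50.0), index=taxa)
        x += np.random.default_rng(0).normal(0, 0.1, 64)
        res = phylo_anova(yule_tree_64, x, g, n_sim=200, seed=1)
        assert res.p_sim == pytest.approx(1.0 / 201.0)

    def test_reproducible_under_seed(self, yule_tree_64):
        taxa, _ = tree_vcv(yule_tree_64)
        x = simulate_bm(yule_tree_64, 1.0, seed=4)["trait_0"]
        g = pd.Series(np.where(np.arange(64) < 32, "a", "b"), index=taxa)
        p1 = phylo_anova(yule_tree_64, x, g, n_sim=300, seed=9).p_sim
        p2 = phylo_anova(yule_tree_64, x, g, n_sim=300, seed=9).p_sim
        assert p1 == p2

    def test_singleton_group_rejected(self, star_tree_40, rng):
        x = pd.Series(rng.standard_normal(40), index=[f"t{i}" for i in range(40)])
        g = pd.Series(["a"] * 39 + ["b"], index=x.index)
        with pytest.raises(ValueError):
            phylo_anova(star_tree_40, x, g)


class TestPairwiseT:
    def test_two_groups_equal_anova_p(self, yule_tree_64):
        taxa, _ = tree_vcv(yule_tree_64)
        x = simulate_bm(yule_tree_64, 1.0, seed=21)["trait_0"]
        g = pd.Series(np.where(np.arange(64) < 32, "a", "b"), index=taxa)
        p_anova = phylo_anova(yule_tree_64, x, g, n_sim=500, seed=13).p_sim
        mat = phylo_pairwise_t(yule_tree_64, x, g, n_sim=500, seed=13, correction="none")
        # F = t^2 for two groups, and the same simulations feed both nulls
        assert mat.loc["a", "b"] == pytest.approx(p_anova)

    def test_pair_count_and_symmetry(self, yule_tree_64):
        taxa, _ = tree_vcv(yule_tree_64)
        x = simulate_bm(yule_tree_64, 1.0, seed=22)["trait_0"]
        g = pd.Series([["a", "b", "c", "d"][i % 4] for i in range(64)], index=taxa)
        mat = phylo_pairwise_t(yule_tree_64, x, g, n_sim=200, seed=5)
        off_diag = mat.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.isfinite(off_diag).all()
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)


class TestPagelsLambda:
    def test_bm_trait_recovers_high_lambda(self, yule_tree_128):
        lams = []
        for rep in range(15):
            y = simulate_bm(yule_tree_128, 1.0, seed=100 + rep)["trait_0"]
            lams.append(pagels_lambda(yule_tree_128, y).lambda_hat)
        assert 0.9 <= float(np.median(lams)) <= 1.0

    def test_shuffled_trait_loses_signal(self, yule_tree_128):
        y = simulate_bm(yule_tree_128, 1.0, seed=200)["trait_0"]
        rng = np.random.default_rng(3)
        ys = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = pagels_lambda(yule_tree_128, ys)
        assert res.lambda_hat < 0.2

    def test_optimum_beats_endpoints(self, yule_tree_128):
        y = simulate_bm(yule_tree_128, 1.0, seed=300)["trait_0"]
        res = pagels_lambda(yule_tree_128, y)
        assert res.logL >= res.logL0 - 1e-9

    def test_star_tree_flagged_unidentifiable(self, star_tree_40, rng):
        y = pd.Series(rng.standard_normal(40), index=[f"t{i}" for i in range(40)])
        res = pagels_lambda(star_tree_40, y)
        assert not res.identifiable

    def test_constant_trait_rejected(self, yule_tree_64):
        taxa, _ = tree_vcv(yule_tree_64)
        with pytest.raises(ValueError):
            pagels_lambda(yule_tree_64, pd.Series(1.0, index=taxa))


class TestExcessMass:
    def test_matches_brute_force_enumeration(self, rng):
        def brute(xs, lambdas):
            xs = np.sort(xs)
            n = len(xs)
            best = 0.0
            for lam in lambdas:
                e1 = max(
                    (j - i + 1) / n - lam * (xs[j] - xs[i])
                    for i in range(n)
                    for j in range(i, n)
                )
                e2 = 0.0
                for i1 in range(n):
                    for j1 in range(i1, n):
                        s1 = (j1 - i1 + 1) / n - lam * (xs[j1] - xs[i1])
                        for i2 in range(j1 + 1, n):
                            for j2 in range(i2, n):
                                s2 = (j2 - i2 + 1) / n - lam * (xs[j2] - xs[i2])
                                e2 = max(e2, s1 + s2)
                best = max(best, max(e2, 0) - max(e1, 0))
            return best

        for sample in (
            rng.normal(0, 1, 16),
            np.concatenate([rng.normal(0, 0.3, 8), rng.normal(5, 0.3, 8)]),
        ):
            lambdas = _lambda_grid(np.sort(sample), 64)
            assert excess_mass_stat(sample, 1) == pytest.approx(
                brute(sample, lambdas), abs=1e-12
            )

    def test_bimodal_sample_has_larger_excess_mass(self, rng):
        uni = rng.normal(0, 1, 150)
        bi = np.concatenate([rng.normal(100, 15, 75), rng.normal(250, 25, 75)])
        assert excess_mass_stat(bi, 1) > excess_mass_stat(uni, 1)

    def test_critical_bandwidth_unimodalises(self, rng):
        bi = np.concatenate([rng.normal(0, 0.5, 60), rng.normal(6, 0.5, 60)])
        h = critical_bandwidth(bi, 1)
        from iridisim.phylostats import _kde_n_modes

        assert _kde_n_modes(bi, h) <= 1
        assert _kde_n_modes(bi, h / 4) > 1


class TestModeTest:
    def test_detects_clear_bimodality(self, rng):
        x = np.concatenate([rng.normal(100, 15, 75), rng.normal(250, 25, 75)])
        assert mode_test(x, 1, n_boot=300, seed=1) < 0.01

    def test_accepts_gaussian(self, rng):
        assert mode_test(rng.standard_normal(150), 1, n_boot=300, seed=2) > 0.05

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal(60)
        assert mode_test(x, 1, 150, seed=7) == mode_test(x, 1, 150, seed=7)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mode_test(np.arange(10.0), 1)


class TestSimEffects:
    def test_recovers_constructed_coefficient(self, rng):
        n = 400
        tab = pd.DataFrame(
            {
                "thin": rng.integers(0, 2, n),
                "hollow": rng.integers(0, 2, n),
                "platelet": rng.integers(0, 2, n),
            }
        )
        tab["hollow_x_platelet"] = tab["hollow"] * tab["platelet"]
        tab["saturation"] = 2.0 * tab["thin"] + rng.normal(0, 0.1, n)
        res = fit_sim_effects(tab, responses=("saturation",))
        coefs = res.tables["saturation"]["coef"]
        assert coefs["thin"] == pytest.approx(2.0, abs=0.05)
        for other in ("hollow", "platelet", "hollow_x_platelet"):
            assert abs(coefs[other]) < 0.05

    def test_collinear_design_rejected_with_names(self, rng):
        n = 100
        tab = pd.DataFrame(
            {
                "thin": rng.integers(0, 2, n),
                "hollow": np.zeros(n),
                "platelet": np.zeros(n),
                "hollow_x_platelet": np.zeros(n),
                "saturation": rng.normal(0, 1, n),
            }
        )
        with pytest.raises(ValueError, match="hollow"):
            fit_sim_effects(tab, responses=("saturation",))


@pytest.fixture(scope="module")
def small_tree():
    return gen_tree(24, 1.0, seed=13)


class TestPlumageLMM:
    def test_zero_variance_matches_ols(self, small_tree, rng):
        taxa, _ = tree_vcv(small_tree)
        rows = []
        for sp in taxa:
            pc = int(rng.integers(0, 2))
            for _ in range(2):
                rows.append(
                    dict(species=sp, patch=f"{sp}:p", PC=pc, y=rng.normal())
                )
        df = pd.DataFrame(rows)
        res = fit_plumage_lmm(
            df, small_tree, "y", ("PC",), var_components=(0.0, 0.0)
        )
        ols = sm.OLS(df["y"], sm.add_constant(df["PC"].astype(float))).fit()
        assert np.allclose(res.params.to_numpy(), ols.params.to_numpy(), atol=1e-6)

    def test_recovers_pc_effect_within_interval(self, small_tree):
        taxa, _ = tree_vcv(small_tree)
        hits = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            u = simulate_bm(small_tree, 0.02, seed=900 + rep)["trait_0"]
            rows = []
            for sp in taxa:
                pc = int(rng.integers(0, 2))
                for _ in range(2):
                    rows.append(
                        dict(
                            species=sp, patch=f"{sp}:p", PC=pc,
                            y=0.1 + 0.2 * pc + u[sp] + rng.normal(0, 0.05),
                        )
                    )
            df = pd.DataFrame(rows)
            res = fit_plumage_lmm(df, small_tree, "y", ("PC",))
            lo, hi = res.conf_int.loc["PC"]
            hits += lo <= 0.2 <= hi
        assert hits / reps >= 0.85

    def test_species_missing_from_tree_rejected(self, small_tree):
        df = pd.DataFrame(
            dict(species=["nope"], patch=["p"], PC=[1], y=[0.1])
        )
        with pytest.raises(ValueError):
            fit_plumage_lmm(df, small_tree, "y", ("PC",))


def test_average_duplicates_collapses_species_rows():
    df = pd.DataFrame(
        {
            "species": ["a", "a", "b"],
            "mt": [100.0, 120.0, 200.0],
            "kind": ["thin_solid_rod", "thin_solid_rod", "thick_solid_rod"],
        }
    )
    out = average_duplicates(df)
    assert len(out) == 2
    assert out.set_index("species").loc["a", "mt"] == pytest.approx(110.0)
    assert out.set_index("species").loc["a", "kind"] == "thin_solid_rod"
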