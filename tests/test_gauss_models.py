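import math

import numpy as np
import pytest

from macroevo.gauss_models import (
    ModelConfig,
    ModelParams,
    aicc,
    build_scenarios,
    compare_scenarios,
    fit_model,
    half_life,
    loglik,
    stationary_variance,
    trait_moments,
)
from macroevo.mk_asr import MkModel
from macroevo.synthetic_data import (
    simulate_mk_states,
    simulate_posterior_sample,
    simulate_traits_matrix,
    simulate_yule_tree,
)
from macroevo.trees import RegimePainting, parse_newick, single_state_painting

from conftest import mvn_logpdf_dense, random_tree


def bm_data(tree, sigma2=1.0, seed=0):
    row = simulate_traits_matrix(
        tree, ModelConfig("BM", "BM1"), ModelParams(sigma2=sigma2, x0=0.0), seed=seed
    )[0]
    return dict(zip(tree.taxa, row))


class TestClosedForms:
    def test_aicc_arithmetic(self):
        assert aicc(-10.0, 3, 55) == pytest.approx(20 + 6 + 24 / 51, abs=1e-9)
        assert aicc(-10.0, 3, 55) == pytest.approx(26.47059, abs=1e-5)

    def test_aicc_k0(self):
        assert aicc(-7.5, 0, 10) == pytest.approx(15.0)

    def test_aicc_large_n_approaches_aic(self):
        assert abs(aicc(-10.0, 3, 10000) - (20 + 6)) < 0.01

    def test_aicc_precondition(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_half_life(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)
        assert half_life(0.357662) == pytest.approx(1.938, abs=1e-3)
        assert half_life(half_life(0.77)) == pytest.approx(0.77)
        with pytest.raises(ValueError):
            half_life(0.0)

    def test_stationary_variance(self):
        assert stationary_variance(2.0, 1.0) == pytest.approx(1.0)
        alpha = math.log(2) / 1.938
        assert stationary_variance(2 * alpha * 0.066, alpha) == pytest.approx(0.066)
        with pytest.raises(ValueError):
            stationary_variance(2.0, 0.0)

    def test_stationary_variance_is_long_time_limit(self):
        alpha, sigma2 = 0.8, 1.7
        T = 100 / alpha
        t = parse_newick(f"(A:{T},B:{T});")
        m = trait_moments(t, ModelConfig("OU", "OU1"),
                          ModelParams(sigma2=sigma2, alpha=alpha, theta=0.0))
        assert m.cov[0, 0] == pytest.approx(stationary_variance(sigma2, alpha), rel=1e-8)


class TestTraitMoments:
    def test_bm_independent(self):
        t = parse_newick("(A:1,B:1);")
        m = trait_moments(t, ModelConfig("BM", "BM1"), ModelParams(sigma2=2.0, x0=0.0))
        assert np.allclose(m.mean, 0.0)
        assert np.allclose(m.cov, 2.0 * np.eye(2))

    def test_ou_fixed_root_variance(self):
        t = parse_newick("(A:1,B:1);")
        m = trait_moments(t, ModelConfig("OU", "OU1"),
                          ModelParams(sigma2=2.0, alpha=1.0, theta=0.0, x0=0.0))
        assert m.cov[0, 0] == pytest.approx(1 - math.exp(-2), abs=1e-12)
        assert m.cov[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_shift_additive_variance(self):
        # height 1, slice at process time 0.6 -> slice age 0.4
        t = parse_newick("(A:1,B:1);")
        m = trait_moments(
            t, ModelConfig("SHIFT", "SHIFT", slice_age=0.4),
            ModelParams(sigma2={"pre": 1.0, "post": 4.0}, x0=0.0))
        assert m.cov[0, 0] == pytest.approx(0.6 + 4 * 0.4, abs=1e-12)

    def test_eb_segment_integral(self):
        t = parse_newick("(A:1,B:1);")
        m = trait_moments(t, ModelConfig("EB", "EB"),
                          ModelParams(sigma2=1.0, r=-1.0, x0=0.0))
        assert m.cov[0, 0] == pytest.approx((math.exp(-1) - 1) / (-1), abs=1e-12)

    def test_oum_mean_integral(self):
        t = parse_newick("(A:2,B:2);")
        paint = RegimePainting(["s1", "s2"], {})
        for node in t.nodes:
            if node is not t.root:
                paint.segments[node.id] = [(2.0, 1.0, "s1"), (1.0, 0.0, "s2")]
        m = trait_moments(
            t, ModelConfig("OU", "OUM", painting=paint),
            ModelParams(sigma2=2.0, alpha=1.0, theta={"s1": 0.0, "s2": 1.0}, x0=0.0))
        assert m.mean[0] == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_stationary_root_mode(self):
        t = parse_newick("(A:1,B:1);")
        m = trait_moments(t, ModelConfig("OU", "OU1"),
                          ModelParams(sigma2=2.0, alpha=1.0, theta=0.5),
                          root_mode="stationary")
        assert np.allclose(m.mean, 0.5)
        assert m.cov[0, 0] == pytest.approx(1.0, abs=1e-12)  # stays at Vy
        with pytest.raises(ValueError):
            trait_moments(t, ModelConfig("BM", "BM1"), ModelParams(sigma2=1.0, x0=0.0),
                          root_mode="stationary")


class TestLimitIdentities:
    def test_limits_on_random_trees(self):
        rng = np.random.default_rng(30)
        for _ in range(5):
            tree = random_tree(rng, 10)
            y = bm_data(tree, seed=int(rng.integers(1 << 30)))
            bm = trait_moments(tree, ModelConfig("BM", "BM1"),
                               ModelParams(sigma2=1.3, x0=0.2))
            ll_bm = loglik(bm, y)

            eb = trait_moments(tree, ModelConfig("EB", "EB"),
                               ModelParams(sigma2=1.3, r=0.0, x0=0.2))
            assert loglik(eb, y) == ll_bm  # exact identity

            sh = trait_moments(
                tree, ModelConfig("SHIFT", "SHIFT", slice_age=0.5),
                ModelParams(sigma2={"pre": 1.3, "post": 1.3}, x0=0.2))
            assert loglik(sh, y) == pytest.approx(ll_bm, abs=1e-10)

            ou = trait_moments(tree, ModelConfig("OU", "OU1"),
                               ModelParams(sigma2=1.3, alpha=1e-10, theta=0.2, x0=0.2))
            assert loglik(ou, y) == pytest.approx(ll_bm, abs=1e-6)

            er = trait_moments(tree, ModelConfig("ER", "ER", slice_age=0.5),
                               ModelParams(sigma2=1.3, alpha=1e-10, theta=0.2, x0=0.2))
            assert loglik(er, y) == pytest.approx(ll_bm, abs=1e-6)

    def test_oum_equal_thetas_is_ou1(self):
        rng = np.random.default_rng(31)
        tree = random_tree(rng, 8)
        _, _, paint = simulate_mk_states(tree, MkModel.er(["a", "b"], 1.0), "a", seed=5)
        y = bm_data(tree, seed=42)
        oum = trait_moments(tree, ModelConfig("OU", "OUM", painting=paint),
                            ModelParams(sigma2=1.0, alpha=0.7,
                                        theta={"a": 0.4, "b": 0.4}))
        ou1 = trait_moments(tree, ModelConfig("OU", "OU1"),
                            ModelParams(sigma2=1.0, alpha=0.7, theta=0.4))
        assert loglik(oum, y) == pytest.approx(loglik(ou1, y), abs=1e-10)


class TestLoglik:
    def test_single_tip_standard_normal(self):
        from macroevo.gauss_models import GaussianMoments

        m = GaussianMoments(["A"], np.zeros(1), np.eye(1))
        assert loglik(m, {"A": 0.0}) == pytest.approx(-0.5 * math.log(2 * math.pi),
                                                      abs=1e-9)

    def test_independent_additivity(self):
        from macroevo.gauss_models import GaussianMoments

        m2 = GaussianMoments(["A", "B"], np.zeros(2), np.diag([1.0, 4.0]))
        mA = GaussianMoments(["A"], np.zeros(1), np.eye(1))
        mB = GaussianMoments(["B"], np.zeros(1), 4.0 * np.eye(1))
        y = {"A": 0.3, "B": -1.2}
        assert loglik(m2, y) == pytest.approx(loglik(mA, y) + loglik(mB, y), abs=1e-10)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(33)
        tree = random_tree(rng, 6)
        m = trait_moments(tree, ModelConfig("OU", "OU1"),
                          ModelParams(sigma2=0.8, alpha=0.6, theta=0.3))
        y = rng.standard_normal(6)
        got = loglik(m, dict(zip(tree.taxa, y)))
        want = mvn_logpdf_dense(y, m.mean, m.cov)
        assert got == pytest.approx(want, abs=1e-8)

    def test_tip_relabeling_invariance(self):
        rng = np.random.default_rng(34)
        tree = random_tree(rng, 10)
        y = bm_data(tree, seed=3)
        m = trait_moments(tree, ModelConfig("BM", "BM1"), ModelParams(sigma2=1.0, x0=0.0))
        assert loglik(m, dict(reversed(list(y.items())))) == pytest.approx(
            loglik(m, y), abs=1e-12)


class TestFitModel:
    def test_bm_recovery(self, tree64):
        Y = simulate_traits_matrix(tree64, ModelConfig("BM", "BM1"),
                                   ModelParams(sigma2=0.1, x0=0.0), seed=40, nsim=100)
        est = [fit_model(tree64, ModelConfig("BM", "BM1"),
                         dict(zip(tree64.taxa, row))).params.sigma2 for row in Y]
        assert abs(np.median(est) - 0.1) < 0.01

    def test_eb_on_bm_hits_boundary(self, tree64):
        # the boundary MLE r=0 is attained for roughly half of Brownian
        # datasets; when it is, EB collapses to BM exactly
        at_bound = 0
        for seed in range(10):
            y = bm_data(tree64, seed=50 + seed)
            bm = fit_model(tree64, ModelConfig("BM", "BM1"), y)
            eb = fit_model(tree64, ModelConfig("EB", "EB"), y)
            assert eb.loglik >= bm.loglik - 1e-9  # BM is nested in EB
            assert eb.aicc > bm.aicc  # the extra parameter never pays
            if eb.params.r == 0.0:
                at_bound += 1
                assert eb.loglik == pytest.approx(bm.loglik, abs=1e-4)
        assert at_bound >= 3

    def test_oum_with_equal_optima_constraint(self, tree20):
        # fitted OU1 is the theta1=theta2 constrained OUM: same likelihood
        _, _, paint = simulate_mk_states(tree20, MkModel.er(["a", "b"], 1.5), "a",
                                         seed=51)
        row = simulate_traits_matrix(
            tree20, ModelConfig("OU", "OU1"),
            ModelParams(sigma2=1.0, alpha=2.0, theta=0.5), seed=52)[0]
        y = dict(zip(tree20.taxa, row))
        ou1 = fit_model(tree20, ModelConfig("OU", "OU1"), y)
        theta = float(ou1.params.theta)
        constrained = trait_moments(
            tree20, ModelConfig("OU", "OUM", painting=paint),
            ModelParams(sigma2=ou1.params.sigma2, alpha=ou1.params.alpha,
                        theta={"a": theta, "b": theta}))
        assert loglik(constrained, y) == pytest.approx(ou1.loglik, abs=1e-8)

    def test_aicc_invariant_asserted(self, tree20):
        f = fit_model(tree20, ModelConfig("BM", "BM1"), bm_data(tree20, seed=53))
        assert f.aicc == pytest.approx(aicc(f.loglik, f.k, f.n))

    def test_parameter_counts(self, tree20):
        _, _, p2 = simulate_mk_states(tree20, MkModel.er(["a", "b"], 1.0), "a", seed=54)
        _, _, p3 = simulate_mk_states(tree20, MkModel.er(["a", "b", "c"], 1.0), "a",
                                      seed=55)
        y = bm_data(tree20, seed=56)
        ks = {
            "BM1": (ModelConfig("BM", "BM1"), 2),
            "EB": (ModelConfig("EB", "EB"), 3),
            "OU1": (ModelConfig("OU", "OU1"), 3),
            "SHIFT": (ModelConfig("SHIFT", "SHIFT", slice_age=0.4), 3),
            "ER": (ModelConfig("ER", "ER", slice_age=0.4), 3),
            "ER4": (ModelConfig("ER", "ER", slice_age=0.4, er_free_post_sigma=True), 4),
            "BMM2": (ModelConfig("BM", "BMM", painting=p2), 3),
            "OUM2": (ModelConfig("OU", "OUM", painting=p2), 4),
            "BMM3": (ModelConfig("BM", "BMM3", painting=p3), 4),
            "OUM3": (ModelConfig("OU", "OUM3", painting=p3), 5),
        }
        for name, (cfg, k) in ks.items():
            assert fit_model(tree20, cfg, y).k == k, name

    def test_insufficient_tips_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="k\\+2"):
            fit_model(t, ModelConfig("OU", "OU1"), {"A": 0.1, "B": 0.2})


class TestScenarioSuite:
    @pytest.fixture(scope="class")
    def regime_states(self, tree20):
        hab_tips, hab_nodes, _ = simulate_mk_states(
            tree20, MkModel.er(["UMF", "LMF"], 0.8), "UMF", seed=60)
        geo_tips, geo_nodes, _ = simulate_mk_states(
            tree20, MkModel.er(["NA", "AHZ", "CA"], 0.8), "NA", seed=61)
        hab_nodes = {tree20.root.id: "UMF", **hab_nodes}
        geo_nodes = {tree20.root.id: "NA", **geo_nodes}
        return (hab_tips, hab_nodes), (geo_tips, geo_nodes), set(tree20.taxa[:7])

    @pytest.fixture(scope="class")
    def paintings(self, tree20, regime_states):
        from macroevo.pipeline import clade_painting
        from macroevo.trees import paint_from_node_states

        (hab_tips, hab_nodes), (geo_tips, geo_nodes), clade_tips = regime_states
        hab = paint_from_node_states(tree20, hab_tips, hab_nodes)
        geo = paint_from_node_states(tree20, geo_tips, geo_nodes)
        clade = clade_painting(tree20, clade_tips)
        return hab, clade, geo

    def test_eleven_scenarios(self, tree20, paintings):
        configs = build_scenarios(tree20, *paintings)
        names = [c.scenario_name for c in configs]
        assert names == [
            "BM1", "EB", "OU1", "SHIFT", "ER", "BMM_Regime", "OUM_Regime",
            "BMM_Clade", "OUM_Clade", "BMM_Geo", "OUM_Geo",
        ]
        geo_bmm = configs[9]
        assert len(geo_bmm.painting.states) == 3

    def test_state_count_mismatch_rejected(self, tree20, paintings):
        hab, clade, geo = paintings
        with pytest.raises(ValueError, match="states"):
            build_scenarios(tree20, geo, clade, geo)

    def test_degenerate_paintings_collapse(self, tree20):
        single2 = single_state_painting(tree20, "x")
        configs = build_scenarios(tree20, single2, single2,
                                  single_state_painting(tree20, "y"))
        y = bm_data(tree20, seed=62)
        fits = {c.scenario_name: fit_model(tree20, c, y) for c in configs}
        assert fits["BMM_Regime"].loglik == pytest.approx(fits["BM1"].loglik, abs=1e-6)
        assert fits["OUM_Clade"].loglik == pytest.approx(fits["OU1"].loglik, abs=1e-6)

    def test_comparison_table(self, tree20, regime_states):
        from macroevo.pipeline import clade_painting
        from macroevo.trees import paint_from_node_states

        (hab_tips, hab_nodes), (geo_tips, geo_nodes), clade_tips = regime_states
        sample = simulate_posterior_sample(tree20, 6, jitter_sd=0.05, seed=63)
        y = bm_data(tree20, seed=64)

        def builder(tree):
            # node ids are stable under age jitter: re-paint on each tree
            return build_scenarios(
                tree,
                paint_from_node_states(tree, hab_tips, hab_nodes),
                clade_painting(tree, clade_tips),
                paint_from_node_states(tree, geo_tips, geo_nodes),
                slice_age=0.4,
            )

        table = compare_scenarios([tree20] + sample, y, builder)
        assert table.reference_delta.min() == 0.0
        assert (table.reference_delta >= 0).all()
        assert table.quantiles is not None
        # order statistics are monotone
        assert (np.diff(table.quantiles, axis=1) >= -1e-12).all()
        df = table.to_frame()
        assert len(df) == 11

    def test_constant_traits_still_emit_table(self, tree20, paintings):
        y = {t: 1.0 for t in tree20.taxa}
        configs = build_scenarios(tree20, *paintings)
        for c in configs[:5]:
            f = fit_model(tree20, c, y)
            assert np.isfinite(f.aicc)
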