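import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

import dendrodiam as dd
from dendrodiam import predictor, regression, synthetic
from dendrodiam.morphometry import NodeClass, feature_table
from dendrodiam.regression import (
    SingularMatrixError,
    UndefinedStatisticError,
    diameter_autocorrelation,
    evaluate_prediction,
    fit_model_set,
    ols_no_intercept,
    pd_equality_fraction,
    pearson_r2,
    rall_check,
    select_features,
    train_test_split,
)
from dendrodiam.swc import MorphNode, Morphology


class TestPearsonR2:
    def test_perfect_correlation(self):
        assert pearson_r2([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = [1.0, -1.0, 1.0, -1.0]
        y = [1.0, 1.0, -1.0, -1.0]
        assert pearson_r2(x, y) == pytest.approx(0.0, abs=1e-15)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
        assert pearson_r2(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r2([1, 1, 1], [1, 2, 3])


class TestOLSNoIntercept:
    def test_exact_fit(self):
        res = ols_no_intercept([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.coefficients[0] == pytest.approx(2.0)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_two_feature_normal_equations_hand_solved(self):
        # X columns (1,0),(0,2),(1,1); y = (1, 4, 4)
        # X'X = [[2,1],[1,5]], X'y = [5, 12] -> beta = (13/9, 19/9)
        X = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        y = np.array([1.0, 4.0, 4.0])
        res = ols_no_intercept(X, y)
        assert res.coefficients[0] == pytest.approx(13 / 9, abs=1e-12)
        assert res.coefficients[1] == pytest.approx(19 / 9, abs=1e-12)

    def test_orthogonal_response_negative_adj_r2(self):
        # y orthogonal to X's column: coefficient 0, uncentered R2 = 0, adj < 0
        X = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, 1.0, 1.0])
        res = ols_no_intercept(X, y)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)
        assert res.adj_r2 < 0

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.arange(1.0, 6), 2 * np.arange(1.0, 6)])
        with pytest.raises(SingularMatrixError, match="PD|TL"):
            ols_no_intercept(X, np.ones(5), ("PD", "TL"))

    def test_matches_statsmodels_uncentered(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        X = rng.uniform(0.1, 3, size=(40, 2))
        y = X @ np.array([0.7, 0.02]) + rng.normal(0, 0.1, 40)
        res = ols_no_intercept(X, y)
        fit = sm.OLS(y, X).fit()
        assert np.allclose(res.coefficients, fit.params, atol=1e-10)
        assert res.r2 == pytest.approx(fit.rsquared, abs=1e-10)

    def test_normal_equations_oracle_property(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            res = ols_no_intercept(X, y)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(res.coefficients, beta, atol=1e-10)


class TestSelectFeatures:
    def test_single_feature_recovered(self):
        tab = synthetic.generate_feature_table({"PD": 0.9}, 500, seed=1)
        sel = select_features(tab, NodeClass.CONTINUING, "generic")
        assert sel.features == ("PD",)

    def test_pair_recovered(self):
        tab = synthetic.generate_feature_table({"PD": 0.5, "LP": 0.004}, 500, seed=2)
        sel = select_features(tab, NodeClass.CONTINUING, "generic")
        assert sel.features == ("LP", "PD")

    def test_impossible_improvement_returns_best_single(self):
        tab = synthetic.generate_feature_table({"PD": 0.5, "LP": 0.004}, 500, seed=3)
        sel = select_features(tab, NodeClass.CONTINUING, "generic", improvement=1.0)
        assert len(sel.features) == 1

    def test_invariant_to_row_and_column_order(self):
        tab = synthetic.generate_feature_table({"PD": 0.5, "LP": 0.004}, 300, seed=4)
        shuffled = tab.sample(frac=1.0, random_state=9)
        sel1 = select_features(tab, NodeClass.CONTINUING, "generic")
        sel2 = select_features(shuffled, NodeClass.CONTINUING, "generic")
        sel3 = select_features(
            tab, NodeClass.CONTINUING, "generic",
            candidates=("TL", "LP", "PS", "TD", "IB", "PD"),
        )
        assert sel1.features == sel2.features == sel3.features
        assert sel1.adj_r2 == pytest.approx(sel2.adj_r2)

    def test_empty_class_errors(self):
        tab = synthetic.generate_feature_table({"PD": 0.9}, 50, seed=5)
        with pytest.raises(UndefinedStatisticError):
            select_features(tab, NodeClass.INITIAL, "generic")


class TestFitModelSet:
    def test_noise_free_recovery_exact(self):
        ms = dd.load_packaged_model_set("striatal")
        spec = replace(synthetic.spec_for_model_set("striatal", 21),
                       diameter_rule=ms, noise_sd=0.0)
        cells = synthetic.generate_archive(spec, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = fit_model_set(cells, seed=0)
        cont = fitted.lookup(NodeClass.CONTINUING, "generic")
        assert cont.features == ("PD",)
        assert cont.coefficients[0] == pytest.approx(0.9834, abs=1e-10)

    def test_noisy_recovery_within_tolerance(self, striatal_archive):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = fit_model_set(striatal_archive, seed=0)
        cont = fitted.lookup(NodeClass.CONTINUING, "generic")
        assert cont.features == ("PD",)
        assert cont.coefficients[0] == pytest.approx(0.9834, abs=0.02)

    def test_split_seeds_differ_but_structure_stable(self, striatal_archive):
        t1, _ = train_test_split(striatal_archive, 0.5, seed=1)
        t2, _ = train_test_split(striatal_archive, 0.5, seed=2)
        names1 = {m.metadata["name"] for m in t1}
        names2 = {m.metadata["name"] for m in t2}
        assert names1 != names2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_model_set(t1, seed=1)
            f2 = fit_model_set(t2, seed=2)
        for cls in NodeClass:
            assert (f1.lookup(cls, "generic").features
                    == f2.lookup(cls, "generic").features)

    def test_provenance_recorded(self, striatal_archive):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = fit_model_set(striatal_archive, seed=42)
        assert fitted.provenance["seed"] == 42
        assert len(fitted.provenance["train_ids"]) == len(striatal_archive)


class TestEvaluatePrediction:
    def test_identity_is_one(self, toy5):
        assert evaluate_prediction(toy5, toy5)["all"] == pytest.approx(1.0)

    def test_uniform_scaling_is_one(self, toy5):
        from dataclasses import replace as rep

        half = toy5.with_nodes([
            rep(n, radius=n.radius * 0.5) if n.type_code != 1 else n
            for n in toy5.nodes
        ])
        assert evaluate_prediction(toy5, half)["all"] == pytest.approx(1.0)

    def test_matches_direct_formula_with_noise(self, small_trees):
        from dataclasses import replace as rep

        m = small_trees[1]
        rng = np.random.default_rng(3)
        noisy_nodes = []
        for n in m.nodes:
            if n.type_code != 1:
                scale = 1 + 0.1 * rng.normal() * n.radius  # heteroscedastic
                noisy_nodes.append(rep(n, radius=max(0.01, n.radius * scale)))
            else:
                noisy_nodes.append(n)
        pred = m.with_nodes(noisy_nodes)
        d_o = [n.diameter for n in m.dendritic_nodes()]
        d_p = [pred.node(n.node_id).diameter for n in m.dendritic_nodes()]
        assert evaluate_prediction(m, pred)["all"] == pytest.approx(
            pearson_r2(d_o, d_p)
        )

    def test_topology_mismatch_errors(self, toy5, chain):
        from dendrodiam.swc import SWCStructureError

        with pytest.raises(SWCStructureError):
            evaluate_prediction(toy5, chain)


def symmetric_rall_tree(depth=4, d0=4.0):
    """Bifurcating tree obeying the 3/2 rule exactly: child = parent * 2^(-2/3)."""
    nodes = [MorphNode(1, 1, 0, 0, 0, 5, -1), MorphNode(2, 3, 10, 0, 0, d0 / 2, 1)]
    frontier = [(2, d0, 10.0, 0.0)]
    nid = 3
    for level in range(depth):
        nxt = []
        d = d0 * 2 ** (-2 * (level + 1) / 3)
        for pid, _, x, y in frontier:
            for dy in (6.0 / (level + 1), -6.0 / (level + 1)):
                nodes.append(MorphNode(nid, 3, x + 10, y + dy, 0, d / 2, pid))
                nxt.append((nid, d, x + 10, y + dy))
                nid += 1
        frontier = nxt
    return Morphology(nodes)


class TestRallCheck:
    def test_exact_rall_tree_r2_one(self):
        # vary the trunk diameter across cells so the correlation is defined
        cells = [symmetric_rall_tree(d0=d) for d in (2.0, 3.0, 4.0, 5.0)]
        res = rall_check(cells)
        assert res["sum_rule_r2"]["basal"] == pytest.approx(1.0)

    def test_matches_pearson_on_oracle_vectors(self, small_trees):
        cells = small_trees[:10]
        res = rall_check(cells)
        xs, ys = [], []
        for m in cells:
            for n in m.dendritic_nodes():
                kids = m.dendritic_children(n.node_id)
                if len(kids) >= 2:
                    xs.append(n.diameter ** 1.5)
                    ys.append(sum(k.diameter ** 1.5 for k in kids))
        assert res["sum_rule_r2"]["basal"] == pytest.approx(pearson_r2(xs, ys))

    def test_no_branch_points_empty(self, chain):
        assert rall_check([chain])["sum_rule_r2"] == {}


class TestPDEquality:
    def test_uniform_chain_is_one(self):
        nodes = [MorphNode(1, 1, 0, 0, 0, 1.0, -1)]
        for i in range(2, 8):
            nodes.append(MorphNode(i, 3, (i - 1) * 5.0, 0, 0, 1.0, i - 1))
        tab = feature_table([Morphology(nodes)])
        assert pd_equality_fraction(tab) == pytest.approx(1.0)

    def test_tapering_chain_is_zero(self, chain):
        tab = feature_table([chain])
        assert pd_equality_fraction(tab) == pytest.approx(0.0)

    def test_planted_fraction(self):
        # chain where exactly 4 of 9 continuing nodes keep the parent diameter
        radii = [1.0, 1.0, 0.9, 0.9, 0.9, 0.8, 0.7, 0.7, 0.6, 0.5]
        nodes = [MorphNode(1, 1, 0, 0, 0, 2.0, -1)]
        for i, r in enumerate(radii, start=2):
            nodes.append(MorphNode(i, 3, (i - 1) * 5.0, 0, 0, r, i - 1))
        tab = feature_table([Morphology(nodes)])
        planted = 4 / 9
        assert pd_equality_fraction(tab) == pytest.approx(planted)


def ar1_chain(seed, rho=0.9, n=600, sd=0.1):
    rng = np.random.default_rng(seed)
    nodes = [MorphNode(1, 1, 0, 0, 0, 5, -1)]
    x = rng.normal(0, sd / math.sqrt(1 - rho**2))  # stationary start
    for i in range(n):
        x = rho * x + rng.normal(0, sd)
        nodes.append(MorphNode(i + 2, 3, (i + 1) * 2.0, 0, 0, (2.0 + x) / 2, i + 1))
    return Morphology(nodes)


def effective_lambda(fit):
    """Lag where the fitted decay reaches 1/e of its amplitude."""
    tot = fit.A1 + fit.A2
    f = lambda k: (fit.A1 * math.exp(-k / fit.lambda1)
                   + fit.A2 * math.exp(-k / fit.lambda2) - tot / math.e)
    return brentq(f, 1e-6, 1e4)


class TestAutocorrelation:
    def test_ar1_single_exponential_limit(self):
        rho = 0.9
        cells = [ar1_chain(s, rho=rho) for s in range(12)]
        fit = diameter_autocorrelation(cells, max_lag=15)
        lam_true = -1.0 / math.log(rho)
        assert effective_lambda(fit) == pytest.approx(lam_true, rel=0.10)
        assert fit.acf[0] == pytest.approx(1.0)
        assert fit.lambda1 <= fit.lambda2

    def test_constant_diameters_undefined(self):
        nodes = [MorphNode(1, 1, 0, 0, 0, 2, -1)]
        for i in range(2, 30):
            nodes.append(MorphNode(i, 3, (i - 1) * 2.0, 0, 0, 1.0, i - 1))
        with pytest.raises(UndefinedStatisticError):
            diameter_autocorrelation([Morphology(nodes)], max_lag=5)

    def test_two_population_ordering(self):
        fast = [ar1_chain(s, rho=0.5) for s in range(6)]
        slow = [ar1_chain(100 + s, rho=0.97) for s in range(6)]
        fit = diameter_autocorrelation(fast + slow, max_lag=20)
        assert fit.lambda1 < fit.lambda2
        assert fit.A1 >= 0 and fit.A2 >= 0

    def test_short_paths_shrink_lag_range(self):
        cells = [ar1_chain(s, n=12) for s in range(4)]
        with pytest.warns(UserWarning, match="shrinking lag range"):
            fit = diameter_autocorrelation(cells, max_lag=20)
        assert fit.lags[-1] < 20


class TestOLSProperties:
    """Scale properties of regression through the origin (hypothesis)."""

    from hypothesis import given, settings, strategies as st

    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 2**20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_coefficients_scale_with_response(self, scale, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.1, 3.0, size=(20, 2))
        y = X @ np.array([0.7, 0.1]) + rng.normal(0, 0.05, 20)
        a = ols_no_intercept(X, y)
        b = ols_no_intercept(X, y * scale)
        assert np.allclose(np.array(b.coefficients),
                           scale * np.array(a.coefficients), rtol=1e-9)
        assert b.r2 == pytest.approx(a.r2, abs=1e-9)

    @given(shift=st.floats(-5.0, 5.0), gain=st.floats(0.1, 10.0),
           seed=st.integers(0, 2**20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_pearson_r2_affine_invariant(self, shift, gain, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(0, 0.5, 25)
        assert pearson_r2(gain * x + shift, y) == pytest.approx(
            pearson_r2(x, y), abs=1e-9
        )
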