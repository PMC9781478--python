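import numpy as np
import pandas as pd
import pytest

from pulsebp import rulefit as rf
from pulsebp.errors import InvalidParameterError, SchemaError


def _frame(n=64, p=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])


class TestRuleGeneration:
    def test_stump_yields_two_complementary_rules(self):
        X = _frame(100, 1, seed=1)
        y = (X["x0"] > 0).astype(float).to_numpy()
        rules = rf.build_rule_ensemble(X, y, tree_size_mean=2, n_trees=1, subsample=1.0, seed=0)
        assert len(rules) == 2
        relations = sorted(r.conditions[0].relation for r in rules)
        assert relations == ["<=", ">"]
        # complementary: supports sum to 1
        assert rules[0].support + rules[1].support == pytest.approx(1.0)

    def test_three_leaf_tree_yields_four_rules(self):
        X = _frame(200, 2, seed=2)
        y = X["x0"].to_numpy() + (X["x1"] > 0.3) * 2.0
        rng = np.random.default_rng(0)
        tree_rules = []
        from sklearn.tree import DecisionTreeRegressor

        tree = DecisionTreeRegressor(max_leaf_nodes=3, random_state=0).fit(X.to_numpy(), y)
        tree_rules = rf._rules_from_tree(tree, list(X.columns))
        # a 3-leaf binary tree has 5 nodes, 4 of them non-root
        assert len(tree_rules) == 4

    def test_rule_list_deterministic_in_seed(self):
        X = _frame(150, 3, seed=3)
        y = X["x0"].to_numpy() * X["x1"].to_numpy()
        a = rf.build_rule_ensemble(X, y, n_trees=20, seed=42)
        b = rf.build_rule_ensemble(X, y, n_trees=20, seed=42)
        assert [r.key() for r in a] == [r.key() for r in b]

    def test_tree_size_draw_mean(self):
        rng = np.random.default_rng(0)
        sizes = rf._draw_tree_sizes(20000, 3.0, rng)
        assert sizes.min() >= 2
        assert abs(sizes.mean() - 3.0) < 0.05

    def test_invalid_params_rejected(self):
        X, y = _frame(10), np.zeros(10)
        with pytest.raises(InvalidParameterError):
            rf.build_rule_ensemble(X, y, n_trees=0)
        with pytest.raises(InvalidParameterError):
            rf._draw_tree_sizes(5, 1.0, np.random.default_rng(0))


class TestWinsorize:
    def test_delta_zero_is_identity(self):
        X = _frame(50, 1, seed=4)
        (term,) = rf.winsorize_linear_terms(X[["x0"]], delta=0.0)
        np.testing.assert_array_equal(term.evaluate(X), X["x0"].to_numpy())
        assert term.sd == pytest.approx(float(X["x0"].std(ddof=0)))

    def test_quantile_bounds_on_integers(self):
        X = pd.DataFrame({"x": np.arange(100.0)})
        (term,) = rf.winsorize_linear_terms(X, delta=0.05)
        assert term.winsor_lo == pytest.approx(4.95)
        assert term.winsor_hi == pytest.approx(94.05)

    def test_constant_column_gets_zero_sd(self):
        X = pd.DataFrame({"x": np.ones(30)})
        (term,) = rf.winsorize_linear_terms(X)
        assert term.sd == 0.0

    def test_invalid_delta_rejected(self):
        with pytest.raises(InvalidParameterError):
            rf.winsorize_linear_terms(_frame(10, 1), delta=0.5)


class TestSparseFit:
    def test_infinite_penalty_gives_intercept_only(self):
        X = _frame(80, 2, seed=5)
        y = 3.0 * X["x0"].to_numpy() + 1.0
        terms = rf.winsorize_linear_terms(X, delta=0.0)
        model = rf.fit_sparse_linear([], terms, X, y, mode="linear_only", penalty_grid=1e9)
        assert model.n_nonzero_terms == 0
        assert model.intercept == pytest.approx(float(np.mean(y)))

    def test_zero_penalty_matches_ols_slope(self):
        X = _frame(40, 1, seed=6)
        rng = np.random.default_rng(7)
        y = 2.5 * X["x0"].to_numpy() - 1.0 + rng.normal(0, 0.1, 40)
        terms = rf.winsorize_linear_terms(X, delta=0.0)
        model = rf.fit_sparse_linear([], terms, X, y, mode="linear_only", penalty_grid=0.0)
        x = X["x0"].to_numpy()
        slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
        assert model.linear_terms[0].coefficient == pytest.approx(slope, abs=1e-6)

    def test_small_instance_matches_normal_equations(self):
        # <=8 rows, 2 candidate terms, penalty 0: must equal the
        # normal-equations solution
        X = pd.DataFrame({"x0": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0], "x1": [1, 0, 2, 1, 3, 2.0]})
        y = np.array([0.3, 1.1, 2.3, 2.8, 4.5, 4.9])
        terms = rf.winsorize_linear_terms(X, delta=0.0)
        model = rf.fit_sparse_linear([], terms, X, y, mode="linear_only", penalty_grid=0.0)
        A = np.column_stack([np.ones(6), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        got = [model.intercept] + [t.coefficient for t in model.linear_terms]
        np.testing.assert_allclose(got, beta, atol=1e-6)

    def test_lasso_path_sparsity_monotone_in_penalty(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(200, 6)), columns=[f"x{i}" for i in range(6)])
        y = X["x0"].to_numpy() * 2 + X["x1"].to_numpy() - 0.5 * X["x2"].to_numpy()
        y = y + rng.normal(0, 0.2, 200)
        terms = rf.winsorize_linear_terms(X, delta=0.0)
        counts = []
        for alpha in [3.0, 1.0, 0.3, 0.1, 0.03, 0.01]:
            m = rf.fit_sparse_linear([], terms, X, y, mode="linear_only", penalty_grid=alpha)
            counts.append(m.n_nonzero_terms)
        assert counts == sorted(counts)

    def test_empty_penalty_grid_rejected(self):
        X = _frame(20, 1)
        terms = rf.winsorize_linear_terms(X)
        with pytest.raises(InvalidParameterError):
            rf.fit_sparse_linear([], terms, X, np.zeros(20), mode="linear_only", penalty_grid=[])

    def test_seeded_fit_is_deterministic(self):
        X = _frame(150, 3, seed=9)
        y = (X["x0"] > 0).to_numpy() * 2.0 + X["x1"].to_numpy()
        a = rf.fit_rulefit(X, y, n_trees=30, seed=5)
        b = rf.fit_rulefit(X, y, n_trees=30, seed=5)
        assert rf.model_to_json(a) == rf.model_to_json(b)


class TestPredict:
    def test_single_rule_hand_evaluation(self):
        rule = rf.Rule((rf.Condition("x1", ">", 0.0),), coefficient=2.0, support=0.5)
        model = rf.RuleEnsembleModel(
            mode="rules_only",
            intercept=1.0,
            rules=[rule],
            linear_terms=[],
            tree_size_mean=2,
            n_trees=1,
            shrinkage=0.1,
            l1_penalty=0.0,
            seed=0,
        )
        X = pd.DataFrame({"x1": [5.0, -5.0]})
        np.testing.assert_allclose(model.predict(X), [3.0, 1.0])

    def test_missing_variable_raises_schema_error(self):
        rule = rf.Rule((rf.Condition("x9", ">", 0.0),), coefficient=1.0, support=0.5)
        model = rf.RuleEnsembleModel(
            mode="rules_only",
            intercept=0.0,
            rules=[rule],
            linear_terms=[],
            tree_size_mean=2,
            n_trees=1,
            shrinkage=0.1,
            l1_penalty=0.0,
            seed=0,
        )
        with pytest.raises(SchemaError):
            model.predict(pd.DataFrame({"x1": [1.0]}))

    def test_json_roundtrip_preserves_predictions(self):
        X = _frame(100, 3, seed=10)
        y = (X["x0"] > 0).to_numpy() * 1.5 + X["x2"].to_numpy()
        model = rf.fit_rulefit(X, y, n_trees=20, seed=1)
        back = rf.model_from_json(rf.model_to_json(model))
        np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-12)


class TestImportance:
    def _model(self, rules=(), terms=()):
        return rf.RuleEnsembleModel(
            mode="rules_plus_linear",
            intercept=0.0,
            rules=list(rules),
            linear_terms=list(terms),
            tree_size_mean=3,
            n_trees=1,
            shrinkage=0.1,
            l1_penalty=0.0,
            seed=0,
        )

    def test_rule_importance_hand_cases(self):
        cases = [(0.5, 2.0, 1.0), (0.0, 2.0, 0.0), (1.0, 2.0, 0.0)]
        for support, coef, expected in cases:
            model = self._model(
                rules=[rf.Rule((rf.Condition("x", ">", 0),), coefficient=coef, support=support)]
            )
            assert rf.term_importance(model)["importance"].iloc[0] == pytest.approx(expected)

    def test_zero_coefficient_linear_term_zero_importance(self):
        model = self._model(terms=[rf.LinearTerm("x", coefficient=0.0, sd=3.0)])
        assert rf.term_importance(model)["importance"].iloc[0] == 0.0

    def test_constant_column_zero_importance_despite_coefficient(self):
        model = self._model(terms=[rf.LinearTerm("x", coefficient=5.0, sd=0.0)])
        assert rf.term_importance(model)["importance"].iloc[0] == 0.0

    def test_single_linear_term_variable_gets_100(self):
        model = self._model(
            terms=[
                rf.LinearTerm("a", coefficient=2.0, sd=1.0),
                rf.LinearTerm("b", coefficient=0.0, sd=1.0),
            ]
        )
        vi = rf.variable_importance(model)
        assert vi["a"] == 100.0 and vi["b"] == 0.0

    def test_two_variable_rule_importance_splits_equally(self):
        rule = rf.Rule(
            (rf.Condition("a", ">", 0), rf.Condition("b", "<=", 1)), coefficient=2.0, support=0.5
        )
        vi = rf.variable_importance(self._model(rules=[rule]), normalize=False)
        assert vi["a"] == pytest.approx(vi["b"])

    def test_importance_conservation_over_variables(self):
        X = _frame(300, 4, seed=11)
        y = (X["x0"] > 0).to_numpy() * 2 + X["x1"].to_numpy() + 0.1 * X["x2"].to_numpy()
        model = rf.fit_rulefit(X, y, n_trees=40, seed=2)
        unnorm = rf.variable_importance(model, normalize=False)
        total_terms = rf.term_importance(model)["importance"].sum()
        assert unnorm.sum() == pytest.approx(total_terms, rel=1e-9)


class TestPartialDependence:
    def test_linear_model_pd_slope_equals_coefficient(self):
        X = _frame(200, 2, seed=12)
        terms = [
            rf.LinearTerm("x0", coefficient=1.7, winsor_lo=-np.inf, winsor_hi=np.inf, sd=1.0),
            rf.LinearTerm("x1", coefficient=-0.6, winsor_lo=-np.inf, winsor_hi=np.inf, sd=1.0),
        ]
        model = rf.RuleEnsembleModel(
            mode="linear_only",
            intercept=0.3,
            rules=[],
            linear_terms=terms,
            tree_size_mean=3,
            n_trees=1,
            shrinkage=0.1,
            l1_penalty=0.0,
            seed=0,
        )
        grid = rf.partial_dependence(model, X, "x0")
        slopes = np.diff(grid["pd"]) / np.diff(grid["x0"])
        np.testing.assert_allclose(slopes, 1.7, atol=1e-9)

    def test_variable_absent_from_model_gives_flat_pd(self):
        X = _frame(100, 2, seed=13)
        model = rf.RuleEnsembleModel(
            mode="linear_only",
            intercept=2.0,
            rules=[],
            linear_terms=[rf.LinearTerm("x0", coefficient=1.0, sd=1.0)],
            tree_size_mean=3,
            n_trees=1,
            shrinkage=0.1,
            l1_penalty=0.0,
            seed=0,
        )
        grid = rf.partial_dependence(model, X, "x1")
        assert grid["pd"].nunique() == 1

    def test_two_variable_grid_shape(self):
        X = _frame(50, 2, seed=14)
        model = rf.RuleEnsembleModel(
            mode="linear_only",
            intercept=0.0,
            rules=[],
            linear_terms=[rf.LinearTerm("x0", coefficient=1.0, sd=1.0)],
            tree_size_mean=3,
            n_trees=1,
            shrinkage=0.1,
            l1_penalty=0.0,
            seed=0,
        )
        grid = rf.partial_dependence(model, X, ["x0", "x1"])
        assert len(grid) == 81  # 9 x 9 decile grid


class TestInteractionStrength:
    def test_additive_target_yields_no_flags(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(400, 3)), columns=["a", "b", "c"])
        y = 2 * X["a"].to_numpy() + np.abs(X["b"].to_numpy())
        report = rf.interaction_strength(
            X, y, model_params=dict(n_trees=60), n_null=10, seed=0, n_eval=80
        )
        assert ((report["H"] >= 0) & (report["H"] <= 1)).all()
        for v in report.index:
            assert report.loc[v, "H"] <= report.loc[v, "null_mean"] + 2 * report.loc[v, "null_sd"]

    def test_product_interaction_detected(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "noise"])
        y = X["a"].to_numpy() * X["b"].to_numpy() + rng.normal(0, 0.1, 500)
        report = rf.interaction_strength(
            X, y, model_params=dict(n_trees=120), n_null=10, seed=1, n_eval=100
        )
        for v in ("a", "b"):
            assert (
                report.loc[v, "H"] > report.loc[v, "null_mean"] + 3 * report.loc[v, "null_sd"]
            )
        n = report.loc["noise"]
        assert n["H"] <= n["null_mean"] + 3 * n["null_sd"]

    def test_model_without_multivariable_rules_skips_null(self):
        X = _frame(100, 2, seed=17)
        y = X["x0"].to_numpy()
        report = rf.interaction_strength(
            X, y, model_params=dict(mode="rules_only", stumps=True, n_trees=20), n_null=10, seed=0
        )
        assert (report["H"] == 0).all()
        assert (report["n_null"] == 0).all()

    def test_n_null_floor_enforced(self):
        X = _frame(30, 2)
        with pytest.raises(InvalidParameterError):
            rf.interaction_strength(X, np.zeros(30), n_null=5)
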