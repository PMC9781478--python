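"""From-scratch rule-ensemble regression (RuleFit).

The model is a sparse linear combination of two kinds of base learners:

* **rules** — binary indicators r_k(x) = prod 1{x_v <= t} extracted from the
  internal nodes of a small gradient-boosted tree ensemble (every non-root
  node contributes the conjunction of conditions on its root path), and
* **winsorized linear terms** — l_j(x_j) = min(max(x_j, q_delta), q_{1-delta})
  which keep the main effects while limiting the leverage of tails.

Coefficients are selected by an L1 (lasso) fit whose penalty is chosen by
internal cross-validation on the training split only.  Diagnostics follow
the rule-ensemble literature: term importance |a_k| sqrt(s_k (1-s_k)) for a
rule with support s_k and |b_j| sd(l_j) for a linear term; per-variable
importance distributes each rule's importance equally over its variables;
interaction strength is the Friedman-Popescu H statistic computed from
partial-dependence functions, referenced against a null distribution
obtained by refitting on additive (main-effects-only) surrogate data.

Tree growth, rule extraction, supports, importances, H and its null are
implemented here; individual regression trees and the lasso solver come
from scikit-learn.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression, lasso_path
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .errors import InvalidParameterError, SchemaError

MODES = ("linear_only", "rules_only", "rules_plus_linear")

#: Defaults for the rule generator and fit (all exposed in the pipeline config).
DEFAULT_TREE_SIZE_MEAN = 3.0
DEFAULT_N_TREES = 300
DEFAULT_SHRINKAGE = 0.01
DEFAULT_SUBSAMPLE = 0.5
DEFAULT_WINSOR_DELTA = 0.025
DEFAULT_PENALTY_GRID_SIZE = 30
DEFAULT_PENALTY_CV_FOLDS = 5

QUANTILE_METHOD = "linear"  # interpolation between order statistics, used everywhere


# ---------------------------------------------------------------------------
# Terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """One split condition ``variable <= threshold`` or ``variable > threshold``."""

    variable: str
    relation: str  # "<=" or ">"
    threshold: float

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return x <= self.threshold if self.relation == "<=" else x > self.threshold

    def describe(self) -> str:
        return f"{self.variable} {self.relation} {self.threshold:.6g}"


@dataclass
class Rule:
    """A conjunction of conditions with its fitted coefficient and support."""

    conditions: tuple[Condition, ...]
    coefficient: float = 0.0
    support: float = float("nan")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(sorted({c.variable for c in self.conditions}))

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(X), dtype=float)
        for c in self.conditions:
            if c.variable not in X.columns:
                raise SchemaError(f"rule references missing variable {c.variable!r}")
            out *= c.evaluate(X[c.variable].to_numpy(dtype=float))
        return out

    def describe(self) -> str:
        return " & ".join(c.describe() for c in self.conditions)

    def key(self) -> tuple:
        return tuple(sorted((c.variable, c.relation, c.threshold) for c in self.conditions))


@dataclass
class LinearTerm:
    """A winsorized linear term with its fitted coefficient."""

    variable: str
    coefficient: float = 0.0
    winsor_lo: float = float("-inf")
    winsor_hi: float = float("inf")
    sd: float = float("nan")  # SD of the winsorized variable on training data

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        if self.variable not in X.columns:
            raise SchemaError(f"linear term references missing variable {self.variable!r}")
        x = X[self.variable].to_numpy(dtype=float)
        return np.clip(x, self.winsor_lo, self.winsor_hi)


@dataclass
class RuleEnsembleModel:
    """A fitted rule ensemble: intercept + rules + winsorized linear terms."""

    mode: str
    intercept: float
    rules: list[Rule]
    linear_terms: list[LinearTerm]
    tree_size_mean: float
    n_trees: int
    shrinkage: float
    l1_penalty: float
    seed: int
    n_candidate_terms: int = 0
    penalty_trace: dict = field(default_factory=dict)

    @property
    def n_nonzero_terms(self) -> int:
        return sum(1 for r in self.rules if r.coefficient != 0.0) + sum(
            1 for t in self.linear_terms if t.coefficient != 0.0
        )

    @property
    def variables(self) -> list[str]:
        vs: set[str] = set()
        for r in self.rules:
            vs.update(r.variables)
        vs.update(t.variable for t in self.linear_terms)
        return sorted(vs)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self, X)


# ---------------------------------------------------------------------------
# Rule generation
# ---------------------------------------------------------------------------


def _draw_tree_sizes(
    n_trees: int, tree_size_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Terminal-node counts: 2 + floor(Exp), scaled so the mean is tree_size_mean."""
    if tree_size_mean < 2:
        raise InvalidParameterError("tree_size_mean must be >= 2")
    if tree_size_mean == 2:
        return np.full(n_trees, 2, dtype=int)
    # E[floor(Exp(scale))] = 1/(exp(1/scale)-1); choose scale so the mean
    # extra-leaf count is tree_size_mean - 2.
    extra = tree_size_mean - 2.0
    scale = 1.0 / np.log1p(1.0 / extra)
    return 2 + np.floor(rng.exponential(scale, size=n_trees)).astype(int)


def _rules_from_tree(tree: DecisionTreeRegressor, feature_names: Sequence[str]) -> list[Rule]:
    """Every non-root node contributes the conjunction along its root path.

    Within one rule, repeated conditions on the same (variable, relation)
    are collapsed to the tightest threshold.
    """
    t = tree.tree_
    rules: list[Rule] = []

    def tighten(conds: list[Condition]) -> tuple[Condition, ...]:
        best: dict[tuple[str, str], float] = {}
        for c in conds:
            key = (c.variable, c.relation)
            if key not in best:
                best[key] = c.threshold
            elif c.relation == "<=":
                best[key] = min(best[key], c.threshold)
            else:
                best[key] = max(best[key], c.threshold)
        return tuple(
            Condition(v, rel, thr) for (v, rel), thr in sorted(best.items())
        )

    def walk(node: int, conds: list[Condition]) -> None:
        if conds:
            rules.append(Rule(conditions=tighten(conds)))
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            return
        var = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(left, conds + [Condition(var, "<=", thr)])
        walk(right, conds + [Condition(var, ">", thr)])

    walk(0, [])
    return rules


def build_rule_ensemble(
    X: pd.DataFrame,
    y: np.ndarray,
    tree_size_mean: float = DEFAULT_TREE_SIZE_MEAN,
    n_trees: int = DEFAULT_N_TREES,
    shrinkage: float = DEFAULT_SHRINKAGE,
    subsample: float = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> list[Rule]:
    """Generate candidate rules by gradient boosting on squared loss.

    Each boosting step fits a small regression tree (terminal-node count
    drawn so its mean is ``tree_size_mean``, minimum 2) to the current
    residuals on a random row subsample; all non-root nodes become
    candidate rules.  Duplicates are removed and supports are computed on
    the full training data.
    """
    if n_trees < 1:
        raise InvalidParameterError("n_trees must be >= 1")
    if not 0 < subsample <= 1:
        raise InvalidParameterError("subsample must be in (0, 1]")
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise InvalidParameterError("X and y must have the same number of rows")
    rng = np.random.default_rng(seed)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    sizes = _draw_tree_sizes(n_trees, tree_size_mean, rng)
    f = np.full(n, float(np.mean(y)))
    rules: list[Rule] = []
    seen: set[tuple] = set()
    n_sub = max(2, int(round(subsample * n)))
    for m in range(n_trees):
        residual = y - f
        idx = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        tree = DecisionTreeRegressor(
            max_leaf_nodes=max(2, int(sizes[m])),
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xv[idx], residual[idx])
        f += shrinkage * tree.predict(Xv)
        for rule in _rules_from_tree(tree, names):
            k = rule.key()
            if k not in seen:
                seen.add(k)
                rules.append(rule)
    for rule in rules:
        rule.support = float(np.mean(rule.evaluate(X)))
    return rules


def winsorize_linear_terms(
    X: pd.DataFrame, delta: float = DEFAULT_WINSOR_DELTA
) -> list[LinearTerm]:
    """Build one winsorized linear term per column.

    Clipping bounds are the ``delta`` and ``1-delta`` empirical quantiles
    (linear interpolation between order statistics).  A constant column
    yields a term with sd = 0, hence zero importance.
    """
    if not 0 <= delta < 0.5:
        raise InvalidParameterError("delta must be in [0, 0.5)")
    terms = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if delta > 0:
            lo, hi = np.quantile(x, [delta, 1.0 - delta], method=QUANTILE_METHOD)
        else:
            lo, hi = -np.inf, np.inf
        clipped = np.clip(x, lo, hi)
        terms.append(
            LinearTerm(
                variable=col,
                winsor_lo=float(lo),
                winsor_hi=float(hi),
                sd=float(np.std(clipped)),
            )
        )
    return terms


# ---------------------------------------------------------------------------
# Sparse fit
# ---------------------------------------------------------------------------


def _design_matrix(
    rules: Sequence[Rule], linear_terms: Sequence[LinearTerm], X: pd.DataFrame
) -> np.ndarray:
    cols = [r.evaluate(X) for r in rules] + [t.evaluate(X) for t in linear_terms]
    if not cols:
        return np.empty((len(X), 0))
    return np.column_stack(cols)


def _default_penalty_grid(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(y)
    yc = y - y.mean()
    alpha_max = float(np.max(np.abs(Z.T @ yc)) / n) if Z.shape[1] else 1.0
    alpha_max = max(alpha_max, 1e-12)
    return np.geomspace(alpha_max, alpha_max * 3e-3, DEFAULT_PENALTY_GRID_SIZE)


def fit_sparse_linear(
    rules: Sequence[Rule],
    linear_terms: Sequence[LinearTerm],
    X: pd.DataFrame,
    y: np.ndarray,
    mode: str = "rules_plus_linear",
    penalty_grid: Sequence[float] | float | None = None,
    cv_folds: int = DEFAULT_PENALTY_CV_FOLDS,
    seed: int = 0,
    tree_size_mean: float = DEFAULT_TREE_SIZE_MEAN,
    n_trees: int = DEFAULT_N_TREES,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> RuleEnsembleModel:
    """L1-penalized squared-error fit over the mode's term set.

    The design has one column per rule indicator and per winsorized linear
    term; columns are standardized internally and coefficients are reported
    back on the original term scale.  ``penalty_grid`` may be a scalar (used
    as-is; 0 means ordinary least squares), an explicit grid, or None for a
    data-driven log-spaced grid.  With a grid, the penalty is chosen by
    ``cv_folds``-fold cross-validation on the training split only.
    """
    if mode not in MODES:
        raise InvalidParameterError(f"mode must be one of {MODES}")
    if mode == "linear_only":
        rules = []
    if mode == "rules_only":
        linear_terms = []
    rules = [Rule(r.conditions, 0.0, r.support) for r in rules]
    linear_terms = [
        LinearTerm(t.variable, 0.0, t.winsor_lo, t.winsor_hi, t.sd) for t in linear_terms
    ]
    if not rules and not linear_terms:
        raise InvalidParameterError(f"mode {mode!r} has no candidate terms")
    y = np.asarray(y, dtype=float)
    Z = _design_matrix(rules, linear_terms, X)
    n, p = Z.shape

    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    usable = sd > 0
    Zs = np.zeros_like(Z)
    Zs[:, usable] = (Z[:, usable] - mu[usable]) / sd[usable]

    trace: dict = {}
    scalar_penalty: float | None = None
    if penalty_grid is None:
        grid = _default_penalty_grid(Zs[:, usable], y)
    elif np.isscalar(penalty_grid):
        scalar_penalty = float(penalty_grid)
        grid = None
    else:
        grid = np.asarray(list(penalty_grid), dtype=float)
        if grid.size == 0:
            raise InvalidParameterError("penalty grid is empty")
        if grid.size == 1:
            scalar_penalty = float(grid[0])
            grid = None

    def fit_at(alpha: float, Zm: np.ndarray, ym: np.ndarray):
        if alpha == 0.0:
            reg = LinearRegression()
        else:
            reg = Lasso(alpha=alpha, max_iter=20000, tol=1e-4)
        reg.fit(Zm, ym)
        return reg

    if grid is not None:
        # warm-started coordinate-descent path per fold: far cheaper than
        # independent fits across the grid
        grid = np.sort(grid)[::-1]
        kf = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=seed % (2**31))
        errors = np.zeros(grid.size)
        for tr, te in kf.split(Zs):
            Ztr = Zs[tr][:, usable]
            ytr = y[tr]
            mu_tr, ybar = Ztr.mean(axis=0), ytr.mean()
            _, coefs, _ = lasso_path(
                Ztr - mu_tr, ytr - ybar, alphas=grid, max_iter=20000, tol=1e-4
            )
            pred = (Zs[te][:, usable] - mu_tr) @ coefs + ybar  # (n_te, n_alphas)
            errors += np.sum((pred - y[te][:, None]) ** 2, axis=0)
        best = int(np.argmin(errors))
        chosen = float(grid[best])
        trace = {"grid": grid.tolist(), "cv_sse": errors.tolist(), "chosen": chosen}
    else:
        chosen = scalar_penalty
        trace = {"grid": [chosen], "chosen": chosen}

    reg = fit_at(chosen, Zs[:, usable], y)
    beta_std = np.zeros(p)
    beta_std[usable] = reg.coef_
    beta = np.zeros(p)
    beta[usable] = beta_std[usable] / sd[usable]
    intercept = float(reg.intercept_ - np.sum(beta[usable] * mu[usable]))

    for i, r in enumerate(rules):
        r.coefficient = float(beta[i])
    for j, t in enumerate(linear_terms):
        t.coefficient = float(beta[len(rules) + j])

    return RuleEnsembleModel(
        mode=mode,
        intercept=intercept,
        rules=rules,
        linear_terms=linear_terms,
        tree_size_mean=tree_size_mean,
        n_trees=n_trees,
        shrinkage=shrinkage,
        l1_penalty=chosen,
        seed=seed,
        n_candidate_terms=p,
        penalty_trace=trace,
    )


def fit_rulefit(
    X: pd.DataFrame,
    y: np.ndarray,
    mode: str = "rules_plus_linear",
    tree_size_mean: float = DEFAULT_TREE_SIZE_MEAN,
    n_trees: int = DEFAULT_N_TREES,
    shrinkage: float = DEFAULT_SHRINKAGE,
    subsample: float = DEFAULT_SUBSAMPLE,
    winsor_delta: float = DEFAULT_WINSOR_DELTA,
    penalty_grid: Sequence[float] | float | None = None,
    cv_folds: int = DEFAULT_PENALTY_CV_FOLDS,
    seed: int = 0,
    stumps: bool | None = None,
) -> RuleEnsembleModel:
    """Convenience wrapper: generate terms for ``mode`` and run the sparse fit.

    In ``rules_only`` mode trees are forced to stumps by default, which
    yields single-variable rules and hence a purely additive
    (main-effects-only) model; pass ``stumps=False`` to keep full trees.
    """
    if stumps is None:
        stumps = mode == "rules_only"
    rules: list[Rule] = []
    if mode != "linear_only":
        rules = build_rule_ensemble(
            X,
            y,
            tree_size_mean=2.0 if stumps else tree_size_mean,
            n_trees=n_trees,
            shrinkage=shrinkage,
            subsample=subsample,
            seed=seed,
        )
    linear_terms = winsorize_linear_terms(X, winsor_delta) if mode != "rules_only" else []
    return fit_sparse_linear(
        rules,
        linear_terms,
        X,
        y,
        mode=mode,
        penalty_grid=penalty_grid,
        cv_folds=cv_folds,
        seed=seed,
        tree_size_mean=2.0 if stumps else tree_size_mean,
        n_trees=n_trees,
        shrinkage=shrinkage,
    )


# ---------------------------------------------------------------------------
# Prediction & diagnostics
# ---------------------------------------------------------------------------


def predict(model: RuleEnsembleModel, X: pd.DataFrame) -> np.ndarray:
    """intercept + sum a_k r_k(x) + sum b_j l_j(x_j)."""
    out = np.full(len(X), model.intercept, dtype=float)
    for r in model.rules:
        if r.coefficient != 0.0:
            out += r.coefficient * r.evaluate(X)
    for t in model.linear_terms:
        if t.coefficient != 0.0:
            out += t.coefficient * t.evaluate(X)
    return out


def term_importance(model: RuleEnsembleModel) -> pd.DataFrame:
    """Global term importances, descending (deterministic tie-break by id).

    Rules: ``|a_k| sqrt(s_k (1 - s_k))``; linear terms: ``|b_j| sd(l_j)``.
    """
    rows = []
    for i, r in enumerate(model.rules):
        imp = abs(r.coefficient) * float(np.sqrt(r.support * (1.0 - r.support)))
        rows.append(
            {
                "term_id": f"rule_{i:05d}",
                "kind": "rule",
                "description": r.describe(),
                "coefficient": r.coefficient,
                "support": r.support,
                "importance": imp,
            }
        )
    for j, t in enumerate(model.linear_terms):
        rows.append(
            {
                "term_id": f"linear_{t.variable}",
                "kind": "linear",
                "description": t.variable,
                "coefficient": t.coefficient,
                "support": np.nan,
                "importance": abs(t.coefficient) * t.sd,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["importance", "term_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def variable_importance(model: RuleEnsembleModel, normalize: bool = True) -> pd.Series:
    """Per-variable importance, max scaled to 100 when ``normalize``.

    A variable receives its linear-term importance plus, for every rule it
    appears in, that rule's importance divided by the number of variables in
    the rule.
    """
    imp: dict[str, float] = {v: 0.0 for v in model.variables}
    for r in model.rules:
        rimp = abs(r.coefficient) * float(np.sqrt(r.support * (1.0 - r.support)))
        if rimp == 0.0:
            continue
        share = rimp / len(r.variables)
        for v in r.variables:
            imp[v] = imp.get(v, 0.0) + share
    for t in model.linear_terms:
        imp[t.variable] = imp.get(t.variable, 0.0) + abs(t.coefficient) * t.sd
    s = pd.Series(imp, dtype=float).sort_values(ascending=False)
    if normalize and len(s) and s.max() > 0:
        s = 100.0 * s / s.max()
    return s


def partial_dependence(
    model: RuleEnsembleModel, X: pd.DataFrame, variables: str | Sequence[str]
) -> pd.DataFrame:
    """Partial dependence over decile grids of one or two variables.

    pd(v) is the mean prediction over the training rows with the chosen
    variable(s) clamped to v; the grid is the 10th..90th percentiles.
    """
    if isinstance(variables, str):
        variables = [variables]
    variables = list(variables)
    if not 1 <= len(variables) <= 2:
        raise InvalidParameterError("partial dependence supports 1 or 2 variables")
    for v in variables:
        if v not in X.columns:
            raise SchemaError(f"variable {v!r} not in X")
    grids = [
        np.quantile(X[v].to_numpy(dtype=float), np.arange(0.1, 0.91, 0.1), method=QUANTILE_METHOD)
        for v in variables
    ]
    rows = []
    if len(variables) == 1:
        for val in grids[0]:
            Xc = X.copy()
            Xc[variables[0]] = val
            rows.append({variables[0]: val, "pd": float(np.mean(predict(model, Xc)))})
    else:
        for v0 in grids[0]:
            for v1 in grids[1]:
                Xc = X.copy()
                Xc[variables[0]] = v0
                Xc[variables[1]] = v1
                rows.append(
                    {
                        variables[0]: v0,
                        variables[1]: v1,
                        "pd": float(np.mean(predict(model, Xc))),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Interaction strength (Friedman-Popescu H)
# ---------------------------------------------------------------------------


def _h_statistics(
    model: RuleEnsembleModel, X: pd.DataFrame, variables: Sequence[str]
) -> dict[str, float]:
    """H_j for each variable, from partial dependence evaluated on the rows.

    H_j^2 = sum_i [F(x_i) - PD_j(x_ij) - PD_{-j}(x_i,-j)]^2 / sum_i F(x_i)^2
    with all functions centered over the evaluation rows.  Both PD functions
    come from one n x n prediction matrix M[i, k] = F(x_j from row k, x_-j
    from row i): column means give PD_j, row means PD_{-j}.
    """
    n = len(X)
    f = predict(model, X)
    f_c = f - f.mean()
    denom = float(np.sum(f_c**2))
    out: dict[str, float] = {}
    for v in variables:
        if denom == 0.0:
            out[v] = 0.0
            continue
        big = pd.concat([X] * n, ignore_index=True)
        big[v] = np.tile(X[v].to_numpy(), n).reshape(n, n).T.reshape(-1)
        # row block i of `big` holds x_-j from row i with x_j swept over all rows
        M = predict(model, big).reshape(n, n)
        pd_j = M.mean(axis=0)  # over complements, one value per x_j (column k)
        pd_rest = M.mean(axis=1)  # over x_j values, one value per complement (row i)
        resid = f_c - (pd_j - pd_j.mean()) - (pd_rest - pd_rest.mean())
        out[v] = float(np.sqrt(np.clip(np.sum(resid**2) / denom, 0.0, 1.0)))
    return out


def interaction_strength(
    X: pd.DataFrame,
    y: np.ndarray,
    model_params: Mapping | None = None,
    variables: Sequence[str] | None = None,
    n_null: int = 20,
    seed: int = 0,
    n_eval: int = 200,
    model: RuleEnsembleModel | None = None,
) -> pd.DataFrame:
    """Interaction strength per variable with a null reference distribution.

    The full model's H_j (normalized departure from additivity in variable
    j, in [0, 1]) is compared with H_j values obtained by refitting the same
    model on ``n_null`` surrogate datasets that are additive by
    construction: predictions of a main-effects-only model (stump rules +
    linear terms) plus resampled residuals.  A variable is flagged when its
    H exceeds null_mean + 2 null_sd.

    Returns a frame indexed by variable with columns ``H, null_mean,
    null_sd, n_null, flag``.
    """
    if n_null < 10:
        raise InvalidParameterError("n_null must be >= 10")
    params = dict(model_params or {})
    params.setdefault("mode", "rules_plus_linear")
    variables = list(variables) if variables is not None else list(X.columns)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)

    if model is None:
        model = fit_rulefit(X, y, **params)

    idx = (
        rng.choice(len(X), size=n_eval, replace=False)
        if len(X) > n_eval
        else np.arange(len(X))
    )
    X_eval = X.iloc[idx].reset_index(drop=True)

    multi = any(len(r.variables) >= 2 and r.coefficient != 0.0 for r in model.rules)
    if not multi:
        return pd.DataFrame(
            {
                "H": 0.0,
                "null_mean": np.nan,
                "null_sd": np.nan,
                "n_null": 0,
                "flag": False,
            },
            index=pd.Index(variables, name="variable"),
        )

    h_obs = _h_statistics(model, X_eval, variables)

    # Additive surrogate: main-effects-only fit + resampled residuals.
    additive_params = dict(params)
    additive_params["mode"] = "rules_only"
    additive_params["stumps"] = True
    additive = fit_rulefit(X, y, **additive_params)
    f_add = predict(additive, X)
    resid = y - f_add

    null_h: dict[str, list[float]] = {v: [] for v in variables}
    for rep in range(n_null):
        y_null = f_add + rng.choice(resid, size=len(resid), replace=True)
        rep_params = dict(params)
        rep_params["seed"] = int(rng.integers(0, 2**31 - 1))
        m_null = fit_rulefit(X, y_null, **rep_params)
        h_rep = _h_statistics(m_null, X_eval, variables)
        for v in variables:
            null_h[v].append(h_rep[v])

    rows = {}
    for v in variables:
        arr = np.asarray(null_h[v])
        mean, sd = float(arr.mean()), float(arr.std(ddof=1))
        rows[v] = {
            "H": h_obs[v],
            "null_mean": mean,
            "null_sd": sd,
            "n_null": n_null,
            "flag": h_obs[v] > mean + 2.0 * sd,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "variable"
    return df


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def model_to_json(model: RuleEnsembleModel, path: str | Path | None = None) -> str:
    payload = {
        "mode": model.mode,
        "intercept": model.intercept,
        "rules": [
            {
                "conditions": [
                    {"variable": c.variable, "relation": c.relation, "threshold": c.threshold}
                    for c in r.conditions
                ],
                "coefficient": r.coefficient,
                "support": r.support,
            }
            for r in model.rules
        ],
        "linear_terms": [
            {
                "variable": t.variable,
                "coefficient": t.coefficient,
                "winsor_lo": t.winsor_lo,
                "winsor_hi": t.winsor_hi,
                "sd": t.sd,
            }
            for t in model.linear_terms
        ],
        "tree_size_mean": model.tree_size_mean,
        "n_trees": model.n_trees,
        "shrinkage": model.shrinkage,
        "l1_penalty": model.l1_penalty,
        "seed": model.seed,
        "n_candidate_terms": model.n_candidate_terms,
        "penalty_trace": model.penalty_trace,
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> RuleEnsembleModel:
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if not text.lstrip().startswith("{"):  # a file path, not JSON text
            text = Path(text).read_text()
    payload = json.loads(text)
    rules = [
        Rule(
            conditions=tuple(
                Condition(c["variable"], c["relation"], c["threshold"])
                for c in r["conditions"]
            ),
            coefficient=r["coefficient"],
            support=r["support"],
        )
        for r in payload["rules"]
    ]
    terms = [
        LinearTerm(
            variable=t["variable"],
            coefficient=t["coefficient"],
            winsor_lo=t["winsor_lo"],
            winsor_hi=t["winsor_hi"],
            sd=t["sd"],
        )
        for t in payload["linear_terms"]
    ]
    return RuleEnsembleModel(
        mode=payload["mode"],
        intercept=payload["intercept"],
        rules=rules,
        linear_terms=terms,
        tree_size_mean=payload["tree_size_mean"],
        n_trees=payload["n_trees"],
        shrinkage=payload["shrinkage"],
        l1_penalty=payload["l1_penalty"],
        seed=payload["seed"],
        n_candidate_terms=payload["n_candidate_terms"],
        penalty_trace=payload.get("penalty_trace", {}),
    )
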