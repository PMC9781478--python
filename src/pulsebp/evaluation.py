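"""Evaluation protocol: error metrics, 10-fold CV, model-variant comparison,
improvement arithmetic, and the paired rest-vs-WBT comparison.

Model accuracy is summarized by MAE and RMSE over *pooled* held-out
predictions from a seeded k-fold split (pooling the concatenated errors, not
averaging per-fold metrics).  Three model variants are compared: a purely
linear model, an additive rules-only model (stump rules, main effects only)
and the full rules-plus-linear ensemble.  The physiological state effect is
assessed with an exact two-sided Wilcoxon signed-rank test on per-subject
means (the study-relevant pairing unit; n is the number of subjects, so the
normal approximation would be invalid and the exact distribution is used).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon
from sklearn.model_selection import GroupKFold, KFold

from .errors import InvalidParameterError, SchemaError
from .rulefit import MODES, RuleEnsembleModel, fit_rulefit, predict


def error_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(MAE, RMSE) in the units of the target (mmHg for BP)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise SchemaError("y_true and y_pred must be equal-length, non-empty vectors")
    err = y_pred - y_true
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def percent_improvement(base_mae: float, new_mae: float) -> float:
    """Relative MAE improvement of ``new`` over ``base``, in percent."""
    if base_mae <= 0:
        raise InvalidParameterError("base_mae must be positive")
    return 100.0 * (base_mae - new_mae) / base_mae


@dataclass
class CVResult:
    """Cross-validation outcome for one (target, mode) combination."""

    mode: str
    k: int
    seed: int
    fold_mae: list[float]
    fold_rmse: list[float]
    fold_n_terms: list[int]
    pooled_mae: float
    pooled_rmse: float
    n: int
    fold_assignment: np.ndarray = field(repr=False, default=None)
    train_mae: float = float("nan")
    train_rmse: float = float("nan")
    train_n_terms: int = 0
    n_candidate_terms: int = 0


def kfold_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    mode: str = "rules_plus_linear",
    k: int = 10,
    seed: int = 0,
    groups: Sequence | None = None,
    model_params: Mapping | None = None,
    refit_train: bool = True,
) -> CVResult:
    """Seeded shuffled k-fold CV with internal penalty selection per fold.

    Pooled MAE/RMSE are computed over the concatenated held-out predictions.
    ``groups`` switches to grouped folding (all beats of a subject share a
    fold).  When ``refit_train`` is set, the model is also refit on the full
    data and training-set metrics are reported alongside.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise InvalidParameterError(f"k={k} exceeds number of rows {n}")
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    params = dict(model_params or {})
    params["mode"] = mode

    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        splits = splitter.split(X, y, groups=np.asarray(groups))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
        splits = splitter.split(X)

    assignment = np.full(n, -1, dtype=int)
    pred = np.full(n, np.nan)
    fold_mae, fold_rmse, fold_terms = [], [], []
    for fold, (tr, te) in enumerate(splits):
        model = fit_rulefit(X.iloc[tr], y[tr], seed=seed + fold, **params)
        p = predict(model, X.iloc[te])
        pred[te] = p
        assignment[te] = fold
        mae, rmse = error_metrics(y[te], p)
        fold_mae.append(mae)
        fold_rmse.append(rmse)
        fold_terms.append(model.n_nonzero_terms)
    pooled_mae, pooled_rmse = error_metrics(y, pred)

    train_mae = train_rmse = float("nan")
    train_terms = n_candidates = 0
    if refit_train:
        full = fit_rulefit(X, y, seed=seed, **params)
        train_mae, train_rmse = error_metrics(y, predict(full, X))
        train_terms = full.n_nonzero_terms
        n_candidates = full.n_candidate_terms

    return CVResult(
        mode=mode,
        k=k,
        seed=seed,
        fold_mae=fold_mae,
        fold_rmse=fold_rmse,
        fold_n_terms=fold_terms,
        pooled_mae=pooled_mae,
        pooled_rmse=pooled_rmse,
        n=n,
        fold_assignment=assignment,
        train_mae=train_mae,
        train_rmse=train_rmse,
        train_n_terms=train_terms,
        n_candidate_terms=n_candidates,
    )


def compare_model_variants(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    groups: Sequence | None = None,
    model_params: Mapping | None = None,
    target: str = "",
    state: str = "",
) -> pd.DataFrame:
    """Run k-fold CV for all three model variants and emit a tidy report.

    One row per mode with held-out (pooled) and training-refit metrics, the
    mean number of non-zero terms across folds, and the candidate-term
    count.
    """
    rows = []
    for mode in MODES:
        cv = kfold_cv(X, y, mode=mode, k=k, seed=seed, groups=groups, model_params=model_params)
        rows.append(
            {
                "target": target,
                "state": state,
                "mode": mode,
                "n": cv.n,
                "cv_mae": cv.pooled_mae,
                "cv_rmse": cv.pooled_rmse,
                "n_terms_mean": float(np.mean(cv.fold_n_terms)),
                "n_terms_train": cv.train_n_terms,
                "n_candidate_terms": cv.n_candidate_terms,
                "train_mae": cv.train_mae,
                "train_rmse": cv.train_rmse,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rest vs WBT comparison
# ---------------------------------------------------------------------------


def exact_wilcoxon_signed_rank(differences: np.ndarray) -> float:
    """Exact two-sided signed-rank p-value on paired differences.

    Zero differences are dropped (the exact-test convention); with no
    non-zero differences there is no evidence and p = 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    res = _scipy_wilcoxon(d, alternative="two-sided", method="exact")
    return float(res.pvalue)


def wilcoxon_rest_vs_wbt(
    beat_table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired rest-vs-WBT comparison of per-subject variable means.

    Beats are collapsed to one mean per subject and state; subjects missing
    either state are excluded with a warning.  Each variable gets the group
    means/SDs (across subjects) and an exact two-sided signed-rank p-value.

    Returns a frame indexed by variable with columns ``rest_mean, rest_sd,
    wbt_mean, wbt_sd, p, significant`` plus 2-decimal presentation columns.
    """
    df = beat_table.data if hasattr(beat_table, "data") else beat_table
    if variables is None:
        variables = [
            c
            for c in df.columns
            if c not in ("subject_id", "state", "beat")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    per_subject = df.groupby(["subject_id", "state"], sort=False)[list(variables)].mean()
    counts = per_subject.reset_index().groupby("subject_id")["state"].nunique()
    complete = counts[counts == 2].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        warnings.warn(
            f"subjects missing one state excluded from the paired test: {dropped}",
            stacklevel=2,
        )
    rows = {}
    for v in variables:
        wide = per_subject[v].unstack("state").loc[complete]
        rest, wbt = wide["rest"].to_numpy(), wide["wbt"].to_numpy()
        p = exact_wilcoxon_signed_rank(wbt - rest)
        rows[v] = {
            "rest_mean": float(np.mean(rest)),
            "rest_sd": float(np.std(rest, ddof=1)) if len(rest) > 1 else np.nan,
            "wbt_mean": float(np.mean(wbt)),
            "wbt_sd": float(np.std(wbt, ddof=1)) if len(wbt) > 1 else np.nan,
            "p": p,
            "n_pairs": int(len(rest)),
            "significant": p < alpha,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    for c in ("rest_mean", "rest_sd", "wbt_mean", "wbt_sd", "p"):
        out[c + "_2dp"] = out[c].round(2)
    return out
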