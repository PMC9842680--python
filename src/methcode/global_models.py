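"""Species-level models of genome-wide methylation vs sequence features.

Ordinary least squares with Wherry-adjusted R-squared and Gaussian AIC;
phylogenetic generalized least squares (PGLS) with Brownian-motion
covariance derived from the species tree (reducing exactly to OLS on a
star phylogeny); bidirectional stepwise AIC selection over 3-mer
features with bootstrap stability scores; per-feature tests with and
without phylogeny (Bonferroni-adjusted); and covariate association
with a phylogeny-corrected p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import SpeciesTree


@dataclass
class ModelFit:
    coefficients: pd.Series
    r2: float
    r2_wherry_adjusted: float
    aic: float
    loglik: float
    n: int
    p: int
    residuals: np.ndarray = field(repr=False, default=None)


@dataclass
class PhyloModelFit:
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    loglik: float
    n: int
    p: int


@dataclass
class StabilityReport:
    stability: pd.Series  # feature -> % of bootstrap iterations selected
    n_bootstrap: int
    mean_aic: float


def _design(X: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    names = ["intercept"] + list(X.columns)
    M = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in X.columns])
    return M, names


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = len(resid)
    s2 = float(resid @ resid) / n
    if s2 <= 0:
        s2 = np.finfo(float).tiny
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


def fit_linear(y: pd.Series, X: pd.DataFrame) -> ModelFit:
    """OLS with Wherry-adjusted R-squared and Gaussian AIC.

    Wherry adjustment: 1 - (1 - R^2)(n - 1)/(n - p - 1). AIC counts the
    intercept, the p slopes, and the variance: 2(p + 2) - 2 logL.
    """
    y_arr = np.asarray(y, dtype=float)
    n, p = len(y_arr), X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    M, names = _design(X)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name the collinear columns by checking rank growth
        bad = []
        cols = [np.ones(n)]
        for c in X.columns:
            trial = np.column_stack(cols + [X[c].to_numpy(float)])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(X[c].to_numpy(float))
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(M, y_arr, rcond=None)
    resid = y_arr - M @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y_arr - y_arr.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    denom = n - p - 1
    r2_wherry = 1.0 - (1.0 - r2) * (n - 1) / denom
    ll = _gaussian_loglik(resid)
    aic = 2.0 * (p + 2) - 2.0 * ll
    return ModelFit(
        coefficients=pd.Series(beta, index=names),
        r2=r2, r2_wherry_adjusted=r2_wherry, aic=aic, loglik=ll,
        n=n, p=p, residuals=resid,
    )


def fit_pgls(y: pd.Series, X: pd.DataFrame, tree: SpeciesTree) -> PhyloModelFit:
    """GLS with Brownian residual covariance from the species tree.

    Sigma_ij is the shared root-to-MRCA path length of species i and j;
    on a star tree Sigma is proportional to the identity and the fit
    equals OLS. Coefficient tests are two-sided t-tests on n - p - 1
    degrees of freedom.
    """
    species = list(y.index)
    missing = sorted(set(species) - set(tree.leaf_names))
    if missing:
        raise ValueError(f"species absent from tree: {missing}")
    V_full, names = tree.vcv()
    order = [names.index(s) for s in species]
    V = V_full[np.ix_(order, order)]
    y_arr = np.asarray(y, dtype=float)
    M, coef_names = _design(X.loc[species] if set(species) <= set(X.index) else X)
    n, k = M.shape
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    My = np.linalg.solve(L, y_arr)
    MX = np.linalg.solve(L, M)
    beta, *_ = np.linalg.lstsq(MX, My, rcond=None)
    resid_w = My - MX @ beta
    dof = n - k
    sigma2 = float(resid_w @ resid_w) / dof
    XtX_inv = np.linalg.pinv(MX.T @ MX)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    ll = _gaussian_loglik(resid_w) - float(np.log(np.diag(L)).sum())
    return PhyloModelFit(
        coefficients=pd.Series(beta, index=coef_names),
        std_errors=pd.Series(se, index=coef_names),
        p_values=pd.Series(pvals, index=coef_names),
        loglik=ll, n=n, p=k - 1,
    )


# ---------------------------------------------------------------------------
# Stepwise selection with bootstrap stability
# ---------------------------------------------------------------------------

def _aic_of(y: np.ndarray, cols: List[np.ndarray]) -> float:
    M = np.column_stack([np.ones(len(y))] + cols) if cols else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    p = len(cols)
    return 2.0 * (p + 2) - 2.0 * _gaussian_loglik(resid)


def _stepwise_once(y: np.ndarray, X: np.ndarray, feat_names: List[str], max_steps: int = 200) -> List[str]:
    """Bidirectional greedy AIC search from the intercept-only model."""
    selected: List[int] = []
    current_aic = _aic_of(y, [])
    n = len(y)
    for _ in range(max_steps):
        best_move = None
        best_aic = current_aic
        for j in range(X.shape[1]):
            if j in selected:
                continue
            if n <= len(selected) + 3:
                break
            a = _aic_of(y, [X[:, i] for i in selected] + [X[:, j]])
            if a < best_aic - 1e-10:
                best_aic, best_move = a, ("add", j)
        for j in selected:
            a = _aic_of(y, [X[:, i] for i in selected if i != j])
            if a < best_aic - 1e-10:
                best_aic, best_move = a, ("drop", j)
        if best_move is None:
            break
        kind, j = best_move
        if kind == "add":
            selected.append(j)
        else:
            selected.remove(j)
        current_aic = best_aic
    return [feat_names[j] for j in selected]


def stepwise_select(
    y: pd.Series,
    X: pd.DataFrame,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> Tuple[StabilityReport, ModelFit]:
    """Stepwise AIC feature selection with bootstrap stability scores.

    The final model is selected on the full data; stability per feature
    is the percentage of bootstrap resamples (species drawn with
    replacement) whose final model contains it.
    """
    if len(y) < 20:
        raise ValueError("need at least 20 observations")
    rng = np.random.default_rng(seed)
    y_arr = np.asarray(y, dtype=float)
    X_arr = X.to_numpy(float)
    feat_names = list(X.columns)
    final_feats = _stepwise_once(y_arr, X_arr, feat_names)
    final_fit = fit_linear(y, X[final_feats] if final_feats else X.iloc[:, :0])

    counts = dict.fromkeys(feat_names, 0)
    aics = []
    n = len(y_arr)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        feats = _stepwise_once(y_arr[idx], X_arr[idx], feat_names)
        for f in feats:
            counts[f] += 1
        aics.append(_aic_of(y_arr[idx], [X_arr[idx, feat_names.index(f)] for f in feats]))
    stability = pd.Series({f: 100.0 * c / n_bootstrap for f, c in counts.items()})
    return StabilityReport(stability=stability, n_bootstrap=n_bootstrap, mean_aic=float(np.mean(aics))), final_fit


# ---------------------------------------------------------------------------
# Per-feature tests and covariate association
# ---------------------------------------------------------------------------

def per_feature_phylo_test(
    y: pd.Series,
    X: pd.DataFrame,
    tree: SpeciesTree,
    bonferroni_factor: Optional[int] = None,
) -> pd.DataFrame:
    """Each feature alone, with and without phylogenetic correction.

    Returns per-feature slope p-values from OLS and PGLS, both
    Bonferroni-adjusted (default factor = number of features, capped
    at 1), as a scatter-ready table.
    """
    m = bonferroni_factor if bonferroni_factor is not None else X.shape[1]
    rows = []
    for feat in X.columns:
        Xi = X[[feat]]
        ols = fit_linear(y, Xi)
        t = ols.coefficients[feat] / _ols_slope_se(y, Xi)
        p_ols = 2.0 * stats.t.sf(abs(t), ols.n - 2)
        pgls = fit_pgls(y, Xi, tree)
        p_pgls = float(pgls.p_values[feat])
        rows.append({
            "feature": feat,
            "p_ols": p_ols,
            "p_pgls": p_pgls,
            "p_ols_adj": min(1.0, p_ols * m),
            "p_pgls_adj": min(1.0, p_pgls * m),
        })
    df = pd.DataFrame(rows).set_index("feature")
    df["neglog10_p_ols"] = -np.log10(df["p_ols"].clip(lower=1e-300))
    df["neglog10_p_pgls"] = -np.log10(df["p_pgls"].clip(lower=1e-300))
    return df


def _ols_slope_se(y: pd.Series, X: pd.DataFrame) -> float:
    y_arr = np.asarray(y, float)
    x = X.iloc[:, 0].to_numpy(float)
    n = len(y_arr)
    M = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(M, y_arr, rcond=None)
    resid = y_arr - M @ beta
    s2 = float(resid @ resid) / (n - 2)
    sxx = float(((x - x.mean()) ** 2).sum())
    return math.sqrt(s2 / sxx) if sxx > 0 else np.inf


def covariate_association(
    metric: pd.Series,
    covariate: pd.Series,
    tree: Optional[SpeciesTree] = None,
    group: Optional[Sequence[str]] = None,
) -> Dict[str, Optional[float]]:
    """Pearson correlation of a species metric with a covariate,
    plus a phylogeny-corrected p-value from PGLS.

    Only species present in both series (and in ``group``, when given)
    enter; fewer than 4 complete pairs yields missing values.
    """
    common = metric.index.intersection(covariate.index)
    if group is not None:
        common = common.intersection(pd.Index(group))
    sub_m = metric.loc[common].astype(float)
    sub_c = covariate.loc[common].astype(float)
    ok = sub_m.notna() & sub_c.notna()
    sub_m, sub_c = sub_m[ok], sub_c[ok]
    if len(sub_m) < 4:
        warnings.warn("fewer than 4 complete species pairs; association missing")
        return {"r": None, "p_naive": None, "p_phylo": None, "n": len(sub_m)}
    r, p_naive = stats.pearsonr(sub_m, sub_c)
    p_phylo = None
    if tree is not None:
        fit = fit_pgls(sub_m, pd.DataFrame({"covariate": sub_c}), tree)
        p_phylo = float(fit.p_values["covariate"])
    return {"r": float(r), "p_naive": float(p_naive), "p_phylo": p_phylo, "n": len(sub_m)}
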