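"""Statistical procedures of the correlative and sensitivity analyses.

* log transform + z-score standardization of positive, skewed ephys variables;
* correlation with normality-gated method choice: Pearson when a Shapiro-Wilk
  test on the linear-regression residuals does not reject normality
  (p >= 0.05), Spearman otherwise; Benjamini-Hochberg FDR adjustment across a
  family of tests;
* exhaustive best-subset linear regression per model size (ranked by adjusted
  R^2, with AIC/BIC reported), final model chosen by minimum mean RMSE over
  repeated (20x) 10-fold cross-validation, with variance-inflation-factor
  screening (VIF < 1.5) of the retained predictors;
* two-sided Fisher exact tests on 2x2 count tables, computed by direct
  hypergeometric enumeration (all tables with the observed margins whose
  probability does not exceed that of the observed table);
* full-model standardized sensitivity regression (used on the model database
  and on synthetic per-neuron populations alike).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionSpec",
    "CorrelationResult",
    "RegressionFit",
    "SubsetSelectionResult",
    "log_standardize",
    "correlate",
    "correlate_pairs",
    "fdr_adjust",
    "vif",
    "best_subset_cv",
    "fisher_exact",
    "sensitivity_regression",
]

SHAPIRO_ALPHA = 0.05
VIF_LIMIT = 1.5


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress on what, and how to pre-transform."""

    response: str
    predictors: Tuple[str, ...]
    log_columns: Tuple[str, ...] = ()
    standardize: bool = True
    subset_sizes: Optional[Tuple[int, ...]] = None  # default 1..len(predictors)

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("predictors must be distinct")


def log_standardize(table: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    """Log-transform the named columns, then z-score (mean 0, sample SD 1,
    ddof=1) the response and predictors.  Errors name the offending column
    when a logged column has non-positive entries or a column is constant.
    """
    out = table.copy()
    for col in spec.log_columns:
        bad = out[col] <= 0
        if bad.any():
            row = out.index[bad][0]
            raise ValueError(f"non-positive value in logged column {col!r} (row {row})")
        out[col] = np.log(out[col])
    if spec.standardize:
        for col in (spec.response, *spec.predictors):
            sd = out[col].std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"cannot standardize constant column {col!r}")
            out[col] = (out[col] - out[col].mean()) / sd
    return out


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" or "spearman"
    coefficient: float
    p_value: float
    p_adjusted: float  # NaN until a family-wise adjustment is applied
    n: int
    shapiro_p: float


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Correlation with the normality-gated method switch.

    Fits y ~ x by least squares, Shapiro-Wilk tests the residuals; normal
    residuals (p >= 0.05) -> Pearson r, otherwise Spearman rho.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(y).max()))):
        shapiro_p = 1.0  # exact fit: no evidence against normality
    else:
        shapiro_p = float(sps.shapiro(resid).pvalue)
    if shapiro_p >= SHAPIRO_ALPHA:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method, float(r), float(p), np.nan, int(x.size), shapiro_p)


def correlate_pairs(
    table: pd.DataFrame, pairs: Sequence[Tuple[str, str]]
) -> pd.DataFrame:
    """Correlate many (x, y) column pairs and FDR-adjust the p values as one
    family; one tidy row per pair."""
    rows = []
    for xcol, ycol in pairs:
        sub = table[[xcol, ycol]].dropna()
        res = correlate(sub[xcol].to_numpy(), sub[ycol].to_numpy())
        rows.append(
            dict(x=xcol, y=ycol, method=res.method, coefficient=res.coefficient,
                 p_value=res.p_value, n=res.n, shapiro_p=res.shapiro_p)
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = fdr_adjust(out["p_value"].to_numpy())
    return out


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1 - R^2_j) from regressing
    column j on the remaining columns (intercept included).  Perfect
    collinearity yields inf."""
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        Xj = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class RegressionFit:
    """An OLS fit on standardized variables."""

    response: str
    predictors: Tuple[str, ...]
    coefficients: Dict[str, float]  # standardized betas
    intercept: float
    r2: float
    adj_r2: float
    aic: float
    bic: float
    vif: Dict[str, float]
    vif_ok: bool


def _ols_fit(y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, float, float, float, float]:
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else np.nan
    sigma2 = max(ss_res / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = p + 2  # betas + intercept + sigma
    return beta, r2, adj, 2 * k - 2 * ll, k * np.log(n) - 2 * ll


def _fit_subset(table: pd.DataFrame, response: str, predictors: Sequence[str]) -> RegressionFit:
    y = table[response].to_numpy(dtype=float)
    X = table[list(predictors)].to_numpy(dtype=float)
    beta, r2, adj, aic, bic = _ols_fit(y, X)
    if len(predictors) >= 2:
        v = vif(table[list(predictors)])
        vifs = {k: float(val) for k, val in v.items()}
    else:
        vifs = {predictors[0]: 1.0}
    return RegressionFit(
        response=response,
        predictors=tuple(predictors),
        coefficients={p: float(b) for p, b in zip(predictors, beta[1:])},
        intercept=float(beta[0]),
        r2=r2,
        adj_r2=adj,
        aic=aic,
        bic=bic,
        vif=vifs,
        vif_ok=all(val < VIF_LIMIT for val in vifs.values()),
    )


@dataclass
class SubsetSelectionResult:
    per_size_best: Dict[int, RegressionFit]
    cv_rmse: Dict[Tuple[str, ...], float]  # mean CV RMSE per candidate subset
    chosen: RegressionFit
    folds: int
    repeats: int
    seed: int


def _cv_rmse(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    folds: int,
    repeats: int,
    seed: int,
) -> float:
    """Mean RMSE over repeated k-fold cross-validation (shuffled folds with a
    recorded seed)."""
    y = table[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), table[list(predictors)].to_numpy(dtype=float)])
    rng = np.random.default_rng(seed)
    n = len(y)
    rmses = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        fold_ids = np.arange(n) % folds
        for f in range(folds):
            test = perm[fold_ids == f]
            train = perm[fold_ids != f]
            beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
            err = y[test] - X[test] @ beta
            rmses.append(float(np.sqrt(np.mean(err**2))))
    return float(np.mean(rmses))


def best_subset_cv(
    table: pd.DataFrame,
    spec: RegressionSpec,
    folds: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> SubsetSelectionResult:
    """Exhaustive best-subset search with repeated cross-validated selection.

    Per model size, every predictor subset is fitted on the (transformed,
    standardized) complete cases and the best by adjusted R^2 retained (AIC
    and BIC are reported alongside); the final model minimizes mean RMSE over
    ``repeats`` x ``folds``-fold cross-validation.  Subsets with p >= n are
    skipped.  The chosen fit carries standardized coefficients, r^2 and VIFs.
    """
    data = log_standardize(table[[spec.response, *spec.predictors]].dropna(), spec)
    n = len(data)
    if n < 3 * folds:
        raise ValueError(f"need at least {3 * folds} complete cases, got {n}")
    sizes = spec.subset_sizes or tuple(range(1, len(spec.predictors) + 1))
    per_size: Dict[int, RegressionFit] = {}
    skipped: List[Tuple[str, ...]] = []
    for size in sizes:
        best = None
        for combo in itertools.combinations(spec.predictors, size):
            if size >= n:
                skipped.append(combo)
                continue
            fit = _fit_subset(data, spec.response, combo)
            if best is None or fit.adj_r2 > best.adj_r2:
                best = fit
        if best is not None:
            per_size[size] = best
    if not per_size:
        raise ValueError("no fittable subset")
    cv_scores = {
        fit.predictors: _cv_rmse(data, spec.response, fit.predictors, folds, repeats, seed)
        for fit in per_size.values()
    }
    chosen_preds = min(cv_scores, key=cv_scores.get)
    chosen = next(f for f in per_size.values() if f.predictors == chosen_preds)
    return SubsetSelectionResult(
        per_size_best=per_size,
        cv_rmse=cv_scores,
        chosen=chosen,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table ``[[a, b], [c, d]]``.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table
    (with a small relative tolerance for ties).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(int(x) != x for x in (a, b, c, d)):
        raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1 = a + b  # row 1 total
    n2 = c + d
    m1 = a + c  # column 1 total
    if n1 == 0 or n2 == 0 or m1 == 0 or b + d == 0:
        raise ValueError("table margins must be positive")
    N = n1 + n2
    rv = sps.hypergeom(N, m1, n1)
    support = np.arange(max(0, m1 - n2), min(m1, n1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def sensitivity_regression(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    log_response: bool = True,
) -> RegressionFit:
    """Full-model standardized multiple regression (no subset search).

    The response is (optionally log-transformed and) standardized, every
    predictor is standardized, and the standardized coefficients quantify the
    sensitivity of the response to each parameter.
    """
    spec = RegressionSpec(
        response=response,
        predictors=tuple(predictors),
        log_columns=(response,) if log_response else (),
    )
    data = log_standardize(table[[response, *predictors]].dropna(), spec)
    return _fit_subset(data, response, tuple(predictors))
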