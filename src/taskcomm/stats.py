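"""Brain-behavior statistics.

Correlates network similarity with behavioral performance (Bonferroni
corrected over condition pairs, optionally swept over wiring costs), fits
multiple regressions of performance on per-subnetwork similarity features
with adjusted R^2 / AIC comparison, traces the lasso variable-selection
path, and provides the categorical (chi-square) and factorial ANOVA stages
used on node identities and fragmentation scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st
from sklearn.linear_model import Lasso, LinearRegression

from .connectivity import ConnectivityMatrix, threshold_by_cost
from .metrics import network_similarity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    p_adjusted: float
    n: int
    n_comparisons: int


@dataclass(frozen=True)
class RegressionReport:
    predictors: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    adjusted_r2: float
    aic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class LassoPath:
    """Coefficient trajectories over an increasing penalty grid.

    ``last_survivor`` is the predictor whose coefficient is the last to
    shrink to zero as the L1 penalty grows — the single feature carrying
    the most independent variance.
    """

    lambda_grid: np.ndarray
    coefficients: np.ndarray  # (n_lambdas, n_predictors)
    predictors: tuple[str, ...]
    last_survivor: str


def similarity_performance_correlation(
    similarities: Sequence[float],
    performance: Sequence[float],
    n_comparisons: int = 6,
) -> CorrelationResult:
    """Pearson correlation with two-sided t-test p, Bonferroni adjusted.

    The default ``n_comparisons=6`` corrects over the six condition pairs of
    a four-condition design.
    """
    x = np.asarray(similarities, dtype=float)
    y = np.asarray(performance, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("similarities and performance must be matching 1-D arrays")
    if x.size < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = _st.pearsonr(x, y)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        p_adjusted=min(1.0, float(p) * n_comparisons),
        n=x.size,
        n_comparisons=n_comparisons,
    )


def cost_sweep_correlation(
    matrices_a: Sequence[ConnectivityMatrix],
    matrices_b: Sequence[ConnectivityMatrix],
    performance: Sequence[float],
    cost_grid: Sequence[float],
) -> pd.DataFrame:
    """Similarity-performance correlation recomputed at each wiring cost.

    Both condition matrices are cost-thresholded per subject, the network
    similarity is recomputed, and its correlation with performance reported
    with *uncorrected* p values (the sweep is descriptive).  Costs at which
    similarity degenerates (e.g. no surviving shared edges) yield NaN rows.
    """
    if len(matrices_a) != len(matrices_b) or len(matrices_a) != len(performance):
        raise ValueError("need one matrix pair and one performance value per subject")
    rows = []
    for cost in cost_grid:
        try:
            sims = [
                network_similarity(
                    threshold_by_cost(a, cost), threshold_by_cost(b, cost)
                ).similarity_r
                for a, b in zip(matrices_a, matrices_b)
            ]
            r, p = _st.pearsonr(sims, np.asarray(performance, dtype=float))
            rows.append({"cost": cost, "r": float(r), "p": float(p)})
        except ValueError:
            rows.append({"cost": cost, "r": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def _feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame(np.asarray(features, dtype=float)).add_prefix("x")


def subnetwork_regression(features, performance: Sequence[float]) -> RegressionReport:
    """OLS of performance on per-subnetwork similarity features.

    Reports adjusted R^2, the model F-test p value, and AIC under the
    Gaussian likelihood convention (constant included) so two reports can be
    compared with :func:`delta_aic`.
    """
    Xf = _feature_frame(features)
    y = np.asarray(performance, dtype=float)
    n, p = Xf.shape
    if n != y.size:
        raise ValueError("feature rows must match performance length")
    if n <= p + 1:
        raise ValueError("need n > n_features + 1 observations")
    X = sm.add_constant(Xf.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(Xf.to_numpy(), rowvar=False)
        dupes = [
            (Xf.columns[i], Xf.columns[j])
            for i, j in zip(*np.triu_indices(p, k=1))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"collinear features: {dupes or list(Xf.columns)}")
    fit = sm.OLS(y, X).fit()
    return RegressionReport(
        predictors=tuple(str(c) for c in Xf.columns),
        coefficients=np.asarray(fit.params[1:]),
        intercept=float(fit.params[0]),
        adjusted_r2=float(fit.rsquared_adj),
        aic=float(fit.aic),
        p_value=float(fit.f_pvalue),
        n=n,
    )


def delta_aic(a: RegressionReport, b: RegressionReport) -> float:
    """AIC(b) - AIC(a): positive values favor model ``a``."""
    return b.aic - a.aic


def lambda_max(features, performance: Sequence[float]) -> float:
    """Smallest penalty at which every lasso coefficient is zero, for
    internally standardized features under the (1/(2n))RSS + lambda*L1
    objective."""
    Xf = _feature_frame(features)
    X = _standardize(Xf.to_numpy())
    y = np.asarray(performance, dtype=float)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))


def default_lambda_grid(features, performance, n_lambdas: int = 100) -> np.ndarray:
    """Increasing log-spaced grid from lambda_max * 1e-4 up to lambda_max."""
    lmax = lambda_max(features, performance)
    return np.logspace(np.log10(lmax * 1e-4), np.log10(lmax), n_lambdas)


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"constant feature column(s) {np.flatnonzero(sd == 0).tolist()}")
    return (X - X.mean(axis=0)) / sd


def lasso_path(
    features, performance: Sequence[float], lambda_grid: Sequence[float] | None = None
) -> LassoPath:
    """L1-penalized least squares solved at every penalty on the grid.

    Features are standardized internally (mean 0, sd 1); the objective is
    (1/(2n))||y - Xb||^2 + lambda*||b||_1, so for mutually orthogonal
    standardized columns the solution is the soft-thresholded OLS
    coefficient sign(b)*max(|b| - lambda, 0), and lambda = 0 reproduces OLS.
    Ties for last survivor go to the smaller column index (logged).
    """
    Xf = _feature_frame(features)
    y = np.asarray(performance, dtype=float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Xf, y)
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must not be empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("lambda grid must be increasing")
    X = _standardize(Xf.to_numpy())
    coefs = np.empty((grid.size, X.shape[1]))
    for i, lam in enumerate(grid):
        if lam == 0:
            coefs[i] = LinearRegression().fit(X, y).coef_
        else:
            model = Lasso(alpha=lam, fit_intercept=True, max_iter=100_000, tol=1e-10)
            coefs[i] = model.fit(X, y).coef_
    nonzero = np.abs(coefs) > 1e-10
    last_idx = np.array(
        [np.flatnonzero(nonzero[:, j]).max() if nonzero[:, j].any() else -1 for j in range(X.shape[1])]
    )
    winners = np.flatnonzero(last_idx == last_idx.max())
    if len(winners) > 1:
        logger.info("last-survivor tie among columns %s; taking the first", winners.tolist())
    survivor = str(Xf.columns[winners[0]])
    return LassoPath(
        lambda_grid=grid,
        coefficients=coefs,
        predictors=tuple(str(c) for c in Xf.columns),
        last_survivor=survivor,
    )


def identity_chi2(counts: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Chi-square test of independence for an identity x module table."""
    table = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, expected = _st.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return float(chi2), int(dof), float(p)


def fragmentation_anova(data: pd.DataFrame) -> dict:
    """Two-way fixed-effects ANOVA of fragmentation: subnetwork x condition.

    ``data`` needs columns ``value``, ``subnetwork``, ``condition`` and, for
    paired post hocs, ``subject``.  The layout must be balanced (equal cell
    counts), as in a complete factorial design.  Post hoc pairwise
    comparisons of subnetwork marginal means are Bonferroni adjusted.
    Returns ``{"anova": table, "posthoc": table}``.
    """
    required = {"value", "subnetwork", "condition"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    cells = data.groupby(["subnetwork", "condition"]).size()
    full = len(data["subnetwork"].unique()) * len(data["condition"].unique())
    if len(cells) != full or cells.nunique() != 1:
        raise ValueError("unbalanced factorial layout")
    fit = sm.OLS.from_formula("value ~ C(subnetwork) * C(condition)", data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    if np.ptp(data["value"].to_numpy()) == 0:
        # constant response: all sums of squares vanish; define F = 0, p = 1
        effects = anova.index != "Residual"
        anova.loc[effects, "F"] = 0.0
        anova.loc[effects, "PR(>F)"] = 1.0

    pairs = list(combinations(sorted(data["subnetwork"].unique()), 2))
    rows = []
    paired = "subject" in data.columns
    for a, b in pairs:
        if paired:
            va = data[data["subnetwork"] == a].groupby("subject")["value"].mean()
            vb = data[data["subnetwork"] == b].groupby("subject")["value"].mean()
            vb = vb.reindex(va.index)
            stat, p = _st.ttest_rel(va, vb)
        else:
            stat, p = _st.ttest_ind(
                data.loc[data["subnetwork"] == a, "value"],
                data.loc[data["subnetwork"] == b, "value"],
            )
        rows.append(
            {
                "a": a,
                "b": b,
                "t": float(stat),
                "p": float(p),
                "p_bonferroni": min(1.0, float(p) * len(pairs)),
            }
        )
    return {"anova": anova, "posthoc": pd.DataFrame(rows)}
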