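"""Group comparisons: one-way ANOVA with Tukey's HSD, and simple OLS fits.

All group comparisons in this pipeline reduce to per-mouse summaries first
(no repeated-measures structure), then a one-way layout with family-wise
control by the studentized range.  Unbalanced designs use the Tukey-Kramer
standard errors.  When Tukey is applied to ANCOVA-adjusted values the
procedure mirrors the two-step practice of adjusting first and comparing
second; this is statistically approximate (the covariate-fit degrees of
freedom are not carried into the comparison).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def anova_tukey(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Tukey HSD comparisons on a one-way layout.

    Returns a tidy frame with one row per group pair: ``group1``,
    ``group2``, ``estimate`` (mean difference, group2 - group1), ``lower``,
    ``upper`` (family-wise confidence limits), ``p_adj`` and ``reject``.
    Requires at least two groups and more than one observation overall per
    group structure (a single observation per group leaves no residual
    degrees of freedom).
    """
    y = np.asarray(values, dtype=float)
    g = pd.Series(groups).astype(str).to_numpy()
    if len(y) != len(g):
        raise ValueError("values and groups length mismatch")
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if np.all(counts < 2):
        raise ValueError("need at least one group with two or more observations")
    if len(y) - len(levels) < 1:
        raise ValueError("no residual degrees of freedom for Tukey HSD")
    if np.ptp(y) == 0:
        # identical values: all differences zero, nothing to reject
        pairs = [
            (levels[i], levels[j])
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
        return pd.DataFrame(
            {
                "group1": [a for a, _ in pairs],
                "group2": [b for _, b in pairs],
                "estimate": 0.0,
                "lower": 0.0,
                "upper": 0.0,
                "p_adj": 1.0,
                "reject": False,
            }
        )
    res = pairwise_tukeyhsd(y, g, alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )
    return pd.DataFrame(
        {
            "group1": table["group1"].astype(str),
            "group2": table["group2"].astype(str),
            "estimate": res.meandiffs,
            "lower": res.confint[:, 0],
            "upper": res.confint[:, 1],
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )


def tukey_pair(table: pd.DataFrame, a: str, b: str) -> pd.Series:
    """Extract the row comparing groups ``a`` and ``b`` (order-insensitive)."""
    hit = table[
        ((table["group1"] == a) & (table["group2"] == b))
        | ((table["group1"] == b) & (table["group2"] == a))
    ]
    if hit.empty:
        raise KeyError(f"no comparison {a} vs {b}")
    return hit.iloc[0]


def fit_linear(y, X) -> dict:
    """Ordinary least squares with an intercept prepended.

    ``X`` is a 1-D covariate or a 2-D design (without intercept).  Returns
    coefficients (intercept first), residuals, R^2 and adjusted R^2.
    Raises on rank deficiency (duplicated covariates).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n, p = design.shape
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")
    return {
        "coefficients": beta,
        "residuals": resid,
        "fitted": fitted,
        "r_squared": r2,
        "adj_r_squared": adj_r2,
    }
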