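"""Covariate normalization of energy expenditure and hydrogen production.

Dividing energy expenditure by body mass is biased whenever groups differ in
metabolically inert mass — a germ-free mouse carries up to ~10 % of its body
mass as cecal water, which consumes no energy but inflates the denominator.
The regression-based alternative (ANCOVA) fits

    value ~ covariates + group

with the group as a qualitative covariate and a single slope per covariate,
then replaces each individual value by its residual plus the model
prediction at the covariate grand means (computed over all mice) with the
mouse's own group coefficient retained.  Group contrasts on the adjusted
values therefore equal the ANCOVA adjusted means, while inert-mass
differences between groups no longer leak into the comparison.

Energy expenditure is adjusted for lean mass plus dissected fat mass
(iBAT + iWAT + vWAT); hydrogen production is adjusted for cecal mass, a
proxy for total gut microbiota mass.  The "classical" per-mass ratios are
provided for comparison and for demonstrating the artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


class CollinearCovariatesError(ValueError):
    pass


@dataclass
class AncovaFit:
    """Result of a regression-based adjustment."""

    response: str
    covariates: list[str]
    groups: pd.Series | None
    coefficients: pd.Series
    residuals: np.ndarray
    grand_means: dict[str, float]
    adjusted: np.ndarray
    r_squared: float
    notes: list[str] = field(default_factory=list)

    def adjusted_series(self) -> pd.Series:
        return pd.Series(self.adjusted, name=f"{self.response}_adjusted")


def _design(
    covariates: pd.DataFrame, groups: pd.Series | None
) -> tuple[pd.DataFrame, list[str]]:
    X = covariates.astype(float).copy()
    group_cols: list[str] = []
    if groups is not None:
        levels = sorted(pd.unique(groups))
        for lev in levels[1:]:  # first level is the reference
            col = f"group[{lev}]"
            X[col] = (groups == lev).astype(float).to_numpy()
            group_cols.append(col)
    X = sm.add_constant(X, has_constant="add")
    return X, group_cols


def ancova_adjust(
    values,
    covariates: pd.DataFrame,
    groups=None,
    response: str = "value",
) -> AncovaFit:
    """Replace each value by residual + prediction at covariate grand means.

    ``covariates`` is a per-mouse numeric frame (e.g. lean and fat mass);
    ``groups`` an optional label series entering the model as a qualitative
    covariate without interactions.  Grand means are mouse-weighted
    (averaged over all mice, pooling groups).  The prediction keeps each
    mouse's own group coefficient, so genuine group effects survive the
    adjustment while covariate-driven variation is removed.

    With no groups given, this is plain regression adjustment (used for the
    degenerate designs where a group factor would be saturated).
    """
    y = np.asarray(values, dtype=float)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != len(y):
        raise ValueError("values and covariates length mismatch")
    if groups is not None:
        groups = pd.Series(groups).reset_index(drop=True)
        if groups.nunique() < 2:
            groups = None
    if (cov.std(ddof=0) == 0).any():
        degenerate = cov.columns[(cov.std(ddof=0) == 0)].tolist()
        # constant covariates carry no information; adjustment is identity on them
        cov = cov.drop(columns=degenerate)
    notes: list[str] = []
    if groups is not None:
        small = groups.value_counts()
        for lev, n in small.items():
            if n == 1:
                notes.append(f"group {lev} has a single mouse; its effect is unshrunk")

    if cov.shape[1] >= 2:
        corr = cov.corr().abs()
        for i, a in enumerate(corr.columns):
            for b in corr.columns[i + 1 :]:
                if corr.loc[a, b] > 1 - 1e-10:
                    raise CollinearCovariatesError(
                        f"covariates '{a}' and '{b}' are collinear"
                    )

    X, group_cols = _design(cov, groups)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CollinearCovariatesError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()

    grand = {c: float(cov[c].mean()) for c in cov.columns}
    Xp = X.copy()
    for c in cov.columns:
        Xp[c] = grand[c]
    pred = fit.predict(Xp)
    adjusted = fit.resid + np.asarray(pred)
    return AncovaFit(
        response=response,
        covariates=list(cov.columns),
        groups=groups,
        coefficients=fit.params,
        residuals=np.asarray(fit.resid),
        grand_means=grand,
        adjusted=np.asarray(adjusted),
        r_squared=float(fit.rsquared),
        notes=notes + ["grand means are mouse-weighted (pooled over all groups)"],
    )


def adjust_energy_expenditure(
    summaries: pd.DataFrame, profiles: pd.DataFrame, value_col: str = "ee_kcal"
) -> AncovaFit:
    """ANCOVA-adjust per-mouse EE summaries by lean and dissected fat mass."""
    prof = profiles.set_index("mouse_id")
    df = summaries.copy()
    df["lean_mass_g"] = df["mouse_id"].map(prof["lean_mass_g"])
    fat = prof[["fat_ibat_g", "fat_iwat_g", "fat_vwat_g"]].sum(axis=1)
    df["fat_total_g"] = df["mouse_id"].map(fat)
    df["group"] = df["mouse_id"].map(prof["group"])
    return ancova_adjust(
        df[value_col],
        df[["lean_mass_g", "fat_total_g"]],
        groups=df["group"],
        response=value_col,
    )


def adjust_hydrogen(
    h2_auc,
    cecal_mass_g,
    groups=None,
) -> AncovaFit:
    """ANCOVA-adjust hydrogen AUC by cecal mass.

    Germ-free mice produce no microbial hydrogen and are excluded upstream;
    only colonized groups are fitted.
    """
    cov = pd.DataFrame({"cecal_mass_g": np.asarray(cecal_mass_g, dtype=float)})
    return ancova_adjust(h2_auc, cov, groups=groups, response="h2_auc")


RATIO_MASS_COLUMNS = {
    "total": "total_mass_g",
    "total_nocecum": "total_mass_nocecum_g",
    "lean": "lean_mass_g",
}


def ratio_normalize(values, mass, which: str | None = None):
    """Classical normalization: value per gram of the chosen mass.

    ``which`` is informational (total | total_nocecum | lean); the caller
    supplies the matching mass column.  Raises on non-positive mass.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive for ratio normalization")
    return v / m
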