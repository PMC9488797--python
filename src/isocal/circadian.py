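"""Circadian aggregation and smoothing.

Per-phase energy expenditure is the trapezoid area under the instantaneous
EE curve over the 12-h light (ZT 0-12) or dark (ZT 12-24) window or the full
day; food intake over a window is cumulative; RER is averaged pointwise.
Windows are half-open ``[t0, t1)`` and the boundary trapezoids are split at
the window edges by linear interpolation, which makes light + dark = full
day exact.  Gaps left by QC removal are spanned by a single trapezoid.

For curves whose continuous circadian evolution is of interest (RER, gross
hydrogen production), values are first averaged at each ZT time point per
individual and a penalized cubic regression spline (P-spline: cubic B-spline
basis, second-order difference penalty, smoothing parameter chosen by
generalized cross-validation) is fitted to the per-timepoint means, on a
cyclic basis by default because the 24-h schedule is periodic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .io import DARK_PHASE, FULL_DAY, LIGHT_PHASE

PHASES = (LIGHT_PHASE, DARK_PHASE, FULL_DAY)


def auc_trapezoid(
    times: np.ndarray, values: np.ndarray, window: tuple[float, float]
) -> float:
    """Trapezoid area under (times, values) restricted to ``[t0, t1)``.

    Edge values at t0 and t1 are obtained by linear interpolation when the
    series extends past the window; otherwise the integral truncates at the
    data range.  Returns NaN when fewer than two support points fall in the
    window (nothing to integrate).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    inside = (t >= t0) & (t < t1)
    ts = list(t[inside])
    vs = list(v[inside])
    if len(ts) < 2 and not (t.size >= 2 and t[0] <= t0 and t[-1] >= t1):
        return float("nan")
    if t.size >= 2:
        if (not ts or ts[0] > t0) and t[0] < t0 <= t[-1]:
            ts.insert(0, t0)
            vs.insert(0, float(np.interp(t0, t, v)))
        if t[-1] >= t1 > t[0]:
            ts.append(t1)
            vs.append(float(np.interp(t1, t, v)))
    if len(ts) < 2:
        return float("nan")
    return float(np.trapezoid(vs, ts))


def cumulative_intake(
    times: np.ndarray, grams: np.ndarray, window: tuple[float, float]
) -> float:
    """Sum of interval consumptions whose timestamps fall in ``[t0, t1)``.

    Consumption columns record grams eaten during the preceding interval,
    so windows partitioning a day sum exactly to the daily total.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(grams, dtype=float)
    t0, t1 = window
    return float(g[(t >= t0) & (t < t1)].sum())


def summarize_phases(frame: pd.DataFrame) -> pd.DataFrame:
    """Per mouse x day x phase aggregates from an exchange-annotated frame.

    Expects the QC'd frame with columns ``t_h``, ``day``, ``ee_kcal_min``,
    ``rer``, ``h2_rate``, ``food_g``.  Returns one row per mouse-day-phase
    with: ``ee_kcal`` (kcal; trapezoid AUC of EE, minutes-to-hours factor
    applied), ``rer_mean``, ``h2_auc`` (ppm*L; AUC of the hydrogen rate),
    ``food_g`` (cumulative) and ``n_points``.  Days absent after QC yield
    no rows; windows with fewer than two support points yield NaN
    aggregates flagged by ``n_points``.
    """
    required = {"mouse_id", "t_h", "day", "ee_kcal_min", "rer", "h2_rate", "food_g"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"summarize_phases needs columns {sorted(missing)}")
    rows = []
    for mouse, g in frame.groupby("mouse_id", sort=False):
        g = g.sort_values("t_h")
        t = g["t_h"].to_numpy(float)
        for day in sorted(g["day"].unique()):
            base = 24.0 * day
            windows = {
                LIGHT_PHASE: (base, base + 12.0),
                DARK_PHASE: (base + 12.0, base + 24.0),
                FULL_DAY: (base, base + 24.0),
            }
            for phase, win in windows.items():
                inside = (t >= win[0]) & (t < win[1])
                n = int(inside.sum())
                ee = auc_trapezoid(t, g["ee_kcal_min"].to_numpy(float), win)
                h2 = auc_trapezoid(t, g["h2_rate"].to_numpy(float), win)
                rer_vals = g.loc[inside, "rer"]
                rows.append(
                    {
                        "mouse_id": mouse,
                        "day": int(day),
                        "phase": phase,
                        "ee_kcal": ee * 60.0,
                        "rer_mean": float(rer_vals.mean()) if n else float("nan"),
                        "h2_auc": h2 * 60.0,
                        "food_g": cumulative_intake(t, g["food_g"].to_numpy(float), win),
                        "n_points": n,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SmoothedCurve:
    """A fitted circadian curve on a uniform ZT grid."""

    grid: np.ndarray
    fitted: np.ndarray
    basis_dim: int
    lam: float
    gcv: float
    edf: float
    cyclic: bool

    def __call__(self, zt) -> np.ndarray:
        return np.interp(np.asarray(zt, dtype=float) % 24.0, self.grid, self.fitted)


def _design_and_penalty(
    x: np.ndarray, basis_dim: int, cyclic: bool, period: float = 24.0
) -> tuple[np.ndarray, np.ndarray]:
    degree = 3
    if cyclic:
        n = basis_dim
        h = period / n
        knots = np.arange(-degree, n + degree + 1) * h
        ext = BSpline.design_matrix(x % period, knots, degree).toarray()
        X = np.zeros((len(x), n))
        for j in range(ext.shape[1]):
            X[:, j % n] += ext[:, j]
        D = np.zeros((n, n))
        for i in range(n):
            D[i, i] = 1.0
            D[i, (i + 1) % n] = -2.0
            D[i, (i + 2) % n] = 1.0
    else:
        n = basis_dim
        lo, hi = float(np.min(x)), float(np.max(x))
        span = hi - lo if hi > lo else 1.0
        n_interior = n - degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else []
        knots = np.concatenate(
            [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
        )
        xx = np.clip(x, lo, hi)
        X = BSpline.design_matrix(xx, knots, degree).toarray()
        D = np.diff(np.eye(n), n=2, axis=0)
    return X, D


def smooth_circadian(
    zt: np.ndarray,
    means: np.ndarray,
    basis_dim: int = 10,
    cyclic: bool = True,
    grid_points: int = 241,
    lambdas: np.ndarray | None = None,
) -> SmoothedCurve:
    """Penalized cubic regression spline through per-timepoint means.

    The smoothing parameter minimises the GCV score
    ``n * RSS / (n - edf)^2`` over a log-spaced grid; ``edf`` is the trace
    of the smoother matrix.  With noiseless data the optimum drives the
    penalty to its smallest grid value, recovering any curve in the spline
    space (a cubic polynomial, with ``cyclic=False``) essentially exactly.
    Requires at least 10 distinct ZT values; a rank-deficient design
    triggers a basis-dimension reduction with a warning.
    """
    x = np.asarray(zt, dtype=float)
    y = np.asarray(means, dtype=float)
    if len(np.unique(x)) < 10:
        raise ValueError("need at least 10 distinct zt values to smooth")
    if basis_dim > len(np.unique(x)):
        warnings.warn(
            f"basis_dim {basis_dim} exceeds distinct timepoints; reducing",
            stacklevel=2,
        )
        basis_dim = len(np.unique(x))
    X, D = _design_and_penalty(x, basis_dim, cyclic)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient spline design; reducing basis dimension", stacklevel=2)
        while basis_dim > 4 and np.linalg.matrix_rank(X) < X.shape[1]:
            basis_dim -= 1
            X, D = _design_and_penalty(x, basis_dim, cyclic)
    if lambdas is None:
        lambdas = np.logspace(-10, 6, 49)

    XtX = X.T @ X
    Xty = X.T @ y
    P = D.T @ D
    n = len(y)
    best = None
    for lam in lambdas:
        A = XtX + lam * P
        try:
            beta = np.linalg.solve(A, Xty)
            Ainv_XtX = np.linalg.solve(A, XtX)
        except np.linalg.LinAlgError:
            continue
        edf = float(np.trace(Ainv_XtX))
        rss = float(np.sum((y - X @ beta) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf)
    if best is None:
        raise np.linalg.LinAlgError("spline fit failed for all smoothing parameters")
    gcv, lam, beta, edf = best

    if cyclic:
        grid = np.linspace(0.0, 24.0, grid_points, endpoint=False)
    else:
        grid = np.linspace(float(np.min(x)), float(np.max(x)), grid_points)
    Xg, _ = _design_and_penalty(grid, basis_dim, cyclic)
    fitted = Xg @ beta
    return SmoothedCurve(
        grid=grid,
        fitted=fitted,
        basis_dim=basis_dim,
        lam=float(lam),
        gcv=float(gcv),
        edf=edf,
        cyclic=cyclic,
    )


def per_timepoint_means(frame: pd.DataFrame, column: str) -> pd.DataFrame:
    """Average a variable at each ZT time point for each individual.

    This is the required order of operations before smoothing group curves:
    averaging within mouse first keeps mice, not records, as the unit.
    """
    out = (
        frame.groupby(["mouse_id", "zt"])[column]
        .mean()
        .rename("mean_value")
        .reset_index()
    )
    return out
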