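"""Datapoint quality control for metabolic-cage traces.

Faulty measurements in long-running isolator cage systems have recognisable
signatures: a 0.01 g food reading is the balance's noise sentinel; negative
food/water consumption or negative gas differentials are physically
impossible; leaky water bottles and dropped food pellets produce large
positive intake outliers; unsealed cages or clogged pre-analyzer filters
depress the O2/CO2 differentials.  The rules below remove exactly these
signatures, in a fixed order, and a day-level completeness rule discards any
mouse-day in which more than a configured fraction of the daily measurement
grid was lost — partial days would bias circadian summaries.

Quartile thresholds pool all days of a mouse (one threshold set per mouse
per variable) and are computed once, on the records surviving the sentinel
and negativity rules; re-applying the QC with the thresholds recorded in the
report removes nothing (fixed-threshold convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import add_time_axis

RULE_FOOD_SENTINEL = "food_sentinel"
RULE_NEGATIVE = "negative_value"
RULE_INTAKE_OUTLIER = "intake_outlier"
RULE_GAS_OUTLIER = "gas_outlier"
RULE_DAY_INCOMPLETE = "day_incomplete"

POINT_RULES = (RULE_FOOD_SENTINEL, RULE_NEGATIVE, RULE_INTAKE_OUTLIER, RULE_GAS_OUTLIER)

_MIN_RECORDS_FOR_QUARTILES = 4


@dataclass(frozen=True)
class QCConfig:
    """Tunable QC parameters.

    food_noise_g
        Balance noise sentinel discarded outright (grams).
    sentinel_tol_g
        Half the balance resolution; the sentinel match is
        ``|food_g - food_noise_g| <= sentinel_tol_g`` because the stored
        floats carry formatting noise.
    iqr_multiplier
        ``k`` in the Tukey-fence outlier rules (Q75 + k*IQR above for
        intake, Q25 - k*IQR below for gas differentials).
    day_removal_fraction
        A mouse-day loses all its records when strictly more than this
        fraction of the expected daily grid was removed.
    cadence_min
        Nominal record spacing; expected records per day = 24 h / cadence.
    """

    food_noise_g: float = 0.01
    sentinel_tol_g: float = 0.005
    iqr_multiplier: float = 1.5
    day_removal_fraction: float = 0.20
    cadence_min: float = 24.0

    def __post_init__(self) -> None:
        if not (0 < self.day_removal_fraction < 1):
            raise ValueError("day_removal_fraction must be in (0,1)")
        for name in ("food_noise_g", "sentinel_tol_g", "iqr_multiplier", "cadence_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def expected_per_day(self) -> int:
        return int(round(24.0 * 60.0 / self.cadence_min))


@dataclass
class QCReport:
    """Auditable bookkeeping of what was removed and why.

    Each removed record is attributed to the first rule (in the fixed rule
    order) that it triggered, so ``input = surviving + sum(rule counts)``
    holds exactly.
    """

    input_count: int = 0
    surviving_count: int = 0
    rule_counts: dict[str, int] = field(default_factory=dict)
    removed: pd.DataFrame | None = None
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)
    quartiles_skipped: list[str] = field(default_factory=list)
    dropped_days: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def count(self, rule: str) -> int:
        return self.rule_counts.get(rule, 0)

    @property
    def total_removed(self) -> int:
        return sum(self.rule_counts.values())

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.rule_counts.get(r, 0)} for r in POINT_RULES]
        rows.append({"rule": RULE_DAY_INCOMPLETE, "removed": self.count(RULE_DAY_INCOMPLETE)})
        rows.append({"rule": "input", "removed": self.input_count})
        rows.append({"rule": "surviving", "removed": self.surviving_count})
        return pd.DataFrame(rows)


def drop_pre_zt0(frame: pd.DataFrame) -> pd.DataFrame:
    """Discard, per mouse, every record before its first lights-on instant.

    A recording that starts mid-cycle (say ZT 20) contributes a partial
    pseudo-day; anchoring all mice at their first ZT 0 keeps the daily grid
    aligned with the light schedule.
    """
    if frame.empty:
        return frame.copy()
    df = frame.sort_values(["mouse_id", "timestamp"], kind="stable")
    keep = np.ones(len(df), dtype=bool)
    pos = 0
    for _, g in df.groupby("mouse_id", sort=False):
        z0 = float(g["zt"].iloc[0])
        if z0 > 1e-9:
            first_zt0 = g["timestamp"].iloc[0] + pd.to_timedelta(24.0 - z0, unit="h")
            keep[pos : pos + len(g)] = (
                g["timestamp"] >= first_zt0 - pd.Timedelta(seconds=1)
            ).to_numpy()
        pos += len(g)
    return df[keep].reset_index(drop=True)


def _q25_q75(x: np.ndarray) -> tuple[float, float]:
    # type-7 (linear interpolation) quartiles, the numpy default
    return float(np.quantile(x, 0.25)), float(np.quantile(x, 0.75))


def apply_point_rules(
    frame: pd.DataFrame,
    cfg: QCConfig | None = None,
    thresholds: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the per-datapoint discard rules in their fixed order.

    Order: (1) food sentinel, (2) negative food/water/dO2/dCO2,
    (3) per-mouse high intake outliers (food or water above Q75 + k*IQR),
    (4) per-mouse low gas outliers (dO2 or dCO2 below Q25 - k*IQR).
    Quartile thresholds are computed per mouse on the records surviving
    rules 1-2, once; pass ``thresholds`` (from a previous report) to reuse
    a fixed set.  Mice with fewer than 4 records surviving rules 1-2 get no
    quartile thresholds and are flagged in the report.
    """
    cfg = cfg or QCConfig()
    df = frame.reset_index(drop=True)
    report = QCReport(input_count=len(df))
    rule = pd.Series("", index=df.index, dtype=object)

    sentinel = (df["food_g"] - cfg.food_noise_g).abs() <= cfg.sentinel_tol_g
    rule[sentinel] = RULE_FOOD_SENTINEL

    negative = (
        (df["food_g"] < 0) | (df["water_g"] < 0) | (df["d_o2"] < 0) | (df["d_co2"] < 0)
    )
    rule[negative & (rule == "")] = RULE_NEGATIVE

    base = rule == ""  # survivors of rules 1-2: the quartile estimation set
    fitted: dict[str, dict[str, float]] = {}
    for mouse, g in df[base].groupby("mouse_id", sort=False):
        if thresholds is not None:
            if mouse in thresholds:
                fitted[mouse] = thresholds[mouse]
            else:
                report.quartiles_skipped.append(str(mouse))
            continue
        if len(g) < _MIN_RECORDS_FOR_QUARTILES:
            report.quartiles_skipped.append(str(mouse))
            continue
        t: dict[str, float] = {}
        for col in ("food_g", "water_g"):
            q25, q75 = _q25_q75(g[col].to_numpy(float))
            t[f"{col}_hi"] = q75 + cfg.iqr_multiplier * (q75 - q25)
        for col in ("d_o2", "d_co2"):
            q25, q75 = _q25_q75(g[col].to_numpy(float))
            t[f"{col}_lo"] = q25 - cfg.iqr_multiplier * (q75 - q25)
        fitted[mouse] = t
    report.thresholds = fitted

    hi = df["mouse_id"].map(lambda m: fitted.get(m, {}).get("food_g_hi", np.inf))
    hi_w = df["mouse_id"].map(lambda m: fitted.get(m, {}).get("water_g_hi", np.inf))
    intake_out = base & ((df["food_g"] > hi) | (df["water_g"] > hi_w))
    rule[intake_out & (rule == "")] = RULE_INTAKE_OUTLIER

    lo_o2 = df["mouse_id"].map(lambda m: fitted.get(m, {}).get("d_o2_lo", -np.inf))
    lo_co2 = df["mouse_id"].map(lambda m: fitted.get(m, {}).get("d_co2_lo", -np.inf))
    gas_out = base & ((df["d_o2"] < lo_o2) | (df["d_co2"] < lo_co2))
    rule[gas_out & (rule == "")] = RULE_GAS_OUTLIER

    removed_mask = rule != ""
    removed = df[removed_mask].copy()
    removed["rule"] = rule[removed_mask]
    survivors = df[~removed_mask].reset_index(drop=True)

    report.removed = removed.reset_index(drop=True)
    report.rule_counts = {r: int((removed["rule"] == r).sum()) for r in POINT_RULES}
    report.surviving_count = len(survivors)
    report.notes.append(
        "quartile thresholds pooled over all days of each mouse, computed once "
        "on records surviving the sentinel and negativity rules"
    )
    return survivors, report


def day_completeness_filter(
    frame: pd.DataFrame, cfg: QCConfig | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Drop every mouse-day missing strictly more than the allowed fraction.

    The denominator is the expected daily grid (24 h / cadence, i.e. 60
    records at the default 24-min cadence), not the observed count: removed
    records are exactly the grid slots with no surviving record, so at the
    default threshold a day with 12/60 slots lost is retained and one with
    13/60 is dropped.
    """
    cfg = cfg or QCConfig()
    report = QCReport(input_count=len(frame))
    if frame.empty:
        report.dropped_days = pd.DataFrame(columns=["mouse_id", "day", "removed_fraction"])
        report.rule_counts = {RULE_DAY_INCOMPLETE: 0}
        return frame.copy(), report

    df = add_time_axis(frame) if "day" not in frame.columns else frame.copy()
    expected = cfg.expected_per_day
    counts = df.groupby(["mouse_id", "day"]).size().rename("observed").reset_index()
    counts["removed_fraction"] = 1.0 - counts["observed"] / expected
    dropped = counts[counts["removed_fraction"] > cfg.day_removal_fraction + 1e-12]

    bad = set(zip(dropped["mouse_id"], dropped["day"]))
    mask = [
        (m, d) not in bad for m, d in zip(df["mouse_id"], df["day"])
    ]
    out = df[np.asarray(mask)].reset_index(drop=True)
    report.surviving_count = len(out)
    report.rule_counts = {RULE_DAY_INCOMPLETE: int(len(df) - len(out))}
    report.dropped_days = dropped[["mouse_id", "day", "removed_fraction"]].reset_index(
        drop=True
    )
    return out, report


def run_qc(
    frame: pd.DataFrame, cfg: QCConfig | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC chain: pre-ZT0 drop, point rules, day completeness.

    Returns the surviving records (with the continuous time axis attached)
    and a merged report whose counts satisfy
    ``input = surviving + pre_zt0 + sum(point rules) + day rule``.
    """
    cfg = cfg or QCConfig()
    df0 = drop_pre_zt0(frame)
    n_pre = len(frame) - len(df0)
    df0 = add_time_axis(df0) if not df0.empty else df0
    survivors, point_rep = apply_point_rules(df0, cfg)
    clean, day_rep = day_completeness_filter(survivors, cfg)

    report = QCReport(
        input_count=len(frame),
        surviving_count=len(clean),
        rule_counts={
            "pre_zt0": n_pre,
            **point_rep.rule_counts,
            **day_rep.rule_counts,
        },
        removed=point_rep.removed,
        thresholds=point_rep.thresholds,
        quartiles_skipped=point_rep.quartiles_skipped,
        dropped_days=day_rep.dropped_days,
        notes=point_rep.notes,
    )
    return clean, report
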