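"""Reading and writing calorimetry study tables.

Metabolic-cage exports are delimited text with one row per cage per
measurement interval (default cadence 24 min): gas differentials between the
measurement chamber and a reference chamber, food and water consumed during
the interval, and the extraction flow.  A :class:`StudyDialect` maps any
lab's column names, delimiter, decimal mark and timestamp format onto the
canonical schema used throughout the pipeline, and fixes the lights-on clock
time that anchors Zeitgeber time (ZT).

Zeitgeber time is hours elapsed since the most recent lights-on event,
modulo 24; ZT 0-12 is the light (resting) phase, ZT 12-24 the dark (active)
phase.  Phase membership is half-open: ZT 12.0 belongs to the dark phase.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical trace columns, in on-disk order
TRACE_FIELDS = (
    "mouse_id",
    "cage_id",
    "timestamp",
    "d_o2",
    "d_co2",
    "d_h2",
    "food_g",
    "water_g",
    "flow_lpm",
)

#: numeric trace columns that must parse for a row to be accepted
_NUMERIC_FIELDS = ("d_o2", "d_co2", "d_h2", "food_g", "water_g", "flow_lpm")

GROUPS = ("GF", "OLIGO", "SPF")

LIGHT_PHASE = "light"
DARK_PHASE = "dark"
FULL_DAY = "full_day"


class DialectError(ValueError):
    """The file does not conform to the declared dialect."""


@dataclass(frozen=True)
class StudyDialect:
    """On-disk dialect of a calorimetry export.

    Parameters
    ----------
    lights_on : datetime.time
        Wall-clock time at which the lights switch on; defines ZT 0.  The
        light schedule is a property of the animal room, so there is no
        default — it must be stated per study.
    column_map : dict
        Maps canonical field names (:data:`TRACE_FIELDS`) to the column
        names used in the file.  Identity by default.
    cadence_min : float
        Nominal spacing between consecutive records of one cage, minutes.
    """

    lights_on: dt.time
    delimiter: str = ","
    decimal: str = "."
    column_map: dict[str, str] = field(default_factory=dict)
    timestamp_format: str = "%Y-%m-%d %H:%M:%S"
    cadence_min: float = 24.0

    def __post_init__(self) -> None:
        unknown = set(self.column_map) - set(TRACE_FIELDS)
        if unknown:
            raise DialectError(f"column_map keys not canonical fields: {sorted(unknown)}")
        mapped = [self.column_map.get(f, f) for f in TRACE_FIELDS]
        if len(set(mapped)) != len(mapped):
            raise DialectError("column_map maps two fields to the same column")

    def file_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


@dataclass
class TraceRecord:
    """One 24-min cage measurement.

    Sign conventions: ``d_o2`` is reference-minus-cage O2 volume fraction
    (consumption positive); ``d_co2`` is cage-minus-reference CO2 fraction
    (production positive); ``d_h2`` is cage-minus-reference hydrogen in ppm.
    """

    mouse_id: str
    cage_id: str
    timestamp: dt.datetime
    d_o2: float
    d_co2: float
    d_h2: float
    food_g: float
    water_g: float
    flow_lpm: float
    zt: float = np.nan
    qc_flags: frozenset[str] = frozenset()


@dataclass
class MouseProfile:
    """Per-animal group and body-composition covariates (grams)."""

    mouse_id: str
    group: str
    total_mass_g: float
    total_mass_nocecum_g: float
    lean_mass_g: float
    fat_ibat_g: float
    fat_iwat_g: float
    fat_vwat_g: float
    cecal_mass_g: float

    @property
    def fat_total_g(self) -> float:
        return self.fat_ibat_g + self.fat_iwat_g + self.fat_vwat_g


PROFILE_FIELDS = tuple(f.name for f in dataclasses.fields(MouseProfile))


class TraceIngest(NamedTuple):
    frame: pd.DataFrame
    rejections: pd.DataFrame  # columns: row, reason


def to_zeitgeber(timestamp: dt.datetime | pd.Timestamp, lights_on: dt.time) -> float:
    """Hours elapsed since the most recent lights-on event, in [0, 24)."""
    anchor = dt.datetime.combine(
        timestamp.date() if isinstance(timestamp, (dt.datetime, pd.Timestamp)) else timestamp,
        lights_on,
    )
    anchor = pd.Timestamp(anchor)
    delta_h = (pd.Timestamp(timestamp) - anchor).total_seconds() / 3600.0
    return float(delta_h % 24.0)


def phase_of(zt: float) -> str:
    """Light/dark phase of a ZT value; half-open, ZT 12.0 is dark."""
    return LIGHT_PHASE if 0.0 <= (zt % 24.0) < 12.0 else DARK_PHASE


def read_traces(path: str | Path, dialect: StudyDialect) -> TraceIngest:
    """Read a calorimetry export into the canonical trace frame.

    Returns a frame sorted by (mouse_id, timestamp) with a computed ``zt``
    column and an empty ``qc_flags`` column, together with a table of
    rejected rows (missing mandatory values or unparseable timestamps), each
    with a reason.  An unmapped mandatory column is a format error and
    raises :class:`DialectError`.
    """
    raw = pd.read_csv(
        path,
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        dtype=str,
        keep_default_na=False,
        na_values=[""],
    )
    missing = [f for f in TRACE_FIELDS if dialect.file_column(f) not in raw.columns]
    if missing:
        raise DialectError(f"mandatory columns unmapped in file: {missing}")
    df = raw.rename(columns={dialect.file_column(f): f for f in TRACE_FIELDS})
    df = df[list(TRACE_FIELDS)].copy()

    rejections: list[tuple[int, str]] = []
    ts = pd.to_datetime(df["timestamp"], format=dialect.timestamp_format, errors="coerce")
    for col in _NUMERIC_FIELDS:
        if dialect.decimal != ".":
            df[col] = df[col].str.replace(dialect.decimal, ".", regex=False)
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["timestamp"] = ts

    bad_ts = ts.isna()
    bad_num = df[list(_NUMERIC_FIELDS)].isna().any(axis=1)
    bad_id = df["mouse_id"].isna() | df["cage_id"].isna()
    for idx in df.index[bad_ts]:
        rejections.append((int(idx), "unparseable timestamp"))
    for idx in df.index[~bad_ts & bad_num]:
        cols = [c for c in _NUMERIC_FIELDS if pd.isna(df.at[idx, c])]
        rejections.append((int(idx), f"missing/unparseable value: {','.join(cols)}"))
    for idx in df.index[~bad_ts & ~bad_num & bad_id]:
        rejections.append((int(idx), "missing identifier"))

    keep = ~(bad_ts | bad_num | bad_id)
    out = df[keep].copy()
    out["zt"] = [to_zeitgeber(t, dialect.lights_on) for t in out["timestamp"]]
    out["qc_flags"] = ""
    out = out.sort_values(["mouse_id", "timestamp"], kind="stable").reset_index(drop=True)
    rej = pd.DataFrame(rejections, columns=["row", "reason"])
    if len(rej):
        logger.warning("read_traces: rejected %d of %d rows", len(rej), len(df))
        for _, r in rej.iterrows():
            logger.info("  row %d: %s", r["row"], r["reason"])
    return TraceIngest(out, rej)


def write_traces(frame: pd.DataFrame, path: str | Path, dialect: StudyDialect) -> None:
    """Write the canonical columns of a trace frame under ``dialect``.

    Inverse of :func:`read_traces` for text-representable values; derived
    columns (zt, qc flags, exchange quantities) are not persisted.
    """
    out = frame[list(TRACE_FIELDS)].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(dialect.timestamp_format)
    out = out.rename(columns={f: dialect.file_column(f) for f in TRACE_FIELDS})
    out.to_csv(
        path,
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        index=False,
    )


def add_time_axis(frame: pd.DataFrame) -> pd.DataFrame:
    """Attach a continuous per-mouse time axis and day index.

    ``t_h`` is hours since the mouse's first ZT 0 instant (the lights-on
    event preceding its first record); ``day`` is ``floor(t_h / 24)``.
    Meaningful once records before the first ZT 0 have been discarded.
    """
    df = frame.sort_values(["mouse_id", "timestamp"], kind="stable").copy()
    first = df.groupby("mouse_id").agg(ts0=("timestamp", "first"), zt0=("zt", "first"))
    anchor = first["ts0"] - pd.to_timedelta(first["zt0"], unit="h")
    df["t_h"] = (
        df["timestamp"] - df["mouse_id"].map(anchor)
    ).dt.total_seconds() / 3600.0
    df["day"] = np.floor(df["t_h"] / 24.0).astype(int)
    return df


def read_profiles(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate the per-mouse body-composition table."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in PROFILE_FIELDS if c not in df.columns]
    if missing:
        raise DialectError(f"profile table missing columns: {missing}")
    validate_profiles(df)
    return df


def write_profiles(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    df[list(PROFILE_FIELDS)].to_csv(path, sep=delimiter, index=False)


def validate_profiles(df: pd.DataFrame, mass_tol_g: float = 0.05) -> None:
    """Check profile invariants; raise ValueError on violation.

    Total mass without cecum must equal total minus cecal mass within
    ``mass_tol_g`` (dissection bookkeeping), all masses must be
    non-negative, and the dissected fat depots cannot exceed total mass.
    """
    mass_cols = [
        "total_mass_g",
        "total_mass_nocecum_g",
        "lean_mass_g",
        "fat_ibat_g",
        "fat_iwat_g",
        "fat_vwat_g",
        "cecal_mass_g",
    ]
    if (df[mass_cols] < 0).any().any():
        raise ValueError("negative mass in profile table")
    resid = df["total_mass_g"] - df["cecal_mass_g"] - df["total_mass_nocecum_g"]
    if (resid.abs() > mass_tol_g).any():
        bad = df.loc[resid.abs() > mass_tol_g, "mouse_id"].tolist()
        raise ValueError(f"total/nocecum/cecal masses inconsistent for {bad}")
    fat = df[["fat_ibat_g", "fat_iwat_g", "fat_vwat_g"]].sum(axis=1)
    if (fat > df["total_mass_g"]).any():
        raise ValueError("fat depot sum exceeds total mass")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups: {sorted(bad_group)}")


def records_to_frame(records: list[TraceRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(TRACE_FIELDS) + ["zt", "qc_flags"])
    df["qc_flags"] = [",".join(sorted(r.qc_flags)) for r in records]
    return df


def frame_to_records(frame: pd.DataFrame) -> list[TraceRecord]:
    out = []
    for _, row in frame.iterrows():
        flags = row.get("qc_flags", "")
        out.append(
            TraceRecord(
                mouse_id=row["mouse_id"],
                cage_id=row["cage_id"],
                timestamp=row["timestamp"],
                d_o2=row["d_o2"],
                d_co2=row["d_co2"],
                d_h2=row["d_h2"],
                food_g=row["food_g"],
                water_g=row["water_g"],
                flow_lpm=row["flow_lpm"],
                zt=row.get("zt", np.nan),
                qc_flags=frozenset(x for x in str(flags).split(",") if x),
            )
        )
    return out
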