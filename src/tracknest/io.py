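"""Track table I/O and experimental-hierarchy handling.

Two-photon motility experiments produce a nested sampling design: cells are
tracked within microscopic fields, fields within lymph nodes, nodes within
mice, mice within imaging dates.  Raw labels ("mouse1", "LN1", ...) are only
unique within their parent, so every level gets a globally unique ID built by
concatenating the (escaped) labels of all its ancestors.  Those unique IDs are
what the grouping structure of the nested random-effects models is built from.

The canonical on-disk format is a long CSV, one row per tracked position:

    date,mouse,lymph_node,field,track_id,population,dye,time_s,x_um,y_um,z_um

Other column names and units are accommodated through :class:`Dialect`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "TrackSet",
    "HierarchyReport",
    "SchemaError",
    "ValidationError",
    "read_tracks",
    "write_tracks",
    "write_steps",
    "read_steps",
    "trackset_from_frame",
    "validate_hierarchy",
    "unique_id",
]

#: hierarchy levels from top to bottom (raw-label column names)
LEVELS = ("date", "mouse", "lymph_node", "field", "track_id")

#: unique-ID column per level
UID_COLUMNS = {
    "date": "uid_date",
    "mouse": "uid_mouse",
    "lymph_node": "uid_lymph_node",
    "field": "uid_field",
    "track_id": "uid_track",
}

LABEL_COLUMNS = LEVELS + ("population", "dye")
VALUE_COLUMNS = ("time_s", "x_um", "y_um", "z_um")
REQUIRED_COLUMNS = LABEL_COLUMNS + VALUE_COLUMNS

_SEP = "|"
_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "min": 60.0, "ms": 1e-3, "h": 3600.0}
_POS_FACTORS = {"um": 1.0, "mm": 1e3, "nm": 1e-3, "m": 1e6}


class SchemaError(ValueError):
    """Input table does not provide a required column."""


class ValidationError(ValueError):
    """Input table violates a track-level invariant."""


def _escape(label: str) -> str:
    return str(label).replace("\\", "\\\\").replace(_SEP, "\\" + _SEP)


def unique_id(*labels) -> str:
    """Join raw labels into one globally unique ID.

    The separator is escaped inside labels, so the mapping from label tuples
    to IDs is injective even for adversarial labels.
    """
    return _SEP.join(_escape(lab) for lab in labels)


@dataclass(frozen=True)
class Dialect:
    """Column-name and unit mapping for foreign track CSVs.

    Parameters
    ----------
    columns : mapping canonical name -> actual column name in the file.
        Only names that differ from the canonical schema need to be listed.
    time_unit : unit of the time column ("s", "min", "ms", "h").
    position_unit : unit of the position columns ("um", "mm", "nm", "m").
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    time_unit: str = "s"
    position_unit: str = "um"

    def actual(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Dialect":
        d = dict(d)
        return cls(
            columns=dict(d.get("columns", {})),
            time_unit=str(d.get("time_unit", "s")),
            position_unit=str(d.get("position_unit", "um")),
        )


DEFAULT_DIALECT = Dialect()


@dataclass
class TrackSet:
    """A collection of 3D cell tracks with their experimental hierarchy.

    ``frame`` holds one row per tracked position, sorted by unique track ID
    and time, with both raw label columns and uid_* columns present.
    """

    frame: pd.DataFrame
    provenance: str = "unknown"

    @property
    def n_tracks(self) -> int:
        return self.frame["uid_track"].nunique()

    @property
    def n_points(self) -> int:
        return len(self.frame)

    def track_ids(self) -> np.ndarray:
        return self.frame["uid_track"].unique()

    def with_frame(self, frame: pd.DataFrame, note: str | None = None) -> "TrackSet":
        prov = self.provenance if note is None else f"{self.provenance} [{note}]"
        return TrackSet(frame=frame, provenance=prov)


@dataclass
class HierarchyReport:
    """Per-level counts and aliasing diagnosis of a TrackSet.

    A level is *aliased* when it is in one-to-one correspondence with its
    immediate child level (e.g. one mouse per date): its variance contribution
    is then inseparable from the child's, and nested fits should drop it.
    """

    n_dates: int
    n_mice: int
    n_nodes: int
    n_fields: int
    n_tracks: int
    n_steps: int
    aliased_levels: list[str]

    def counts(self) -> dict[str, int]:
        return {
            "dates": self.n_dates,
            "mice": self.n_mice,
            "nodes": self.n_nodes,
            "fields": self.n_fields,
            "tracks": self.n_tracks,
            "steps": self.n_steps,
        }


def _add_unique_ids(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    parts = []
    for level in LEVELS:
        parts.append(df[level].astype(str).map(_escape))
        acc = parts[0]
        for p in parts[1:]:
            acc = acc + _SEP + p
        df[UID_COLUMNS[level]] = acc
    return df


def trackset_from_frame(df: pd.DataFrame, provenance: str = "in-memory") -> TrackSet:
    """Build a validated TrackSet from a canonical-schema DataFrame.

    Sorts points by time within tracks, constructs unique hierarchy IDs and
    enforces the track invariants (strictly increasing time, finite positions,
    one population and dye per track).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    for c in VALUE_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise")
    if not np.isfinite(df[list(VALUE_COLUMNS)].to_numpy(float)).all():
        raise ValidationError("non-finite time or position values present")
    df = _add_unique_ids(df)
    df = df.sort_values(["uid_track", "time_s"], kind="mergesort").reset_index(drop=True)

    dup = df.duplicated(subset=["uid_track", "time_s"])
    if dup.any():
        bad = df.loc[dup, "uid_track"].iloc[0]
        raise ValidationError(f"duplicate (track, time) row in track {bad!r}")
    # after a stable sort, time is strictly increasing iff no duplicates,
    # but guard against NaNs that escaped the finite check
    t = df["time_s"].to_numpy(float)
    same = df["uid_track"].to_numpy()
    within = same[1:] == same[:-1]
    if np.any(within & ~(np.diff(t) > 0)):
        bad = df["uid_track"].to_numpy()[1:][within & ~(np.diff(t) > 0)][0]
        raise ValidationError(f"non-monotone time within track {bad!r}")
    if (df["time_s"] < 0).any():
        raise ValidationError("negative time values present")

    lab = df.groupby("uid_track")[["population", "dye"]].nunique()
    multi = lab[(lab > 1).any(axis=1)]
    if len(multi):
        raise ValidationError(
            f"track {multi.index[0]!r} carries more than one population or dye label"
        )
    return TrackSet(frame=df, provenance=provenance)


def read_tracks(path, dialect: Dialect | None = None) -> TrackSet:
    """Read a track CSV into a TrackSet.

    The file must have a header row.  Column names and units are remapped via
    ``dialect``; times are converted to seconds and positions to micrometres.
    """
    dialect = dialect or DEFAULT_DIALECT
    raw = pd.read_csv(path)
    rename = {}
    missing = []
    for canonical in REQUIRED_COLUMNS:
        actual = dialect.actual(canonical)
        if actual not in raw.columns:
            missing.append(f"{canonical} (expected file column {actual!r})")
        else:
            rename[actual] = canonical
    if missing:
        raise SchemaError("missing required column(s): " + "; ".join(missing))
    df = raw.rename(columns=rename)[list(REQUIRED_COLUMNS)]

    try:
        tf = _TIME_FACTORS[dialect.time_unit]
    except KeyError:
        raise SchemaError(f"unknown time unit {dialect.time_unit!r}") from None
    try:
        pf = _POS_FACTORS[dialect.position_unit]
    except KeyError:
        raise SchemaError(f"unknown position unit {dialect.position_unit!r}") from None
    df["time_s"] = pd.to_numeric(df["time_s"], errors="raise") * tf
    for c in ("x_um", "y_um", "z_um"):
        df[c] = pd.to_numeric(df[c], errors="raise") * pf
    return trackset_from_frame(df, provenance=str(path))


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet back to canonical CSV (raw labels only, no uid columns)."""
    ts.frame[list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def write_steps(steps: pd.DataFrame, path) -> None:
    """Write a step or cell table to CSV (lossless round trip via read_steps)."""
    steps.to_csv(Path(path), index=False)


def read_steps(path) -> pd.DataFrame:
    return pd.read_csv(path)


def validate_hierarchy(ts: TrackSet) -> HierarchyReport:
    """Count units per hierarchy level and flag perfectly confounded levels.

    Because unique IDs are nested (every child belongs to exactly one parent),
    a parent level is in bijection with its child level exactly when the two
    levels have the same number of distinct values; the parent is then
    reported in ``aliased_levels``.
    """
    df = ts.frame
    if not len(df):
        raise ValidationError("empty TrackSet")
    counts = {level: df[UID_COLUMNS[level]].nunique() for level in LEVELS}
    n_steps = int(
        (df.groupby("uid_track", sort=False).size() - 1).clip(lower=0).sum()
    )
    aliased = []
    for parent, child in zip(LEVELS[:-1], LEVELS[1:]):
        if counts[parent] == counts[child]:
            aliased.append(parent)
    return HierarchyReport(
        n_dates=counts["date"],
        n_mice=counts["mouse"],
        n_nodes=counts["lymph_node"],
        n_fields=counts["field"],
        n_tracks=counts["track_id"],
        n_steps=n_steps,
        aliased_levels=aliased,
    )
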