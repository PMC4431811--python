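"""Step- and cell-based motility parameters, and track filters.

A track of T positions yields T-1 *steps*.  Each step has an instantaneous
speed (3D displacement over its own frame interval, in um/min) and, from the
second step on, a turning angle in degrees between the current and previous
step vectors (0 deg = straight ahead).  Pooling steps across all tracks gives
step-based parameters; summarising each track to its mean/median gives
cell-based parameters.

Track filters remove non-motile or too-short tracks before any statistics:
fewer than 3 time steps, total path length below 17 um (~3 cell diameters),
or squared net displacement below 300 um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LABEL_COLUMNS, UID_COLUMNS, TrackSet, ValidationError

__all__ = [
    "FilterConfig",
    "FilterReport",
    "StepComputer",
    "TrackFilter",
    "CellSummarizer",
    "compute_steps",
    "apply_track_filters",
    "cell_summaries",
    "track_metrics",
]

_CARRY = list(LABEL_COLUMNS) + [UID_COLUMNS[k] for k in UID_COLUMNS]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three track filters.

    min_time_steps counts *steps* (a track with T points has T-1 steps);
    min_path_length is the summed step length in um; min_displacement_sq is
    the squared start-to-end straight-line displacement in um^2.
    """

    min_time_steps: int = 3
    min_path_length: float = 17.0
    min_displacement_sq: float = 300.0
    filter_duration: bool = True
    filter_path_length: bool = True
    filter_displacement: bool = True

    def __post_init__(self):
        if self.min_time_steps < 0 or self.min_path_length < 0 or self.min_displacement_sq < 0:
            raise ValueError("filter thresholds must be nonnegative")

    @classmethod
    def disabled(cls) -> "FilterConfig":
        return cls(filter_duration=False, filter_path_length=False, filter_displacement=False)


@dataclass
class FilterReport:
    """How many tracks each rule removed.

    A track failing several rules is counted once per rule but removed once.
    """

    n_input: int = 0
    n_retained: int = 0
    n_removed: int = 0
    removed_by_rule: dict = field(default_factory=dict)


def _step_arrays(df: pd.DataFrame):
    """Vectorised per-step quantities for a time-sorted track frame."""
    xyz = df[["x_um", "y_um", "z_um"]].to_numpy(float)
    t = df["time_s"].to_numpy(float)
    track = df["uid_track"].to_numpy()
    d = np.diff(xyz, axis=0)
    dt = np.diff(t)
    same = track[1:] == track[:-1]  # rows that are steps (same track as previous)
    return xyz, t, track, d, dt, same


def track_metrics(ts: TrackSet) -> pd.DataFrame:
    """Per-track step count, duration, path length and net displacement."""
    df = ts.frame
    _, t, track, d, dt, same = _step_arrays(df)
    step_len = np.linalg.norm(d, axis=1)
    step_len = np.where(same, step_len, 0.0)
    g = df.groupby("uid_track", sort=False)
    first = g.head(1).set_index("uid_track")
    last = g.tail(1).set_index("uid_track")
    agg = pd.DataFrame(index=first.index)
    agg["n_steps"] = g.size().to_numpy() - 1
    agg["duration_s"] = last["time_s"] - first["time_s"]
    path = pd.Series(step_len, index=df.index[:-1]).groupby(track[:-1]).sum()
    # tracks whose only row is the frame's last row contribute no step rows
    agg["path_length_um"] = path.reindex(agg.index).fillna(0.0)
    disp = np.linalg.norm(
        last[["x_um", "y_um", "z_um"]].to_numpy(float)
        - first[["x_um", "y_um", "z_um"]].to_numpy(float),
        axis=1,
    )
    agg["displacement_um"] = disp
    agg["displacement_sq_um2"] = disp**2
    return agg


class StepComputer(BaseEstimator, TransformerMixin):
    """Transformer turning a TrackSet into a step table.

    The output DataFrame has one row per step with the full hierarchy and
    treatment labels, the step vector (dx, dy, dz), dt in seconds, speed in
    um/min and turning angle in degrees ([0, 180], NaN for the first step of
    each track and for steps adjacent to a zero-length step vector).
    """

    def fit(self, X: TrackSet, y=None):
        return self

    def transform(self, X: TrackSet) -> pd.DataFrame:
        df = X.frame
        if not len(df):
            raise ValidationError("empty TrackSet")
        _, t, track, d, dt, same = _step_arrays(df)
        if np.any(same & ~(dt > 0)):
            bad = track[1:][same & ~(dt > 0)][0]
            raise ValidationError(f"non-positive frame interval in track {bad!r}")

        norm = np.linalg.norm(d, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            speed = norm / dt * 60.0  # um/s -> um/min

        # turning angle between consecutive step vectors of the same track
        v1, v2 = d[:-1], d[1:]
        n1, n2 = norm[:-1], norm[1:]
        consec = same[:-1] & same[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
        cosang = np.clip(cosang, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        ang[~consec] = np.nan
        ang[(n1 == 0) | (n2 == 0)] = np.nan
        angle = np.full(len(d), np.nan)
        angle[1:] = ang

        rows = df.iloc[1:].reset_index(drop=True)
        out = rows[_CARRY].copy()
        out["time_s"] = t[1:]
        out["dt_s"] = dt
        out["dx_um"], out["dy_um"], out["dz_um"] = d[:, 0], d[:, 1], d[:, 2]
        out["speed"] = speed
        out["angle"] = angle
        out = out[same].reset_index(drop=True)
        out["step_index"] = out.groupby("uid_track", sort=False).cumcount()
        return out


class TrackFilter(BaseEstimator, TransformerMixin):
    """Transformer applying the duration / path-length / displacement filters.

    After ``transform`` the removal counts are available as ``report_``.
    """

    def __init__(self, min_time_steps: int = 3, min_path_length: float = 17.0,
                 min_displacement_sq: float = 300.0, filter_duration: bool = True,
                 filter_path_length: bool = True, filter_displacement: bool = True):
        self.min_time_steps = min_time_steps
        self.min_path_length = min_path_length
        self.min_displacement_sq = min_displacement_sq
        self.filter_duration = filter_duration
        self.filter_path_length = filter_path_length
        self.filter_displacement = filter_displacement

    def _config(self) -> FilterConfig:
        return FilterConfig(
            min_time_steps=self.min_time_steps,
            min_path_length=self.min_path_length,
            min_displacement_sq=self.min_displacement_sq,
            filter_duration=self.filter_duration,
            filter_path_length=self.filter_path_length,
            filter_displacement=self.filter_displacement,
        )

    def fit(self, X: TrackSet, y=None):
        return self

    def transform(self, X: TrackSet) -> TrackSet:
        cfg = self._config()
        metrics = track_metrics(X)
        removed = {}
        drop = pd.Series(False, index=metrics.index)
        if cfg.filter_duration:
            bad = metrics["n_steps"] < cfg.min_time_steps
            removed["duration"] = int(bad.sum())
            drop |= bad
        if cfg.filter_path_length:
            bad = metrics["path_length_um"] < cfg.min_path_length
            removed["path_length"] = int(bad.sum())
            drop |= bad
        if cfg.filter_displacement:
            bad = metrics["displacement_sq_um2"] < cfg.min_displacement_sq
            removed["displacement_sq"] = int(bad.sum())
            drop |= bad
        keep_ids = set(metrics.index[~drop])
        frame = X.frame[X.frame["uid_track"].isin(keep_ids)].reset_index(drop=True)
        self.report_ = FilterReport(
            n_input=len(metrics),
            n_retained=len(keep_ids),
            n_removed=int(drop.sum()),
            removed_by_rule=removed,
        )
        return X.with_frame(frame, note="filtered")


class CellSummarizer(BaseEstimator, TransformerMixin):
    """Collapse a step table to one row per cell (track).

    Produces mean and median of speed and angle (missing angles excluded),
    step count, duration, path length and net displacement, plus ``speed`` and
    ``angle`` response columns set to the summary chosen by ``stat``.
    """

    def __init__(self, stat: str = "mean"):
        self.stat = stat

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.stat not in ("mean", "median"):
            raise ValueError(f"stat must be 'mean' or 'median', got {self.stat!r}")
        if not len(X):
            raise ValidationError("empty step table")
        g = X.groupby("uid_track", sort=False)
        out = g[_CARRY].first()
        out["n_steps"] = g.size()
        out["duration_s"] = g["dt_s"].sum()
        step_len = X["speed"] * X["dt_s"] / 60.0
        out["path_length_um"] = step_len.groupby(X["uid_track"], sort=False).sum()
        disp = g[["dx_um", "dy_um", "dz_um"]].sum()
        out["displacement_um"] = np.linalg.norm(disp.to_numpy(float), axis=1)
        out["speed_mean"] = g["speed"].mean()
        out["speed_median"] = g["speed"].median()
        out["angle_mean"] = g["angle"].mean()
        out["angle_median"] = g["angle"].median()
        out["speed"] = out[f"speed_{self.stat}"]
        out["angle"] = out[f"angle_{self.stat}"]
        return out.reset_index(drop=True)


def compute_steps(ts: TrackSet) -> pd.DataFrame:
    """Convert a TrackSet into a step table (see :class:`StepComputer`)."""
    return StepComputer().transform(ts)


def apply_track_filters(ts: TrackSet, cfg: FilterConfig | None = None):
    """Apply the track filters; returns (filtered TrackSet, FilterReport)."""
    cfg = cfg or FilterConfig()
    tf = TrackFilter(**{k: getattr(cfg, k) for k in (
        "min_time_steps", "min_path_length", "min_displacement_sq",
        "filter_duration", "filter_path_length", "filter_displacement")})
    out = tf.transform(ts)
    return out, tf.report_


def cell_summaries(steps: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """One-row-per-cell summary of a step table (see :class:`CellSummarizer`)."""
    return CellSummarizer(stat=stat).transform(steps)
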