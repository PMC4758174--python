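"""Telemetry tracks, movement bursts and nightly distances.

Radio-tracked squirrels are followed on foot at night; a fix is recorded
every time the animal changes location, together with the number of minutes
it stayed put there (0 while moving).  A movement *burst* is a continuous
period of movement delimited by periods of inactivity at least
``inactivity_threshold`` minutes long.  The stop fix that ends one burst is
also the start of the next, so burst lengths partition the nightly distance
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import HabitatClass, composition_along_buffer, composition_in_region

#: Default minutes of inactivity that split a night into separate bursts.
DEFAULT_INACTIVITY_THRESHOLD = 10.0


class DataInconsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class Fix:
    """One telemetry relocation."""

    individual_id: str
    sex: str  # 'F' or 'M'
    timestamp: pd.Timestamp
    x: float
    y: float
    stationary_minutes: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("fix coordinates must be finite")
        if self.stationary_minutes < 0:
            raise ValueError("stationary_minutes must be non-negative")


def _polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


@dataclass(frozen=True)
class MovementBurst:
    """A continuous run of movement fixes within one night."""

    fixes: tuple[Fix, ...]
    length: float = field(init=False)
    duration: float = field(init=False)
    speed: float = field(init=False)

    def __post_init__(self) -> None:
        pts = np.array([(f.x, f.y) for f in self.fixes])
        length = _polyline_length(pts)
        if len(self.fixes) >= 2:
            t0, t1 = self.fixes[0].timestamp, self.fixes[-1].timestamp
            duration = (t1 - t0).total_seconds() / 60.0
            # Time parked at the start or at interior stops is not time in
            # motion; the last fix's stationary time falls after arrival.
            duration -= sum(f.stationary_minutes for f in self.fixes[:-1])
        else:
            duration = 0.0
        if length > 0 and duration <= 0:
            raise DataInconsistencyError(
                f"burst of individual {self.fixes[0].individual_id!r} moved "
                f"{length:.1f} m in non-positive duration {duration:.1f} min"
            )
        speed = length / duration if duration > 0 else 0.0
        object.__setattr__(self, "length", length)
        object.__setattr__(self, "duration", duration)
        object.__setattr__(self, "speed", speed)

    @property
    def points(self) -> np.ndarray:
        return np.array([(f.x, f.y) for f in self.fixes])


@dataclass(frozen=True)
class NightTrack:
    """All fixes of one individual during one nightly tracking period."""

    fixes: tuple[Fix, ...]

    def __post_init__(self) -> None:
        ts = [f.timestamp for f in self.fixes]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be strictly increasing within a night")

    @property
    def individual_id(self) -> str:
        return self.fixes[0].individual_id

    @property
    def sex(self) -> str:
        return self.fixes[0].sex

    @property
    def night(self) -> pd.Timestamp:
        """The date the tracking period started (spans of midnight keep it)."""
        return self.fixes[0].timestamp.normalize()

    @property
    def tracking_duration(self) -> float:
        if len(self.fixes) < 2:
            return 0.0
        last = self.fixes[-1]
        span = (last.timestamp - self.fixes[0].timestamp).total_seconds() / 60.0
        return span + last.stationary_minutes


def merge_repeated_fixes(fixes) -> tuple[Fix, ...]:
    """Merge consecutive fixes at the same tree, accumulating stationary time."""
    merged: list[Fix] = []
    for f in fixes:
        if merged and (f.x, f.y) == (merged[-1].x, merged[-1].y):
            prev = merged[-1]
            merged[-1] = Fix(
                prev.individual_id, prev.sex, prev.timestamp, prev.x, prev.y,
                prev.stationary_minutes + f.stationary_minutes,
            )
        else:
            merged.append(f)
    return tuple(merged)


def extract_bursts(
    track: NightTrack, inactivity_threshold: float = DEFAULT_INACTIVITY_THRESHOLD
) -> list[MovementBurst]:
    """Split a night into movement bursts at long stationary periods.

    A fix whose ``stationary_minutes`` is at least the threshold ends the
    current burst and opens the next one (the stop location belongs to both,
    so no movement is lost).  A night with no movement at all — every fix
    stationary, or a single fix — yields no bursts.
    """
    if inactivity_threshold <= 0:
        raise ValueError("inactivity_threshold must be positive")
    segments: list[list[Fix]] = []
    current: list[Fix] = []
    for f in track.fixes:
        current.append(f)
        if f.stationary_minutes >= inactivity_threshold:
            segments.append(current)
            current = [f]
    segments.append(current)
    bursts = []
    for seg in segments:
        pts = np.array([(g.x, g.y) for g in seg])
        if len(seg) >= 2 and _polyline_length(pts) > 0:
            bursts.append(MovementBurst(fixes=tuple(seg)))
    return bursts


def burst_metrics(burst: MovementBurst) -> tuple[float, float, float]:
    """(length m, duration min, speed m/min) of a burst."""
    return burst.length, burst.duration, burst.speed


def nightly_distance(track: NightTrack) -> float:
    """Total Euclidean path length over the whole night.

    Stationary periods contribute zero because consecutive fixes at the same
    location are zero-length segments.
    """
    pts = np.array([(f.x, f.y) for f in track.fixes])
    return _polyline_length(pts)


def tracks_from_frame(df: pd.DataFrame) -> list[NightTrack]:
    """Build NightTracks from a telemetry table.

    Expected columns: individual_id, sex, datetime (ISO 8601), x, y,
    stationary_minutes.  Rows are grouped into nights by individual and the
    date the tracking period started; fixes repeated at the same tree are
    merged.
    """
    df = df.copy()
    df["datetime"] = pd.to_datetime(df["datetime"])
    df = df.sort_values(["individual_id", "datetime"])
    tracks = []
    for (_ind, _night), grp in df.groupby(
        ["individual_id", df["datetime"].dt.normalize()], sort=True
    ):
        fixes = [
            Fix(r.individual_id, r.sex, r.datetime, float(r.x), float(r.y),
                float(r.stationary_minutes))
            for r in grp.itertuples()
        ]
        tracks.append(NightTrack(fixes=merge_repeated_fixes(fixes)))
    return tracks


#: Data dictionary for the tidy model frame written by export_model_frame.
MODEL_FRAME_COLUMNS = [
    "individual_id",       # token
    "sex",                 # F / M
    "night",               # date the tracking period started (ISO)
    "month",               # calendar month 1-12 of the night
    "burst_id",            # 0-based burst index within the night; -1 = night row
    "response_length_m",   # burst length (burst rows) / nightly distance (night rows)
    "response_speed_m_min",  # burst speed; NaN on night rows
    "log_duration_min",    # log burst duration (burst rows) / log tracking time (night)
    "h1_buffer", "h2_buffer", "h3_buffer",  # proportions in 25 m burst buffer
    "h1_hr", "h2_hr", "h3_hr",              # proportions in the 100% MCP
    "hr_area_ha",          # home-range size
    "flag",                # '' or reason a covariate is missing
]


def export_model_frame(tracks, home_ranges, raster, *,
                       inactivity_threshold: float = DEFAULT_INACTIVITY_THRESHOLD,
                       buffer_radius: float = 25.0) -> pd.DataFrame:
    """Tidy burst- and night-level table ready for downstream mixed models.

    One row per movement burst (response = length, speed) and one row per
    night (response = nightly distance).  Habitat covariates are H1-H3
    proportions in a 25 m buffer along the burst and within the individual's
    home range.  Rows with an uncomputable covariate are flagged, never
    dropped.
    """
    rows = []
    hr_comp_cache: dict[str, dict] = {}
    for track in tracks:
        ind = track.individual_id
        hr = home_ranges.get(ind)
        if hr is not None and ind not in hr_comp_cache:
            hr_comp_cache[ind] = composition_in_region(raster, hr)
        hr_comp = hr_comp_cache.get(ind)

        def base_row(flag=""):
            row = {c: np.nan for c in MODEL_FRAME_COLUMNS}
            row.update(
                individual_id=ind, sex=track.sex,
                night=track.night.date().isoformat(),
                month=int(track.night.month), flag=flag,
            )
            if hr is not None:
                row["hr_area_ha"] = hr.area_ha
                for k in (1, 2, 3):
                    row[f"h{k}_hr"] = hr_comp[HabitatClass(k)]
            else:
                row["flag"] = "missing_home_range"
            return row

        bursts = extract_bursts(track, inactivity_threshold)
        for b_id, burst in enumerate(bursts):
            row = base_row()
            row.update(burst_id=b_id, response_length_m=burst.length,
                       response_speed_m_min=burst.speed,
                       log_duration_min=np.log(burst.duration) if burst.duration > 0 else np.nan)
            try:
                comp = composition_along_buffer(raster, burst.points, buffer_radius)
                for k in (1, 2, 3):
                    row[f"h{k}_buffer"] = comp[HabitatClass(k)]
            except ValueError:
                row["flag"] = (row["flag"] + ";" if row["flag"] else "") + "buffer_outside_raster"
            rows.append(row)

        night_row = base_row()
        dur = track.tracking_duration
        night_row.update(burst_id=-1, response_length_m=nightly_distance(track),
                         log_duration_min=np.log(dur) if dur > 0 else np.nan)
        rows.append(night_row)

    return pd.DataFrame(rows, columns=MODEL_FRAME_COLUMNS)
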