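"""Track-environment syncing: hourly positions, wind/swell extraction, relative angles.

Builds the hourly modeling table: one row per bird-hour of continuous
flight carrying the flap count, windspeed (km/h), significant swell
height (m), and the folded bird-wind and bird-swell angles (BWA, BSA,
degrees in [0, 180]; 0 = traveling with the wind/swell, 180 = directly
against it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .accel import FlapEvents, flaps_per_hour
from .geo import initial_bearing
from .hmm import StateSequence

__all__ = [
    "EnvGrid",
    "interpolate_track",
    "wind_speed_dir",
    "relative_angle",
    "extract_env",
    "hourly_aggregate",
]


@dataclass
class EnvGrid:
    """Hourly gridded environment fields on a regular lat/lon grid.

    Wraps an :class:`xarray.Dataset` with dims ``(time, lat, lon)`` and
    variables ``u10``/``v10`` (10-m wind components, m/s), ``swh``
    (significant height of total swell, m) and ``mwd`` (mean swell
    direction, degrees). ``swell_convention`` declares whether ``mwd``
    is the direction the swell comes *from* (meteorological, like wind)
    or travels *toward*; the bird-swell angle flips accordingly.
    """

    ds: xr.Dataset
    swell_convention: str = "from"

    def __post_init__(self) -> None:
        for v in ("u10", "v10", "swh", "mwd"):
            if v not in self.ds:
                raise ValueError(f"environment dataset is missing variable {v!r}")
        if self.swell_convention not in ("from", "toward"):
            raise ValueError("swell_convention must be 'from' or 'toward'")
        if float(self.ds["swh"].min()) < 0:
            raise ValueError("swell height must be non-negative")

    @property
    def hours(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.ds["time"].values)


def interpolate_track(
    fixes: pd.DataFrame, interval_min: int = 10, max_gap_min: float = 60.0
) -> pd.DataFrame:
    """Linearly interpolate GPS fixes onto a uniform grid of wall-clock times.

    The grid runs at ``interval_min`` minutes snapped to round wall-clock
    multiples. Positions inside recording gaps longer than
    ``max_gap_min`` are left missing rather than bridged.
    """
    ts = pd.to_datetime(fixes["timestamp"]).to_numpy()
    if np.any(np.diff(ts) < np.timedelta64(0, "s")):
        raise ValueError("GPS timestamps are not time-ordered")
    t = ts.astype("datetime64[s]").astype(float)
    step = interval_min * 60
    t0 = np.ceil(t[0] / step) * step
    t1 = np.floor(t[-1] / step) * step
    grid = np.arange(t0, t1 + step / 2, step)
    lat = np.interp(grid, t, fixes["lat"].to_numpy(dtype=float))
    lon = np.interp(grid, t, fixes["lon"].to_numpy(dtype=float))
    # flag grid points that fall inside an over-long recording gap
    gaps = np.diff(t)
    too_long = np.flatnonzero(gaps > max_gap_min * 60)
    missing = np.zeros(grid.size, dtype=bool)
    for i in too_long:
        missing |= (grid > t[i]) & (grid < t[i + 1])
    lat[missing] = np.nan
    lon[missing] = np.nan
    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(grid, unit="s"),
            "lat": lat,
            "lon": lon,
        }
    )
    if "bird_id" in fixes.columns:
        out.insert(0, "bird_id", fixes["bird_id"].iloc[0])
    return out


def wind_speed_dir(u, v):
    """Wind speed (km/h) and meteorological direction from u/v components (m/s).

    ``wind_from`` is the direction the wind blows *from*, degrees
    clockwise from north: (0, -5) is a northerly (from the north),
    (-5, 0) an easterly.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = 3.6 * np.hypot(u, v)
    wind_from = np.mod(270.0 - np.degrees(np.arctan2(v, u)), 360.0)
    return speed, wind_from


def relative_angle(bearing, origin_dir):
    """Folded angle in [0, 180] between travel bearing and a flow's travel direction.

    ``origin_dir`` is the direction the wind or swell comes *from*; the
    flow travels toward ``origin_dir + 180``. 0 means moving with the
    flow (direct tailwind), 180 directly against it (headwind), 90 a
    crossflow. Adding a common rotation to both arguments leaves the
    result unchanged.
    """
    bearing = np.asarray(bearing, dtype=float)
    origin_dir = np.asarray(origin_dir, dtype=float)
    travel_with = np.mod(origin_dir + 180.0, 360.0)
    d = np.mod(np.abs(bearing - travel_with), 360.0)
    return np.minimum(d, 360.0 - d)


def extract_env(grid: EnvGrid, lat, lon, hour) -> dict[str, float]:
    """Bilinear spatial interpolation of the hourly fields at a position.

    The grid is hourly, so the field at the exact requested hour is used
    with no temporal interpolation. Directions are interpolated through
    their unit-vector components to avoid the 0/360 wrap. A position
    outside the grid extent yields NaNs with a warning.
    """
    lats = grid.ds["lat"].values
    lons = grid.ds["lon"].values
    if not (
        min(lats) <= lat <= max(lats)
        and min(lons) <= lon <= max(lons)
        and np.datetime64(hour) in grid.ds["time"].values
    ):
        warnings.warn(
            f"position ({lat:.3f}, {lon:.3f}) at {hour} outside grid extent",
            stacklevel=2,
        )
        return {
            "windspeed": np.nan,
            "wind_from": np.nan,
            "swell_height": np.nan,
            "swell_dir": np.nan,
        }
    sel = grid.ds.sel(time=np.datetime64(hour))
    mwd_rad = np.radians(sel["mwd"])
    fields = xr.Dataset(
        {
            "u10": sel["u10"],
            "v10": sel["v10"],
            "swh": sel["swh"],
            "mwd_sin": np.sin(mwd_rad),
            "mwd_cos": np.cos(mwd_rad),
        }
    ).interp(lat=lat, lon=lon, method="linear")
    speed, wind_from = wind_speed_dir(float(fields["u10"]), float(fields["v10"]))
    swell_dir = float(
        np.mod(np.degrees(np.arctan2(float(fields["mwd_sin"]), float(fields["mwd_cos"]))), 360.0)
    )
    return {
        "windspeed": float(speed),
        "wind_from": float(wind_from),
        "swell_height": float(fields["swh"]),
        "swell_dir": swell_dir,
    }


@dataclass
class DropLog:
    """Record of bird-hours excluded from the modeling table, with reasons."""

    records: list[tuple[str, pd.Timestamp, str]] = field(default_factory=list)

    def add(self, bird_id: str, hour: pd.Timestamp, reason: str) -> None:
        self.records.append((bird_id, hour, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["bird_id", "hour", "reason"])


def hourly_aggregate(
    states: StateSequence,
    flaps: FlapEvents,
    track: pd.DataFrame,
    grid: EnvGrid,
    bird_id: str = "",
    stage: str = "",
    complete_trip: bool = True,
    drop_log: DropLog | None = None,
) -> pd.DataFrame:
    """Build the hourly flight table for one bird.

    One row per UTC clock hour fully covered by the track. Hours
    containing at least one rest-labeled 10-minute interval are dropped
    (the analysis is restricted to continuous flight), as are hours with
    a missing position or an out-of-grid environment extraction. The
    travel bearing of an hour is the initial great-circle bearing from
    the position at the top of the hour to the position one hour later.
    """
    if states.times is None:
        raise ValueError("state sequence carries no timestamps")
    bird_id = bird_id or states.bird_id or ""
    t = pd.to_datetime(track["timestamp"])
    track_t = t.to_numpy().astype("datetime64[s]").astype(float)
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    log = drop_log if drop_log is not None else DropLog()

    start = states.times.min().ceil("h")
    end = (states.times.max() + pd.Timedelta(minutes=states.interval_min)).floor("h")
    hours = pd.date_range(start, end - pd.Timedelta(hours=1), freq="h")
    if len(hours) == 0:
        warnings.warn("no overlapping clock hours between streams", stacklevel=2)
        return pd.DataFrame()
    counts = flaps_per_hour(flaps, hours)

    rows = []
    state_t = states.times.to_numpy()
    for h in hours:
        h_end = h + pd.Timedelta(hours=1)
        in_hour = (state_t >= h.to_numpy()) & (state_t < h_end.to_numpy())
        if not in_hour.any():
            log.add(bird_id, h, "no-behavior-data")
            continue
        if np.any(states.labels[in_hour] == 0):
            log.add(bird_id, h, "rest-in-hour")
            continue
        th = h.timestamp()
        th1 = h_end.timestamp()
        if th < track_t[0] or th1 > track_t[-1]:
            log.add(bird_id, h, "track-does-not-cover-hour")
            continue
        lat0 = np.interp(th, track_t, lat)
        lon0 = np.interp(th, track_t, lon)
        lat1 = np.interp(th1, track_t, lat)
        lon1 = np.interp(th1, track_t, lon)
        if not np.all(np.isfinite([lat0, lon0, lat1, lon1])):
            log.add(bird_id, h, "missing-position")
            continue
        env = extract_env(grid, lat0, lon0, h)
        if not np.isfinite(env["windspeed"]):
            log.add(bird_id, h, "out-of-grid")
            continue
        bearing = float(initial_bearing(lat0, lon0, lat1, lon1))
        swell_from = env["swell_dir"]
        if grid.swell_convention == "toward":
            swell_from = (swell_from + 180.0) % 360.0
        rows.append(
            {
                "bird_id": bird_id,
                "hour": h,
                "lat": lat0,
                "lon": lon0,
                "bearing": bearing,
                "flaps": int(counts.loc[h]),
                "windspeed": env["windspeed"],
                "wind_from": env["wind_from"],
                "swell_height": env["swell_height"],
                "swell_dir": swell_from,
                "BWA": float(relative_angle(bearing, env["wind_from"])),
                "BSA": float(relative_angle(bearing, swell_from)),
                "stage": stage,
                "complete_trip": bool(complete_trip),
            }
        )
    if not rows:
        warnings.warn(f"no flight hours retained for bird {bird_id!r}", stacklevel=2)
        return pd.DataFrame()
    return pd.DataFrame(rows)
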