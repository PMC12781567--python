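"""Readers and writers for the pipeline's standard formats.

CSV for the per-bird streams (accelerometer, GPS, immersion, states,
flap counts, hourly tables) and NetCDF (via xarray) for gridded
environment fields. Synthetic and field data use the same formats, so
generated cohorts are interchangeable with real deployments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .accel import AccelTrace
from .hmm import STATE_NAMES, StateSequence
from .trackenv import EnvGrid

__all__ = [
    "read_accel_csv",
    "write_accel_csv",
    "read_gps_csv",
    "write_gps_csv",
    "read_immersion_csv",
    "write_immersion_csv",
    "write_flap_counts_csv",
    "write_states_csv",
    "read_states_csv",
    "write_hourly_table",
    "read_hourly_table",
    "read_env_netcdf",
    "write_env_netcdf",
]


def _parse_times(col: pd.Series) -> np.ndarray:
    """Timestamps as POSIX seconds, accepting ISO-8601 strings or epoch numbers."""
    if np.issubdtype(col.dtype, np.number):
        return col.to_numpy(dtype=float)
    return pd.to_datetime(col).astype("int64").to_numpy() / 1e9


def read_accel_csv(path: str | Path, rate: float | None = None) -> AccelTrace:
    """Read a tri-axial accelerometer CSV (timestamp, ax, ay, az in g)."""
    df = pd.read_csv(path)
    times = _parse_times(df["timestamp"])
    if rate is None:
        dt = np.median(np.diff(times))
        rate = float(round(1.0 / dt))
    return AccelTrace(times, df["ax"].to_numpy(), df["ay"].to_numpy(), df["az"].to_numpy(), rate=rate)


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp": trace.times, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    ).to_csv(path, index=False, float_format="%.6f")


def read_gps_csv(path: str | Path) -> pd.DataFrame:
    """GPS fixes: bird_id, timestamp, lat, lon."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_gps_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_immersion_csv(path: str | Path) -> pd.DataFrame:
    """Immersion records: bird_id, start, end, state in {wet, dry}."""
    df = pd.read_csv(path)
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    bad = ~df["state"].str.lower().isin(["wet", "dry"])
    if bad.any():
        raise ValueError(f"invalid immersion states: {df.loc[bad, 'state'].unique()}")
    return df


def write_immersion_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_flap_counts_csv(counts: pd.Series, bird_id: str, path: str | Path) -> None:
    """Hourly flap counts as (bird_id, hour, flaps)."""
    pd.DataFrame(
        {"bird_id": bird_id, "hour": counts.index, "flaps": counts.to_numpy()}
    ).to_csv(path, index=False)


def write_states_csv(states: StateSequence, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bird_id": states.bird_id,
            "timestamp": states.times,
            "state": np.array(STATE_NAMES)[states.labels],
        }
    ).to_csv(path, index=False)


def read_states_csv(path: str | Path) -> StateSequence:
    df = pd.read_csv(path)
    labels = np.array([STATE_NAMES.index(s) for s in df["state"]])
    return StateSequence(
        labels,
        times=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
        bird_id=str(df["bird_id"].iloc[0]) if len(df) else "",
    )


def write_hourly_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# Default column mapping for externally deposited hourly-summary tables
DRYAD_COLUMNS = {
    "bird_id": "bird_id",
    "hour": "hour",
    "flaps": "flaps",
    "windspeed": "windspeed",
    "swell_height": "swell_height",
    "BWA": "BWA",
    "BSA": "BSA",
}


def read_hourly_table(
    path: str | Path, columns: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read an hourly flight table, optionally renaming deposited columns.

    ``columns`` maps canonical names (keys of ``DRYAD_COLUMNS``) to the
    file's column names, so externally deposited hourly summaries can be
    ingested straight into the modeling stage.
    """
    df = pd.read_csv(path)
    mapping = dict(DRYAD_COLUMNS)
    if columns:
        mapping.update(columns)
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    df = df.rename(columns=rename)
    required = {"bird_id", "flaps", "windspeed", "swell_height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hourly table is missing columns: {sorted(missing)}")
    if "hour" in df.columns:
        df["hour"] = pd.to_datetime(df["hour"])
    if "stage" not in df.columns:
        df["stage"] = ""
    if "complete_trip" not in df.columns:
        df["complete_trip"] = True
    return df


ENV_VAR_NAMES = {"u10": "u10", "v10": "v10", "swh": "swh", "mwd": "mwd"}


def read_env_netcdf(
    path: str | Path,
    var_names: dict[str, str] | None = None,
    swell_convention: str = "from",
) -> EnvGrid:
    """Read hourly gridded fields; ``var_names`` maps canonical to file names."""
    ds = xr.open_dataset(path, engine="scipy")
    names = dict(ENV_VAR_NAMES)
    if var_names:
        names.update(var_names)
    ds = ds.rename({v: k for k, v in names.items() if v in ds and v != k})
    return EnvGrid(ds.load(), swell_convention=swell_convention)


def write_env_netcdf(grid: EnvGrid, path: str | Path) -> None:
    ds = grid.ds.copy()
    # NetCDF3 (scipy backend) cannot store ns-resolution times
    ds["time"] = ds["time"].astype("datetime64[s]")
    ds.to_netcdf(path, engine="scipy")
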