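"""Trajectory feature extraction.

A :class:`Track` is one trip's timestamped positions (with an optional
ground-truth behavioural mode per record).  Each *step* spans two
consecutive records; six observed variables are computed per step:

=============  =============================================================
``v``          speed over the step, km/h (great-circle distance / duration)
``phi``        heading: forward azimuth at the step's start point, radians
               in (-pi, pi], clockwise from north
``dv_prev``    change of speed between the previous and the current step
``dphi_prev``  turning angle between the previous and the current step,
               wrapped to (-pi, pi]
``dv_next``    change of speed between the current and the next step
``dphi_next``  turning angle between the current and the next step
=============  =============================================================

plus ``dt``, the step duration in hours.  Units are km/h, radians and
hours throughout.  Sampling may be irregular; records are used as they are
(no interpolation), with dt entering the speed and duration accounting.
Lag/lead change variables are undefined at trip boundaries and carry NaN
there; model code treats NaN as a missing value (emission factor one,
excluded from fitting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .utils import haversine_km, initial_bearing_rad, wrap_to_pi

logger = logging.getLogger(__name__)

VARIABLES = ("v", "phi", "dv_prev", "dphi_prev", "dv_next", "dphi_next")
#: variables that live on the circle (-pi, pi]
CIRCULAR_VARIABLES = ("phi", "dphi_prev", "dphi_next")

TRACK_COLUMNS = ("trip_id", "timestamp", "lon", "lat", "mode")


@dataclass
class Track:
    """One trip's ordered position records."""

    trip_id: str
    records: pd.DataFrame  # columns: timestamp (datetime64), lon, lat, mode (str or NA)

    def __post_init__(self):
        df = self.records
        missing = {"timestamp", "lon", "lat"} - set(df.columns)
        if missing:
            raise ValueError(f"track {self.trip_id!r} missing columns {sorted(missing)}")
        if "mode" not in df.columns:
            df = df.assign(mode=pd.NA)
        df = df.reset_index(drop=True)
        ts = pd.to_datetime(df["timestamp"])
        if ts.isna().any():
            raise ValueError(f"track {self.trip_id!r} has unparseable timestamps")
        dt = ts.diff().dropna()
        if (dt <= pd.Timedelta(0)).any():
            raise ValueError(f"track {self.trip_id!r}: timestamps must be strictly increasing")
        if (df["lon"].abs() > 180).any() or (df["lat"].abs() > 90).any():
            raise ValueError(f"track {self.trip_id!r}: coordinates out of range")
        df["timestamp"] = ts
        self.records = df

    def __len__(self) -> int:
        return len(self.records)


def compute_step_features(track: Track) -> pd.DataFrame:
    """Per-step observed variables for one track.

    Step ``t`` spans records ``t -> t+1``; a track of ``n`` records yields
    ``n - 1`` steps.  A step's mode label is the label of its start record.
    """
    df = track.records
    if len(df) < 3:
        raise ValueError(f"track {track.trip_id!r}: need >= 3 records, got {len(df)}")

    ts = df["timestamp"].to_numpy()
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)

    dt = np.diff(ts).astype("timedelta64[ns]").astype(float) / 3.6e12  # hours
    if np.any(dt <= 0):
        raise ValueError(f"track {track.trip_id!r}: duplicate timestamps")

    dist = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    v = dist / dt
    phi = initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])

    dv_prev = np.concatenate([[np.nan], np.diff(v)])
    dv_next = np.concatenate([np.diff(v), [np.nan]])
    dphi = wrap_to_pi(np.diff(phi))
    dphi_prev = np.concatenate([[np.nan], dphi])
    dphi_next = np.concatenate([dphi, [np.nan]])

    out = pd.DataFrame({
        "trip_id": track.trip_id,
        "t_start": df["timestamp"].iloc[:-1].to_numpy(),
        "v": v,
        "phi": phi,
        "dv_prev": dv_prev,
        "dphi_prev": dphi_prev,
        "dv_next": dv_next,
        "dphi_next": dphi_next,
        "dt": dt,
        "mode": df["mode"].iloc[:-1].to_numpy(),
    })
    return out


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def read_tracks(path) -> list[Track]:
    """Read tracks from a CSV with columns trip_id,timestamp,lon,lat,mode.

    Rows are grouped by trip_id (order of first appearance).  Malformed
    rows raise a ValueError naming the offending line numbers; an empty
    file yields an empty list with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"trip_id": str, "mode": str})
    if df.empty:
        logger.warning("no records in %s", path)
        return []
    missing = {"trip_id", "timestamp", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = ts.isna() | lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # 1-based, plus header
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    df = df.assign(timestamp=ts, lon=lon, lat=lat)
    if "mode" not in df.columns:
        df["mode"] = pd.NA

    tracks = []
    for trip_id, grp in df.groupby("trip_id", sort=False):
        tracks.append(Track(trip_id=str(trip_id),
                            records=grp[["timestamp", "lon", "lat", "mode"]]))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    frames = []
    for tr in tracks:
        df = tr.records.copy()
        df.insert(0, "trip_id", tr.trip_id)
        frames.append(df[list(TRACK_COLUMNS)])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    out = out.copy()
    if len(out):
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"trip_id": str, "mode": str})
    if "t_start" in df.columns:
        df["t_start"] = pd.to_datetime(df["t_start"])
    return df
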