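"""CSV and config I/O for the track and observation formats.

Track CSV dialect: one row per fix, header
``track_id,time,lon,lat,behaviour[,bearing,distance]`` with time as numeric
seconds or ISO-8601 timestamps; colony coordinates and grouping metadata
come from a YAML/JSON config or as explicit arguments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tracks import GeoTrack, StepAngleSeries

__all__ = [
    "read_tracks_csv", "write_tracks_csv", "write_steps_csv",
    "read_steps_csv", "load_config",
]


def _times_to_seconds(values: pd.Series) -> np.ndarray:
    try:
        return values.astype(float).to_numpy()
    except (ValueError, TypeError):
        stamps = pd.to_datetime(values, utc=True, format="ISO8601")
        return (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy()


def read_tracks_csv(
    path,
    colony_lon: float,
    colony_lat: float,
    colony: str = "unknown",
    species: str = "unknown",
    period: str = "chick_rearing",
) -> list[GeoTrack]:
    """Read a multi-track fix CSV into a list of :class:`GeoTrack`."""
    df = pd.read_csv(path)
    required = {"track_id", "time", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.reset_index(drop=True)
        time = _times_to_seconds(grp["time"])
        time = time - time[0]
        tracks.append(GeoTrack(
            track_id=str(tid),
            colony_lon=colony_lon, colony_lat=colony_lat,
            time=time,
            lon=grp["lon"].to_numpy(float),
            lat=grp["lat"].to_numpy(float),
            behaviour=(grp["behaviour"].to_numpy(object)
                       if "behaviour" in grp and grp["behaviour"].notna().all() else None),
            bearing=(grp["bearing"].to_numpy(float)
                     if "bearing" in grp and grp["bearing"].notna().all() else None),
            distance=(grp["distance"].to_numpy(float)
                      if "distance" in grp and grp["distance"].notna().all() else None),
            colony=colony, species=species, period=period,
        ))
    return tracks


def write_tracks_csv(tracks, path) -> None:
    """Write tracks in the fix-per-row dialect (bearing/distance if present)."""
    frames = []
    for tr in tracks:
        d = {"track_id": tr.track_id, "time": tr.time,
             "lon": tr.lon, "lat": tr.lat}
        if tr.behaviour is not None:
            d["behaviour"] = tr.behaviour
        if tr.bearing is not None:
            d["bearing"] = tr.bearing
        if tr.distance is not None:
            d["distance"] = tr.distance
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def write_steps_csv(series_list, path) -> None:
    """Write derived observation series: one row per step."""
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "track_id": s.track_id,
            "t": np.arange(len(s)),
            "step_km": s.step,
            "angle_rad": s.angle,
            "dist_colony_km": s.dist_colony,
            "behaviour": (s.behaviour if s.behaviour is not None
                          else np.full(len(s), np.nan)),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_steps_csv(path, cadence_s: float = 1.0) -> list[StepAngleSeries]:
    """Round-trip reader for :func:`write_steps_csv` output."""
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("t")
        beh = None
        if "behaviour" in grp and grp["behaviour"].notna().all():
            beh = grp["behaviour"].to_numpy(float).astype(int)
        out.append(StepAngleSeries(
            track_id=str(tid),
            step=grp["step_km"].to_numpy(float),
            angle=grp["angle_rad"].to_numpy(float),
            dist_colony=grp["dist_colony_km"].to_numpy(float),
            behaviour=beh, cadence_s=cadence_s,
        ))
    return out


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        return yaml.safe_load(fh)
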