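"""File I/O: GPS/radar CSV schemas, GPX, observation tables, reports.

CSV schemas
-----------
GPS:   ``test_id, timestamp, x, y, alt_agl_m`` (optional ``test_type``);
       timestamp is ISO-8601 or epoch seconds; x/y projected planar metres.
Radar: ``track_id, timestamp, x, y`` (optional ``test_id``), or
       ``track_id, timestamp, range_m, bearing_deg`` with a radar origin.

A one-shot converter is provided for spreadsheet-born data: export the
workbook sheet to these columns once, then the pipeline only ever reads CSV.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .geometry import RadarOrigin
from .tracks import GpsTrack, RadarTrack

__all__ = ["read_gps", "read_radar", "write_gps", "write_radar", "read_gpx",
           "convert_workbook", "write_observations", "read_observations",
           "write_report"]


def _parse_times(col: pd.Series) -> np.ndarray:
    """Epoch seconds from ISO-8601 strings or numeric epoch values."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, utc=True, format="ISO8601")
    return parsed.astype("int64").to_numpy() / 1e9


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_gps(path) -> list[GpsTrack]:
    """Read GPS flight tracks grouped by test_id, time-sorted.

    lat/lon input is rejected unless pre-projected: the pipeline works in
    planar metres and does not guess a projection.
    """
    df = pd.read_csv(path)
    if {"lat", "lon"} <= set(df.columns) and not {"x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: lat/lon given without a projection; "
                         "project to planar metres (x, y) first")
    _require(df, ["test_id", "timestamp", "x", "y", "alt_agl_m"], path)
    tracks = []
    for tid, g in df.groupby("test_id", sort=True):
        tracks.append(GpsTrack(
            test_id=str(tid), t=_parse_times(g["timestamp"]),
            x=g["x"].to_numpy(float), y=g["y"].to_numpy(float),
            alt=g["alt_agl_m"].to_numpy(float),
            test_type=str(g["test_type"].iloc[0]) if "test_type" in g else ""))
    return tracks


def read_radar(path, origin: RadarOrigin | None = None) -> list[RadarTrack]:
    """Read radar tracks grouped by track_id, time-sorted.

    Polar input (range_m, bearing_deg) needs the radar origin to convert to
    planar coordinates.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        warnings.warn(f"{path}: empty radar file")
        return []
    _require(df, ["track_id", "timestamp"], path)
    if not {"x", "y"} <= set(df.columns):
        _require(df, ["range_m", "bearing_deg"], path)
        if origin is None:
            raise ValueError(f"{path}: polar radar input requires a radar origin")
        b = np.radians(df["bearing_deg"].to_numpy(float))
        r = df["range_m"].to_numpy(float)
        df["x"] = origin.x + r * np.sin(b)
        df["y"] = origin.y + r * np.cos(b)
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        tracks.append(RadarTrack(
            track_id=str(tid), t=_parse_times(g["timestamp"]),
            x=g["x"].to_numpy(float), y=g["y"].to_numpy(float),
            test_id=str(g["test_id"].iloc[0]) if "test_id" in g else ""))
    return tracks


def write_gps(path, tracks) -> None:
    rows = []
    for tr in tracks:
        rows.append(pd.DataFrame({
            "test_id": tr.test_id, "timestamp": tr.t, "x": tr.x, "y": tr.y,
            "alt_agl_m": tr.alt, "test_type": tr.test_type}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_radar(path, tracks) -> None:
    rows = []
    for tr in tracks:
        rows.append(pd.DataFrame({
            "track_id": tr.track_id, "timestamp": tr.t, "x": tr.x, "y": tr.y,
            "test_id": tr.test_id}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_gpx(path, projector=None) -> list[GpsTrack]:
    """Minimal GPX reader (track points with lat, lon, ele, time).

    ``projector(lat, lon) -> (x, y)`` must be supplied to obtain planar
    metres; GPX carries geographic coordinates only.
    """
    if projector is None:
        raise ValueError("GPX input requires a projector(lat, lon) -> (x, y)")
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    tracks = []
    for i, trk in enumerate(root.findall("gpx:trk", ns)):
        name_el = trk.find("gpx:name", ns)
        tid = name_el.text if name_el is not None else str(i + 1)
        ts, xs, ys, alts = [], [], [], []
        for pt in trk.iter("{http://www.topografix.com/GPX/1/1}trkpt"):
            lat = float(pt.attrib["lat"])
            lon = float(pt.attrib["lon"])
            ele = pt.find("gpx:ele", ns)
            tm = pt.find("gpx:time", ns)
            x, y = projector(lat, lon)
            xs.append(x)
            ys.append(y)
            alts.append(float(ele.text) if ele is not None else np.nan)
            ts.append(datetime.fromisoformat(tm.text.replace("Z", "+00:00"))
                      .replace(tzinfo=timezone.utc).timestamp())
        tracks.append(GpsTrack(test_id=tid, t=np.array(ts), x=np.array(xs),
                               y=np.array(ys), alt=np.array(alts)))
    return tracks


def convert_workbook(xlsx_path, sheet, column_map: dict, out_csv) -> pd.DataFrame:
    """One-shot spreadsheet-to-CSV converter.

    ``column_map`` maps source column names to the pipeline schema (e.g.
    ``{"TrackID": "test_id", "Time": "timestamp", ...}``); the mapping must
    be given explicitly on first use since workbook layouts vary.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise ValueError(f"workbook sheet {sheet!r} lacks columns {missing}")
    out = df[list(column_map)].rename(columns=column_map)
    out.to_csv(out_csv, index=False)
    return out


def write_observations(path, obs: pd.DataFrame) -> None:
    obs.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "detected" in df:
        df["detected"] = df["detected"].astype(bool)
    if "in_clutter" in df:
        df["in_clutter"] = df["in_clutter"].astype(bool)
    return df


def write_report(path, report: dict) -> None:
    """JSON report writer; numpy scalars serialized at full precision."""
    def default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
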