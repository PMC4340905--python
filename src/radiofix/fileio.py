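"""CSV and GeoJSON dialects used between pipeline stages.

All tabular data travels as plain CSV with fixed headers; positions and
home-range polygons are additionally exported as GeoJSON.  Readers
validate the schema and report offending rows by line number; writers and
readers round-trip losslessly on the in-memory model.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

from .scene import PulseTruth
from .types import (
    BearingFix,
    CalibrationVector,
    DetectionResult,
    PositionFix,
    RangeModel,
    RSSIRecording,
)

__all__ = [
    "write_recording", "read_recording",
    "write_ground_truth", "read_ground_truth",
    "write_detections", "read_detections",
    "write_bearing_fixes", "read_bearing_fixes",
    "write_calibration", "read_calibration",
    "write_range_models", "read_range_models",
    "write_positions", "read_positions",
    "positions_to_geojson", "mcp_to_geojson",
]

_REC_META_PREFIX = "# meta "


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# -- recordings ---------------------------------------------------------

def write_recording(rec: RSSIRecording, path) -> None:
    """Recording CSV: `time_s,antenna,rssi_dba`, metadata in a # meta line."""
    meta = {"station_id": rec.station_id, "channel_khz": rec.channel_khz,
            "duration_s": rec.duration_s}
    with open(path, "w") as fh:
        fh.write(_REC_META_PREFIX + json.dumps(meta) + "\n")
        fh.write("time_s,antenna,rssi_dba\n")
        for t, a, r in zip(rec.times_s, rec.antennas, rec.rssi_dba):
            fh.write(f"{float(t)!r},{int(a)},{float(r)!r}\n")


def read_recording(path, station_id: Optional[str] = None,
                   channel_khz: Optional[float] = None,
                   duration_s: Optional[float] = None) -> RSSIRecording:
    """Read a recording CSV, validating antenna indices row by row."""
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_REC_META_PREFIX):
            meta = json.loads(first[len(_REC_META_PREFIX):])
            skip = 1
        else:
            skip = 0
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    _require_columns(df, ["time_s", "antenna", "rssi_dba"], path)
    ant = df["antenna"].to_numpy()
    bad = np.flatnonzero((ant < 0) | (ant > 3) | (ant != ant.astype(int)))
    if bad.size:
        # +2 for the header line (and +1 more if a meta line is present)
        line = int(bad[0]) + 2 + skip
        raise SchemaError(f"{path}:{line}: antenna index {ant[bad[0]]} "
                          "outside 0..3")
    times = df["time_s"].to_numpy(float)
    duration = duration_s if duration_s is not None else meta.get(
        "duration_s", float(times[-1] - times[0]) if times.size else 0.0)
    return RSSIRecording(
        station_id=station_id or meta.get("station_id", "unknown"),
        channel_khz=channel_khz if channel_khz is not None
        else meta.get("channel_khz", float("nan")),
        times_s=times, antennas=ant.astype(int),
        rssi_dba=df["rssi_dba"].to_numpy(float), duration_s=float(duration))


# -- ground truth -------------------------------------------------------

def write_ground_truth(truth: Iterable[PulseTruth], path) -> None:
    pd.DataFrame([{"pulse_time_s": t.pulse_time_s,
                   "true_bearing_deg": t.true_bearing_deg,
                   "true_distance_m": t.true_distance_m}
                  for t in truth]).to_csv(path, index=False)


def read_ground_truth(path) -> list[PulseTruth]:
    df = pd.read_csv(path)
    _require_columns(df, ["pulse_time_s", "true_bearing_deg",
                          "true_distance_m"], path)
    return [PulseTruth(r.pulse_time_s, r.true_bearing_deg, r.true_distance_m)
            for r in df.itertuples()]


# -- detections ---------------------------------------------------------

_DET_COLUMNS = ["station_id", "channel_khz", "t_start_s", "phase_s",
                "rssi_on_n", "rssi_on_e", "rssi_on_s", "rssi_on_w",
                "rssi_off", "snr_db", "valid"]


def write_detections(rows: Iterable[tuple[str, float, float, DetectionResult]],
                     path) -> None:
    """Detection CSV; rows are (station_id, channel_khz, t_start_s, result)."""
    out = []
    for station_id, channel_khz, t_start_s, res in rows:
        on = res.rssi_on if res.rssi_on is not None else [np.nan] * 4
        out.append({"station_id": station_id, "channel_khz": channel_khz,
                    "t_start_s": t_start_s, "phase_s": res.phase_s,
                    "rssi_on_n": on[0], "rssi_on_e": on[1],
                    "rssi_on_s": on[2], "rssi_on_w": on[3],
                    "rssi_off": res.rssi_off, "snr_db": res.snr_db,
                    "valid": res.valid})
    pd.DataFrame(out, columns=_DET_COLUMNS).to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _DET_COLUMNS, path)
    return df


# -- bearing fixes ------------------------------------------------------

_FIX_COLUMNS = ["station_id", "time_s", "channel_khz", "bearing_deg",
                "delta_brg_deg", "rssi_max_dba", "snr_db", "valid"]


def write_bearing_fixes(fixes: Iterable[BearingFix], path) -> None:
    pd.DataFrame([{c: getattr(f, c) for c in _FIX_COLUMNS}
                  for f in fixes], columns=_FIX_COLUMNS).to_csv(path, index=False)


def read_bearing_fixes(path) -> list[BearingFix]:
    df = pd.read_csv(path)
    _require_columns(df, _FIX_COLUMNS, path)
    return [BearingFix(station_id=str(r.station_id), time_s=r.time_s,
                       channel_khz=r.channel_khz, bearing_deg=r.bearing_deg,
                       delta_brg_deg=r.delta_brg_deg,
                       rssi_max_dba=r.rssi_max_dba, snr_db=r.snr_db,
                       valid=bool(r.valid))
            for r in df.itertuples()]


# -- calibration vector -------------------------------------------------

def write_calibration(cal: CalibrationVector, path) -> None:
    pd.DataFrame({"azimuth_deg": cal.azimuth_deg,
                  "error_deg": cal.error_deg}).to_csv(path, index=False)


def read_calibration(path) -> CalibrationVector:
    df = pd.read_csv(path)
    _require_columns(df, ["azimuth_deg", "error_deg"], path)
    return CalibrationVector(df["azimuth_deg"].to_numpy(float),
                             df["error_deg"].to_numpy(float))


# -- range models -------------------------------------------------------

GLOBAL_STATION = "*"


def write_range_models(models: Mapping[str, RangeModel], path) -> None:
    """Range model CSV: `station_id,a_coeff,b_coeff`; '*' is the global fallback."""
    pd.DataFrame([{"station_id": sid, "a_coeff": m.a_coeff,
                   "b_coeff": m.b_coeff} for sid, m in models.items()]
                 ).to_csv(path, index=False)


def read_range_models(path) -> dict[str, RangeModel]:
    df = pd.read_csv(path)
    _require_columns(df, ["station_id", "a_coeff", "b_coeff"], path)
    return {str(r.station_id): RangeModel(r.a_coeff, r.b_coeff)
            for r in df.itertuples()}


def model_for_station(models: Mapping[str, RangeModel],
                      station_id: str) -> RangeModel:
    """Per-station range model with a '*' global fallback."""
    if station_id in models:
        return models[station_id]
    if GLOBAL_STATION in models:
        return models[GLOBAL_STATION]
    raise KeyError(f"no range model for station {station_id!r} "
                   "and no global fallback")


# -- positions ----------------------------------------------------------

_POS_COLUMNS = ["time_s", "channel_khz", "east_m", "north_m",
                "n_stations", "method"]


def write_positions(fixes: Iterable[PositionFix], path) -> None:
    pd.DataFrame([{c: getattr(f, c) for c in _POS_COLUMNS}
                  for f in fixes], columns=_POS_COLUMNS).to_csv(path, index=False)


def read_positions(path) -> list[PositionFix]:
    df = pd.read_csv(path)
    _require_columns(df, _POS_COLUMNS, path)
    return [PositionFix(time_s=r.time_s, channel_khz=r.channel_khz,
                        east_m=r.east_m, north_m=r.north_m,
                        n_stations=int(r.n_stations), method=str(r.method))
            for r in df.itertuples()]


def positions_to_geojson(fixes: Iterable[PositionFix]) -> dict:
    """GeoJSON FeatureCollection of Point features in the local planar frame."""
    features = [{
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [f.east_m, f.north_m]},
        "properties": {"time_s": f.time_s, "channel_khz": f.channel_khz,
                       "n_stations": f.n_stations, "method": f.method},
    } for f in fixes]
    return {"type": "FeatureCollection", "features": features}


def mcp_to_geojson(polygon: Polygon, area_m2: float) -> dict:
    return {"type": "Feature", "geometry": mapping(polygon),
            "properties": {"area_m2": area_m2, "estimator": "mcp_100"}}
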