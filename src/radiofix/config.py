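"""Deployment configuration: stations, transmitters, trajectories, scan plan.

A whole deployment is described by one structured text (YAML) file.
Unknown keys provoke a warning, not a failure, so configs written by
newer revisions still load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .schedule import ChannelPlan
from .types import (
    DEFAULT_THRESHOLD_DB,
    AntennaPattern,
    CalibrationVector,
    PulseTemplate,
    RangeModel,
    StationSpec,
    Trajectory,
    TransmitterSpec,
)

__all__ = ["StationConfig", "DeploymentConfig", "load_config", "save_config"]


@dataclass
class StationConfig:
    """A station plus everything calibrated for it."""

    spec: StationSpec
    threshold_db: float = DEFAULT_THRESHOLD_DB
    calibration: CalibrationVector = field(default_factory=CalibrationVector.zero)
    range_model: Optional[RangeModel] = None


@dataclass
class DeploymentConfig:
    """One tracking deployment: stations, transmitters and the scan plan."""

    stations: list[StationConfig]
    transmitters: list[TransmitterSpec]
    trajectories: dict[str, Trajectory]
    plan: Optional[ChannelPlan] = None
    epoch: str = "1970-01-01T00:00:00Z"
    seed: int = 0


def _check_keys(mapping: dict, known: set[str], context: str) -> None:
    unknown = set(mapping) - known
    if unknown:
        warnings.warn(f"{context}: ignoring unknown keys {sorted(unknown)}")


_STATION_KEYS = {"id", "position", "height_m", "antenna_rotations_deg",
                 "dwell_ms", "cycle_ms", "noise_floor_dba", "noise_sd_db",
                 "seed", "pattern", "threshold_db", "calibration",
                 "range_model"}
_PATTERN_KEYS = {"amplitude_db", "offset_db", "distortion"}
_TX_KEYS = {"id", "channel_khz", "pulse_period_s", "pulse_duration_s",
            "power_dba_at_1m", "duty_windows", "trajectory"}
_TOP_KEYS = {"stations", "transmitters", "channel_plan", "epoch", "seed"}
_PLAN_KEYS = {"dwell_s", "channels"}
_CHANNEL_KEYS = {"channel_khz", "period_s", "duration_s",
                 "timing_tolerance_frac"}


def _parse_pattern(d: dict, context: str) -> AntennaPattern:
    _check_keys(d, _PATTERN_KEYS, context)
    distortion = None
    if d.get("distortion") is not None:
        tab = d["distortion"]
        distortion = (np.asarray(tab["azimuth_deg"], float),
                      np.asarray(tab["deviation_db"], float))
    return AntennaPattern(amplitude_db=d.get("amplitude_db", 10.0),
                          offset_db=d.get("offset_db", 0.0),
                          distortion=distortion)


def _parse_station(d: dict) -> StationConfig:
    context = f"station {d.get('id', '?')}"
    _check_keys(d, _STATION_KEYS, context)
    pattern = _parse_pattern(d.get("pattern", {}), context)
    spec = StationSpec(
        id=str(d["id"]),
        position=tuple(d.get("position", (0.0, 0.0))),
        height_m=d.get("height_m", 4.0),
        antenna_rotations_deg=d.get("antenna_rotations_deg",
                                    (0.0, 90.0, 180.0, 270.0)),
        dwell_ms=d.get("dwell_ms", 3.75), cycle_ms=d.get("cycle_ms", 15.0),
        noise_floor_dba=d.get("noise_floor_dba", 20.0),
        noise_sd_db=d.get("noise_sd_db", 2.0),
        seed=d.get("seed", 0), pattern=pattern)
    cal = CalibrationVector.zero()
    if d.get("calibration") is not None:
        cal = CalibrationVector(np.asarray(d["calibration"]["azimuth_deg"], float),
                                np.asarray(d["calibration"]["error_deg"], float))
    model = None
    if d.get("range_model") is not None:
        model = RangeModel(d["range_model"]["a_coeff"],
                           d["range_model"]["b_coeff"])
    return StationConfig(spec=spec,
                         threshold_db=d.get("threshold_db", DEFAULT_THRESHOLD_DB),
                         calibration=cal, range_model=model)


def _parse_transmitter(d: dict) -> tuple[TransmitterSpec, Optional[Trajectory]]:
    context = f"transmitter {d.get('id', '?')}"
    _check_keys(d, _TX_KEYS, context)
    tx = TransmitterSpec(
        id=str(d["id"]), channel_khz=float(d["channel_khz"]),
        pulse_period_s=d.get("pulse_period_s", 1.0),
        pulse_duration_s=d.get("pulse_duration_s", 0.02),
        power_dba_at_1m=d.get("power_dba_at_1m", 160.0),
        duty_windows=d.get("duty_windows"))
    traj = None
    if d.get("trajectory") is not None:
        traj = Trajectory(np.asarray(d["trajectory"], float))
    return tx, traj


def load_config(path) -> DeploymentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys(raw, _TOP_KEYS, str(path))
    stations = [_parse_station(s) for s in raw.get("stations", [])]
    transmitters, trajectories = [], {}
    for t in raw.get("transmitters", []):
        tx, traj = _parse_transmitter(t)
        transmitters.append(tx)
        if traj is not None:
            trajectories[tx.id] = traj
    plan = None
    if raw.get("channel_plan") is not None:
        p = raw["channel_plan"]
        _check_keys(p, _PLAN_KEYS, "channel_plan")
        channels = []
        for c in p.get("channels", []):
            _check_keys(c, _CHANNEL_KEYS, "channel")
            channels.append((float(c["channel_khz"]), PulseTemplate(
                period_s=c["period_s"], duration_s=c["duration_s"],
                timing_tolerance_frac=c.get("timing_tolerance_frac", 0.03))))
        plan = ChannelPlan(channels=channels, dwell_s=p.get("dwell_s", 10.0))
    return DeploymentConfig(stations=stations, transmitters=transmitters,
                            trajectories=trajectories, plan=plan,
                            epoch=raw.get("epoch", "1970-01-01T00:00:00Z"),
                            seed=int(raw.get("seed", 0)))


def save_config(cfg: DeploymentConfig, path) -> None:
    out: dict = {"epoch": cfg.epoch, "seed": cfg.seed, "stations": [],
                 "transmitters": []}
    for sc in cfg.stations:
        s = sc.spec
        d = {"id": s.id, "position": list(s.position), "height_m": s.height_m,
             "antenna_rotations_deg": list(s.antenna_rotations_deg),
             "dwell_ms": s.dwell_ms, "cycle_ms": s.cycle_ms,
             "noise_floor_dba": s.noise_floor_dba,
             "noise_sd_db": s.noise_sd_db, "seed": s.seed,
             "pattern": {"amplitude_db": s.pattern.amplitude_db,
                         "offset_db": s.pattern.offset_db},
             "threshold_db": sc.threshold_db,
             "calibration": {"azimuth_deg": sc.calibration.azimuth_deg.tolist(),
                             "error_deg": sc.calibration.error_deg.tolist()}}
        if s.pattern.distortion is not None:
            d["pattern"]["distortion"] = {
                "azimuth_deg": s.pattern.distortion[0].tolist(),
                "deviation_db": s.pattern.distortion[1].tolist()}
        if sc.range_model is not None:
            d["range_model"] = {"a_coeff": sc.range_model.a_coeff,
                                "b_coeff": sc.range_model.b_coeff}
        out["stations"].append(d)
    for tx in cfg.transmitters:
        d = {"id": tx.id, "channel_khz": tx.channel_khz,
             "pulse_period_s": tx.pulse_period_s,
             "pulse_duration_s": tx.pulse_duration_s,
             "power_dba_at_1m": tx.power_dba_at_1m}
        if tx.duty_windows is not None:
            d["duty_windows"] = [list(w) for w in tx.duty_windows]
        if tx.id in cfg.trajectories:
            d["trajectory"] = cfg.trajectories[tx.id].samples.tolist()
        out["transmitters"].append(d)
    if cfg.plan is not None:
        out["channel_plan"] = {
            "dwell_s": cfg.plan.dwell_s,
            "channels": [{"channel_khz": f, "period_s": tpl.period_s,
                          "duration_s": tpl.duration_s,
                          "timing_tolerance_frac": tpl.timing_tolerance_frac}
                         for f, tpl in cfg.plan.channels]}
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
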