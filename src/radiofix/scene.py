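"""Forward model of a tracking scene.

Simulates what a four-antenna station records while a pulsed transmitter
moves through the scene: free-space propagation, ground (Fresnel-zone)
attenuation, the sinusoidal-in-dB antenna patterns, round-robin antenna
multiplexing and additive Gaussian receiver noise in dB.  Every simulated
recording is returned together with its per-pulse ground truth so each
downstream stage can be tested against a known scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .propagation import free_space_rssi, height_attenuation
from .types import (
    AntennaPattern,
    RSSIRecording,
    StationSpec,
    Trajectory,
    TransmitterSpec,
    wrap_deg,
)

__all__ = ["PulseTruth", "antenna_gain", "azimuth_deg", "simulate_recording",
           "simulate_quadrant_rssi"]


@dataclass
class PulseTruth:
    """Ground truth for one emitted pulse (at the pulse's mid-time)."""

    pulse_time_s: float
    true_bearing_deg: float
    true_distance_m: float


def antenna_gain(pattern: AntennaPattern, relative_bearing_deg):
    """Gain (dB) of a directional antenna at a bearing off boresight."""
    return pattern.gain_db(relative_bearing_deg)


def azimuth_deg(from_east, from_north, to_east, to_north):
    """Azimuth from one point to another, degrees clockwise from north."""
    az = np.rad2deg(np.arctan2(np.asarray(to_east, float) - from_east,
                               np.asarray(to_north, float) - from_north))
    return wrap_deg(az)


def simulate_quadrant_rssi(pattern: AntennaPattern, rssi_max_dba, azimuth,
                           antenna_rotations_deg=(0.0, 90.0, 180.0, 270.0),
                           noise_sd_db: float = 0.0, rng=None):
    """Four per-antenna on-pulse RSSI readings for given boresight RSSI.

    ``rssi_max_dba`` is the RSSI an antenna pointed straight at the
    transmitter would read (C + S); the offset level C follows as
    ``rssi_max − amplitude``.  Accepts scalars or equal-length arrays and
    returns an ``(n, 4)`` array.  Gaussian noise in dB is added per reading
    when ``noise_sd_db > 0`` (``rng`` required then).
    """
    rmax = np.atleast_1d(np.asarray(rssi_max_dba, dtype=float))
    az = np.atleast_1d(np.asarray(azimuth, dtype=float))
    rmax, az = np.broadcast_arrays(rmax, az)
    offset = rmax - pattern.amplitude_db
    rot = np.asarray(antenna_rotations_deg, dtype=float)
    rel = az[:, None] - rot[None, :]
    out = offset[:, None] + (pattern.gain_db(rel) - pattern.offset_db)
    if noise_sd_db > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sd_db > 0")
        out = out + rng.normal(0.0, noise_sd_db, size=out.shape)
    return out


def _sample_grid(station: StationSpec, t_start_s: float, duration_s: float):
    """Round-robin sample times and antenna indices over the dwell."""
    cycle_s = station.cycle_ms / 1e3
    dwell_s = station.dwell_ms / 1e3
    n_cycles = int(np.floor(duration_s / cycle_s))
    if n_cycles < 1:
        raise ValueError("duration_s must cover at least one switch cycle")
    cycle_starts = t_start_s + np.arange(n_cycles) * cycle_s
    # one instantaneous RSSI reading per antenna dwell, at the dwell midpoint
    offsets = (np.arange(4) + 0.5) * dwell_s
    times = (cycle_starts[:, None] + offsets[None, :]).ravel()
    antennas = np.tile(np.arange(4), n_cycles)
    return times, antennas


def simulate_recording(station: StationSpec, tx: TransmitterSpec,
                       trajectory: Trajectory, t_start_s: float,
                       duration_s: float, rng=None):
    """Simulate one station/channel dwell; returns (recording, ground truth).

    Per-sample RSSI during a pulse is free-space level minus Fresnel
    ground loss plus the sampled antenna's directional gain; between
    pulses the receiver reads its noise floor.  Gaussian noise
    (``station.noise_sd_db``) is added to every sample in dB.  The ground
    truth lists, for each pulse whose mid-time falls inside the dwell and
    inside a duty window, the true azimuth and horizontal distance at that
    instant.
    """
    if duration_s < tx.pulse_period_s:
        raise ValueError("duration_s must cover at least one pulse period")
    if not trajectory.covers(t_start_s, t_start_s + duration_s):
        raise ValueError("trajectory does not cover the requested time span")
    if rng is None:
        rng = np.random.default_rng(station.seed)

    times, antennas = _sample_grid(station, t_start_s, duration_s)
    east, north, height = trajectory.position_at(times)
    d_east = east - station.position[0]
    d_north = north - station.position[1]
    dist = np.hypot(d_east, d_north)
    if np.any(dist <= 0):
        raise ValueError("transmitter coincides with the station")
    az = wrap_deg(np.rad2deg(np.arctan2(d_east, d_north)))

    on_pulse = np.mod(times, tx.pulse_period_s) < tx.pulse_duration_s
    on_pulse &= tx.is_active(times)

    rot = np.asarray(station.antenna_rotations_deg)
    level = (free_space_rssi(tx.power_dba_at_1m, dist, tx.channel_khz)
             - height_attenuation(height, station.height_m, dist, tx.channel_khz)
             + station.pattern.gain_db(az - rot[antennas]))
    rssi = np.where(on_pulse, level, station.noise_floor_dba)
    if station.noise_sd_db > 0:
        rssi = rssi + rng.normal(0.0, station.noise_sd_db, size=rssi.shape)

    rec = RSSIRecording(station_id=station.id, channel_khz=tx.channel_khz,
                        times_s=times, antennas=antennas, rssi_dba=rssi,
                        duration_s=duration_s)

    # ground truth at each pulse mid-time inside the dwell
    first_k = int(np.ceil((t_start_s - tx.pulse_duration_s / 2.0) / tx.pulse_period_s))
    truth: list[PulseTruth] = []
    k = first_k
    while True:
        mid = k * tx.pulse_period_s + tx.pulse_duration_s / 2.0
        if mid > t_start_s + duration_s:
            break
        if mid >= t_start_s and bool(tx.is_active(mid)):
            e, n, _ = trajectory.position_at(mid)
            de, dn = e - station.position[0], n - station.position[1]
            truth.append(PulseTruth(
                pulse_time_s=float(mid),
                true_bearing_deg=float(wrap_deg(np.rad2deg(np.arctan2(de, dn)))),
                true_distance_m=float(np.hypot(de, dn)),
            ))
        k += 1
    return rec, truth
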