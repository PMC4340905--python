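"""Core data containers shared across the tracking pipeline.

Conventions used throughout the package:

* positions are planar ``(east_m, north_m)`` coordinates in a local frame;
* azimuths/bearings are degrees clockwise from north, wrapped to ``[0, 360)``;
* signal strengths are on the dBa scale (dB referenced to one attowatt,
  i.e. dBm + 150) — a strong signal is ~100 dBa, a weak one ~30 dBa;
* times are seconds since the deployment epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TransmitterSpec",
    "AntennaPattern",
    "StationSpec",
    "Trajectory",
    "RSSIRecording",
    "PulseTemplate",
    "DetectionResult",
    "QuadrantReading",
    "BearingFix",
    "CalibrationVector",
    "RangeModel",
    "BeaconObservation",
    "RotationMeasurement",
    "ThresholdCurvePoint",
    "PositionFix",
    "ActivityBudget",
    "wrap_deg",
    "signed_angle_diff_deg",
]


def wrap_deg(angle_deg):
    """Wrap an angle (scalar or array) to ``[0, 360)`` degrees."""
    return np.mod(angle_deg, 360.0)


def signed_angle_diff_deg(a_deg, b_deg):
    """Signed difference ``a - b`` wrapped to ``[-180, 180)`` degrees."""
    return np.mod(np.asarray(a_deg, dtype=float) - b_deg + 180.0, 360.0) - 180.0


@dataclass
class TransmitterSpec:
    """A pulsed telemetry transmitter on one frequency channel.

    ``power_dba_at_1m`` is the source strength expressed as the RSSI that
    would be read 1 m from the transmitter at the reference frequency.
    ``duty_windows`` lists (start, end) seconds-of-day when the transmitter
    is active; ``None`` means always on.
    """

    id: str
    channel_khz: float
    pulse_period_s: float = 1.0
    pulse_duration_s: float = 0.02
    power_dba_at_1m: float = 160.0
    duty_windows: Optional[Sequence[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.pulse_period_s <= 0:
            raise ValueError("pulse_period_s must be positive")
        if not (0 < self.pulse_duration_s < self.pulse_period_s):
            raise ValueError("pulse_duration_s must lie in (0, pulse_period_s)")
        if self.duty_windows is not None:
            wins = sorted(tuple(w) for w in self.duty_windows)
            for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
                if b0 < a1:
                    raise ValueError("duty windows must not overlap")
            self.duty_windows = wins

    def is_active(self, time_s) -> np.ndarray:
        """Vectorised duty-window test on seconds-since-epoch timestamps."""
        t = np.asarray(time_s, dtype=float)
        if self.duty_windows is None:
            return np.ones_like(t, dtype=bool)
        tod = np.mod(t, 86400.0)
        active = np.zeros_like(t, dtype=bool)
        for start, end in self.duty_windows:
            active |= (tod >= start) & (tod < end)
        return active


@dataclass
class AntennaPattern:
    """Directional antenna gain, sinusoidal in the dB domain.

    Ideal gain at relative bearing Δ (degrees off boresight) is
    ``offset_db + amplitude_db * cos(Δ)``; an optional tabulated distortion
    (periodic over [0, 360)) is added on top to model pattern imperfections.
    """

    amplitude_db: float = 10.0
    offset_db: float = 0.0
    distortion: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.amplitude_db <= 0:
            raise ValueError("amplitude_db must be positive")
        if self.distortion is not None:
            az, dev = self.distortion
            az = np.asarray(az, dtype=float)
            dev = np.asarray(dev, dtype=float)
            if az.shape != dev.shape or az.ndim != 1 or az.size == 0:
                raise ValueError("distortion must be two equal-length 1-D tables")
            order = np.argsort(az)
            self.distortion = (wrap_deg(az[order]), dev[order])

    def gain_db(self, relative_bearing_deg):
        delta = wrap_deg(np.asarray(relative_bearing_deg, dtype=float))
        g = self.offset_db + self.amplitude_db * np.cos(np.deg2rad(delta))
        if self.distortion is not None:
            az, dev = self.distortion
            # periodic linear interpolation over the tabulated deviations
            az_ext = np.concatenate([az, [az[0] + 360.0]])
            dev_ext = np.concatenate([dev, [dev[0]]])
            g = g + np.interp(delta, az_ext, dev_ext)
        return g


DEFAULT_ANTENNA_ROTATIONS = (0.0, 90.0, 180.0, 270.0)


@dataclass
class StationSpec:
    """A four-antenna tracking station.

    The four directional antennas point at ``antenna_rotations_deg`` (the
    nominal N/E/S/W boresights, optionally with a mounting error) and are
    sampled round-robin: each antenna for ``dwell_ms``, a full cycle every
    ``cycle_ms``.
    """

    id: str
    position: tuple[float, float] = (0.0, 0.0)
    height_m: float = 4.0
    antenna_rotations_deg: Sequence[float] = DEFAULT_ANTENNA_ROTATIONS
    dwell_ms: float = 3.75
    cycle_ms: float = 15.0
    noise_floor_dba: float = 20.0
    noise_sd_db: float = 2.0
    seed: int = 0
    pattern: AntennaPattern = field(default_factory=AntennaPattern)

    def __post_init__(self) -> None:
        rot = tuple(float(r) for r in self.antenna_rotations_deg)
        if len(rot) != 4:
            raise ValueError("a station has exactly 4 antennas")
        self.antenna_rotations_deg = rot
        if self.dwell_ms * 4 > self.cycle_ms:
            raise ValueError("4 antenna dwells must fit within one cycle")
        if self.noise_sd_db < 0:
            raise ValueError("noise_sd_db must be non-negative")


@dataclass
class Trajectory:
    """Piecewise-linear transmitter path: (time_s, east_m, north_m, height_m)."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 4 or s.shape[0] == 0:
            raise ValueError("samples must be an (n, 4) array")
        if s.shape[0] > 1 and not np.all(np.diff(s[:, 0]) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        self.samples = s

    @classmethod
    def static(cls, east_m: float, north_m: float, height_m: float = 1.0,
               t0: float = 0.0, t1: float = 1e9) -> "Trajectory":
        return cls(np.array([[t0, east_m, north_m, height_m],
                             [t1, east_m, north_m, height_m]]))

    @property
    def t_min(self) -> float:
        return float(self.samples[0, 0])

    @property
    def t_max(self) -> float:
        return float(self.samples[-1, 0])

    def covers(self, t_start: float, t_end: float) -> bool:
        return self.t_min <= t_start and t_end <= self.t_max

    def position_at(self, time_s):
        """Linear interpolation of (east, north, height) at the given times."""
        t = np.asarray(time_s, dtype=float)
        if np.any(t < self.t_min) or np.any(t > self.t_max):
            raise ValueError("requested time outside trajectory span")
        ts = self.samples[:, 0]
        east = np.interp(t, ts, self.samples[:, 1])
        north = np.interp(t, ts, self.samples[:, 2])
        height = np.interp(t, ts, self.samples[:, 3])
        return east, north, height


@dataclass
class RSSIRecording:
    """Time-multiplexed per-antenna RSSI sample stream for one dwell."""

    station_id: str
    channel_khz: float
    times_s: np.ndarray
    antennas: np.ndarray
    rssi_dba: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.antennas = np.asarray(self.antennas, dtype=int)
        self.rssi_dba = np.asarray(self.rssi_dba, dtype=float)
        n = self.times_s.size
        if not (self.antennas.size == n and self.rssi_dba.size == n):
            raise ValueError("times, antennas and rssi must have equal length")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any((self.antennas < 0) | (self.antennas > 3)):
            raise ValueError("antenna indices must be in 0..3")
        if not np.all(np.isfinite(self.rssi_dba)):
            raise ValueError("rssi values must be finite")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass
class PulseTemplate:
    """Expected pulse timing of a transmitter, with the receiver's tolerance."""

    period_s: float
    duration_s: float
    timing_tolerance_frac: float = 0.03

    def __post_init__(self) -> None:
        if not (0 < self.duration_s < self.period_s):
            raise ValueError("duration_s must lie in (0, period_s)")
        if not (0 <= self.timing_tolerance_frac < 0.5):
            raise ValueError("timing_tolerance_frac must lie in [0, 0.5)")


#: Default acceptance threshold (dB); per-deployment calibration refines it.
DEFAULT_THRESHOLD_DB = 3.3


@dataclass
class DetectionResult:
    """Outcome of matched-filter pulse detection on one recording."""

    phase_s: float
    period_s: float
    rssi_off: float
    snr_db: float
    valid: bool
    threshold_db: float
    rssi_on: Optional[np.ndarray] = None       # four per-antenna on-pulse means
    rssi_on_mean: float = float("nan")         # on-pulse mean of the averaged series
    score: float = float("nan")                # matched-filter correlation peak


@dataclass
class QuadrantReading:
    """Per-antenna RSSI relabelled relative to the strongest (front) antenna."""

    rssi_f: float
    rssi_l: float
    rssi_r: float
    rssi_re: float
    k_deg: float

    def __post_init__(self) -> None:
        others = (self.rssi_l, self.rssi_r, self.rssi_re)
        if any(np.isfinite(o) and o > self.rssi_f for o in others):
            raise ValueError("front antenna must carry the strongest RSSI")


@dataclass
class BearingFix:
    """One station's estimate of a transmitter's direction (and range)."""

    station_id: str
    time_s: float
    channel_khz: float
    bearing_deg: float
    delta_brg_deg: float
    rssi_max_dba: float
    snr_db: float = float("nan")
    distance_m: Optional[float] = None
    valid: bool = True


@dataclass
class CalibrationVector:
    """Tabulated azimuth-dependent bearing error, periodic over [0, 360)."""

    azimuth_deg: np.ndarray
    error_deg: np.ndarray

    def __post_init__(self) -> None:
        az = wrap_deg(np.asarray(self.azimuth_deg, dtype=float))
        err = np.asarray(self.error_deg, dtype=float)
        if az.shape != err.shape or az.ndim != 1 or az.size == 0:
            raise ValueError("calibration vector needs matching 1-D tables")
        if not np.all(np.isfinite(err)):
            raise ValueError("calibration corrections must be finite")
        order = np.argsort(az)
        self.azimuth_deg = az[order]
        self.error_deg = err[order]

    @classmethod
    def zero(cls) -> "CalibrationVector":
        return cls(np.array([0.0]), np.array([0.0]))

    def error_at(self, bearing_deg):
        b = wrap_deg(np.asarray(bearing_deg, dtype=float))
        az = np.concatenate([self.azimuth_deg, [self.azimuth_deg[0] + 360.0]])
        err = np.concatenate([self.error_deg, [self.error_deg[0]]])
        return np.interp(b, az, err)


@dataclass
class RangeModel:
    """Exponential RSSI-to-distance model DIST = A * B**RSSImax."""

    a_coeff: float
    b_coeff: float

    def __post_init__(self) -> None:
        if self.a_coeff <= 0:
            raise ValueError("a_coeff must be positive")
        if not (0 < self.b_coeff < 1):
            raise ValueError("b_coeff must lie in (0, 1): distance shrinks as RSSI grows")


@dataclass
class BeaconObservation:
    """A range-calibration point: known distance, observed boresight RSSI."""

    true_distance_m: float
    rssi_max_dba: float

    def __post_init__(self) -> None:
        if self.true_distance_m <= 0:
            raise ValueError("true_distance_m must be positive")


@dataclass
class RotationMeasurement:
    """A calibration-turntable point: true vs computed azimuth."""

    true_azimuth_deg: float
    computed_azimuth_deg: float
    rssi_max_dba: float = float("nan")

    def __post_init__(self) -> None:
        self.true_azimuth_deg = float(wrap_deg(self.true_azimuth_deg))
        self.computed_azimuth_deg = float(wrap_deg(self.computed_azimuth_deg))


@dataclass
class ThresholdCurvePoint:
    """One (S/N, |azimuth error|) observation for threshold estimation."""

    snr_db: float
    abs_azimuth_error_deg: float

    def __post_init__(self) -> None:
        if self.abs_azimuth_error_deg < 0:
            raise ValueError("abs_azimuth_error_deg must be non-negative")


@dataclass
class PositionFix:
    """A localised transmitter position with its provenance."""

    time_s: float
    channel_khz: float
    east_m: float
    north_m: float
    n_stations: int
    method: str  # "triangulated" or "single_station"
    contributing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in ("triangulated", "single_station"):
            raise ValueError("method must be 'triangulated' or 'single_station'")
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if self.method == "triangulated" and self.n_stations < 2:
            raise ValueError("triangulation needs at least 2 stations")


@dataclass
class ActivityBudget:
    """Feeding vs search time split from single-station fix sequences."""

    feeding_time_s: float
    search_time_s: float
    labels: tuple[str, ...] = ()

    @property
    def total_s(self) -> float:
        return self.feeding_time_s + self.search_time_s
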