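import numpy as np
import pytest

from radiofix import AntennaPattern, StationSpec, Trajectory, TransmitterSpec


@pytest.fixture
def ideal_pattern():
    """Sinusoidal-in-dB pattern, 10 dB span about a 0 dB offset."""
    return AntennaPattern(amplitude_db=10.0, offset_db=0.0)


@pytest.fixture
def ideal_station(ideal_pattern):
    """Noiseless four-antenna station at the origin."""
    return StationSpec(id="S1", position=(0.0, 0.0), noise_sd_db=0.0,
                       noise_floor_dba=20.0, pattern=ideal_pattern)


def make_station(station_id="S1", position=(0.0, 0.0), noise_sd_db=0.0,
                 seed=0, **kw):
    return StationSpec(id=station_id, position=position,
                       noise_sd_db=noise_sd_db, seed=seed,
                       pattern=AntennaPattern(amplitude_db=10.0, offset_db=0.0),
                       **kw)


def make_transmitter(channel_khz=150_000.0, period=1.0, duration=0.1,
                     power=160.0, duty=None):
    return TransmitterSpec(id="T1", channel_khz=channel_khz,
                           pulse_period_s=period, pulse_duration_s=duration,
                           power_dba_at_1m=power, duty_windows=duty)


def static_trajectory(bearing_deg, distance_m, height_m=50.0):
    b = np.deg2rad(bearing_deg)
    return Trajectory.static(distance_m * np.sin(b), distance_m * np.cos(b),
                             height_m=height_m)


@pytest.fixture
def table1_counts():
    """Printed field-deployment RSSI histogram (dBa band -> fix count)."""
    return {(None, 45): 13_742, (45, 51): 8_710, (51, 61): 3_133,
            (61, 71): 6_357, (71, 81): 5_691, (81, 91): 4_370,
            (91, 101): 11_584, (101, None): 2_104}


def expand_table1(counts):
    """Representative integer dBa value per band, repeated by count."""
    reps = {(None, 45): 40, (45, 51): 47, (51, 61): 55, (61, 71): 65,
            (71, 81): 75, (81, 91): 85, (91, 101): 95, (101, None): 105}
    vals = np.concatenate([np.full(n, reps[band], dtype=float)
                           for band, n in counts.items()])
    return vals
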