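"""RSSI-based ranging and signal-strength record filters.

Distance follows the exponential attenuation model DIST = A·B^RSSImax:
A sets the metre scale, B (between 0 and 1) the dB slope.  Both are
calibrated per deployment from beacon transmitters at known distances by
ordinary least squares in log space, where the model is linear:
log DIST = log A + RSSImax·log B.

Records are additionally filtered on signal strength: readings above
100 dBa sit in the receiver detector's non-linear region and are
excluded, while the 45–100 dBa band is the stable performance region.
"""

from __future__ import annotations

import numpy as np

from .types import BeaconObservation, RangeModel

__all__ = ["estimate_distance", "fit_range_model", "filter_rssi_band",
           "band_fraction", "STABLE_BAND_DBA", "MAX_VALID_DBA"]

#: stable performance region of the receiver (dBa), half-open [lo, hi)
STABLE_BAND_DBA = (45.0, 101.0)

#: readings strictly above this are excluded in post-processing
MAX_VALID_DBA = 100.0


def _rssi_values(fixes) -> np.ndarray:
    """Extract rssi_max_dba from fixes, plain numbers, or observation objects."""
    vals = [getattr(f, "rssi_max_dba", f) for f in fixes]
    return np.asarray(vals, dtype=float)


def estimate_distance(model: RangeModel, rssi_max_dba):
    """DIST = A·B^RSSImax (m); strictly decreasing in RSSI since B < 1."""
    r = np.asarray(rssi_max_dba, dtype=float)
    out = model.a_coeff * model.b_coeff ** r
    return out if out.shape else float(out)


def fit_range_model(observations) -> RangeModel:
    """Least-squares fit of log(distance) = log A + RSSI·log B.

    Needs at least two observations with distinct RSSI; with exactly two
    the fit interpolates them exactly.
    """
    obs = list(observations)
    if len(obs) < 2:
        raise ValueError("at least 2 beacon observations are required")
    rssi = np.array([o.rssi_max_dba for o in obs], dtype=float)
    dist = np.array([o.true_distance_m for o in obs], dtype=float)
    if np.any(dist <= 0):
        raise ValueError("beacon distances must be positive")
    if np.ptp(rssi) == 0:
        raise ValueError("beacon observations must span distinct RSSI values")
    slope, intercept = np.polyfit(rssi, np.log(dist), 1)
    return RangeModel(a_coeff=float(np.exp(intercept)),
                      b_coeff=float(np.exp(slope)))


def filter_rssi_band(fixes, max_dba: float = MAX_VALID_DBA):
    """Partition fixes into (kept, excluded) on the overload criterion.

    Excluded are fixes with ``rssi_max_dba > max_dba`` — readings in the
    receiver's non-linear overload region; everything else is kept.  The
    two lists partition the input and preserve order.
    """
    fixes = list(fixes)
    rssi = _rssi_values(fixes)
    kept = [f for f, r in zip(fixes, rssi) if r <= max_dba]
    excluded = [f for f, r in zip(fixes, rssi) if r > max_dba]
    return kept, excluded


def band_fraction(fixes, lo_dba: float, hi_dba: float) -> float:
    """Fraction of fixes with ``lo_dba <= rssi_max_dba < hi_dba``.

    The band is half-open on the left; with integer-valued dBa readings
    the printed band "45–100" corresponds to ``[45, 101)``.
    """
    rssi = _rssi_values(fixes)
    if rssi.size == 0:
        raise ValueError("band_fraction needs a non-empty set of fixes")
    return float(np.mean((rssi >= lo_dba) & (rssi < hi_dba)))
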