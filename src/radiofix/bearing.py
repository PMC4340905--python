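"""Amplitude-comparison direction finding from four-antenna RSSI.

With antenna gain sinusoidal in dB — G(Δ) = C + S·cos(Δ) — the four
readings taken 90° apart determine the arrival azimuth exactly.  Writing
F/L/R/Re for the readings relabelled about the strongest (front) antenna,

    R − L  = 2·S·sin(ΔBRG),      F − Re = 2·S·cos(ΔBRG),

so ΔBRG = atan2(R − L, F − Re) recovers the bearing offset from the front
boresight, and BRG = K + ΔBRG with K the front antenna's rotation from
north.  The rear reading is reconstructed as Re = L + R − F because a
Yagi's rear lobe is unreliable.  The boresight signal strength follows as
RSSImax = C̄ + (F − C̄)/cos(ΔBRG) with C̄ = (L + R)/2.
"""

from __future__ import annotations

import numpy as np

from .types import CalibrationVector, QuadrantReading, wrap_deg

__all__ = ["AmbiguousBearingError", "relabel_quadrants", "reconstruct_rear",
           "compute_bearing", "apply_calibration", "estimate_rssi_max",
           "bearing_from_antennas"]


class AmbiguousBearingError(ValueError):
    """The four readings carry no usable directional information."""


def relabel_quadrants(rssi_by_antenna, antenna_rotations_deg=(0.0, 90.0, 180.0, 270.0)
                      ) -> QuadrantReading:
    """Relabel the four antenna readings about the strongest one.

    F is the maximum (ties broken by lowest antenna index), R its
    clockwise neighbour (+90°), L its counter-clockwise neighbour (−90°),
    Re the opposite antenna; ``k_deg`` is F's rotation from north.
    """
    rssi = np.asarray(rssi_by_antenna, dtype=float)
    rot = np.asarray(antenna_rotations_deg, dtype=float)
    if rssi.shape != (4,) or rot.shape != (4,):
        raise ValueError("exactly four RSSI values and rotations are required")
    if not np.all(np.isfinite(rssi)):
        raise ValueError("RSSI values must be finite")
    f = int(np.argmax(rssi))  # argmax takes the lowest index on ties

    def _at(offset_deg: float) -> int:
        target = wrap_deg(rot[f] + offset_deg)
        idx = np.flatnonzero(np.isclose(wrap_deg(rot - target), 0.0) |
                             np.isclose(wrap_deg(rot - target), 360.0))
        if idx.size != 1:
            raise ValueError("antenna rotations must be 90 degrees apart")
        return int(idx[0])

    return QuadrantReading(rssi_f=float(rssi[f]),
                           rssi_l=float(rssi[_at(-90.0)]),
                           rssi_r=float(rssi[_at(+90.0)]),
                           rssi_re=float(rssi[_at(180.0)]),
                           k_deg=float(rot[f]))


def reconstruct_rear(q: QuadrantReading) -> float:
    """Rear RSSI implied by the sinusoidal model: Re = L + R − F.

    This is the unique linear form making the two opposite-pair means
    agree under G(Δ) = C + S·cos(Δ); it replaces the measured rear value,
    which a directional antenna's poor back lobe renders untrustworthy.
    """
    return q.rssi_l + q.rssi_r - q.rssi_f


def compute_bearing(q: QuadrantReading, *, eps_db: float = 1e-9):
    """Invert the quadrant reading to (bearing_deg, delta_brg_deg).

    Uses the reconstructed rear value.  Raises
    :class:`AmbiguousBearingError` when both RSSI differences vanish
    (isotropic reading: no direction is encoded).
    """
    re = reconstruct_rear(q)
    d_rl = q.rssi_r - q.rssi_l
    d_fre = q.rssi_f - re
    if abs(d_rl) < eps_db and abs(d_fre) < eps_db:
        raise AmbiguousBearingError("all antennas read the same RSSI")
    delta = float(np.rad2deg(np.arctan2(d_rl, d_fre)))
    bearing = float(wrap_deg(q.k_deg + delta))
    return bearing, delta


def apply_calibration(bearing_deg, cal: CalibrationVector):
    """Subtract the interpolated azimuth error from a computed bearing."""
    corrected = np.asarray(bearing_deg, dtype=float) - cal.error_at(bearing_deg)
    out = wrap_deg(corrected)
    return out if out.shape else float(out)


def estimate_rssi_max(q: QuadrantReading, delta_brg_deg: float,
                      mode: str = "exact") -> float:
    """Boresight RSSI: what an antenna aimed at the transmitter would read.

    mode "exact" inverts the sinusoidal model: C̄ + (F − C̄)/cos(ΔBRG)
    with C̄ = (L + R)/2, which returns C + S exactly on model-generated
    readings.  mode "verbatim" evaluates the alternative historical form
    F − C̄·cos(ΔBRG) + C̄, kept for comparison; it is not an exact
    inverse of the sinusoidal pattern.
    """
    if abs(delta_brg_deg) >= 90.0:
        raise ValueError("|delta_brg_deg| must be below 90 degrees")
    c = float(np.cos(np.deg2rad(delta_brg_deg)))
    if c <= 0:
        raise ValueError("cos(delta_brg) must be positive")
    cbar = (q.rssi_l + q.rssi_r) / 2.0
    if mode == "exact":
        return cbar + (q.rssi_f - cbar) / c
    if mode == "verbatim":
        return q.rssi_f - cbar * c + cbar
    raise ValueError("mode must be 'exact' or 'verbatim'")


def bearing_from_antennas(rssi_by_antenna,
                          antenna_rotations_deg=(0.0, 90.0, 180.0, 270.0),
                          cal: CalibrationVector | None = None,
                          rssi_max_mode: str = "exact"):
    """Convenience pipeline: relabel → invert → calibrate → RSSImax.

    Returns ``(bearing_deg, delta_brg_deg, rssi_max_dba)`` with the
    calibration correction applied to the bearing when given.
    """
    q = relabel_quadrants(rssi_by_antenna, antenna_rotations_deg)
    bearing, delta = compute_bearing(q)
    if cal is not None:
        bearing = apply_calibration(bearing, cal)
    rssi_max = estimate_rssi_max(q, delta, mode=rssi_max_mode)
    return bearing, delta, rssi_max
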