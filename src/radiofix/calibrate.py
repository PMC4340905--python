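"""Deployment calibration: antenna-array error vector and acceptance threshold.

A station's bearing errors are systematic in azimuth (pattern and
mounting imperfections), so a rotation experiment — comparing computed
against true azimuths around the circle — yields a periodic error curve.
Its tabulation is the calibration vector later subtracted from every
bearing.

The acceptance threshold is the minimum S/N at which bearings remain
trustworthy.  Rather than reading a knee off a scatter plot by eye, the
estimator sweeps a 0.1 dB grid and returns the smallest threshold above
which a chosen quantile of the absolute azimuth error stays within a
bound; field deployments of this class of station land in the low
single-digit dB range (3.0–3.5 dB).
"""

from __future__ import annotations

import numpy as np

from .types import CalibrationVector, signed_angle_diff_deg, wrap_deg

__all__ = ["build_calibration_vector", "estimate_acceptance_threshold"]


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.deg2rad(angles_deg)
    return float(np.rad2deg(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def build_calibration_vector(measurements, node_spacing_deg: float = 5.0
                             ) -> CalibrationVector:
    """Tabulate the azimuth-dependent bearing error from rotation data.

    Each measurement is assigned to its nearest node on a
    ``node_spacing_deg`` grid over [0, 360); the node's correction is the
    circular mean of (computed − true) within its bin.  Nodes with no
    data are filled by periodic linear interpolation between populated
    neighbours, so a partially covered arc extends smoothly.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("at least one rotation measurement is required")
    if not (0 < node_spacing_deg <= 120):
        raise ValueError("node_spacing_deg must lie in (0, 120]")
    nodes = np.arange(0.0, 360.0, node_spacing_deg)
    true = np.array([m.true_azimuth_deg for m in measurements])
    err = signed_angle_diff_deg([m.computed_azimuth_deg for m in measurements], true)
    # nearest node, circularly
    node_idx = np.round(true / node_spacing_deg).astype(int) % nodes.size

    values = np.full(nodes.size, np.nan)
    for i in range(nodes.size):
        sel = node_idx == i
        if sel.any():
            values[i] = _circular_mean_deg(err[sel])
    filled = np.isfinite(values)
    if not filled.all():
        az_f = nodes[filled]
        v_f = values[filled]
        az_ext = np.concatenate([az_f, [az_f[0] + 360.0]])
        v_ext = np.concatenate([v_f, [v_f[0]]])
        values[~filled] = np.interp(nodes[~filled], az_ext, v_ext,
                                    period=360.0)
    return CalibrationVector(azimuth_deg=wrap_deg(nodes), error_deg=values)


def estimate_acceptance_threshold(points, error_bound_deg: float = 15.0,
                                  quantile: float = 0.9,
                                  grid_db: float = 0.1) -> float:
    """Smallest S/N threshold keeping the error quantile within a bound.

    Sweeps candidate thresholds t on a ``grid_db`` grid from the lowest
    observed S/N upwards and returns the smallest t for which, among
    points with S/N ≥ t, the ``quantile`` of the absolute azimuth error
    is ≤ ``error_bound_deg``.  Monotone by construction: tightening the
    bound can only raise the threshold.  Raises when no threshold
    satisfies the bound, with a diagnostic of the best achievable error.
    """
    points = list(points)
    if len(points) < 50:
        raise ValueError("at least 50 threshold-curve points are required")
    snr = np.array([p.snr_db for p in points], dtype=float)
    errs = np.array([p.abs_azimuth_error_deg for p in points], dtype=float)
    if not (0 < quantile <= 1):
        raise ValueError("quantile must lie in (0, 1]")
    t0 = np.floor(snr.min() / grid_db) * grid_db
    best_q = np.inf
    for t in np.arange(t0, snr.max() + grid_db / 2, grid_db):
        sel = snr >= t
        if not sel.any():
            break
        q = float(np.quantile(errs[sel], quantile))
        best_q = min(best_q, q)
        if q <= error_bound_deg:
            return float(round(t / grid_db) * grid_db)
    raise ValueError(
        f"no threshold satisfies the {quantile:.0%} error bound "
        f"{error_bound_deg} deg (best achievable quantile: {best_q:.1f} deg)")
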