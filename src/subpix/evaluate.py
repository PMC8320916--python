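"""Detector evaluation against ground truth.

Provides mutual-nearest-neighbour matching with RMSE and count bookkeeping,
pixel-locking curves (absolute localization error versus the true sub-pixel
coordinate), streak angle/length error summaries, and the velocity-error
arithmetic used to translate a position RMSE into a physical velocity
uncertainty for particle tracking velocimetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import k as BOLTZMANN
from scipy.spatial import cKDTree

__all__ = [
    "MatchReport",
    "match_truth",
    "pixel_locking_curve",
    "angle_difference_deg",
    "streak_error_stats",
    "velocity_uncertainty",
    "thermal_speed",
]


@dataclass(eq=False)
class MatchReport:
    """Result of pairing detections with ground truth.

    ``pairs`` holds ``(truth_index, detection_index, distance_px)`` rows;
    "all correctly detected" means no misses and no spurious detections,
    i.e. ``n_matched == n_truth == n_detected``.
    """

    pairs: pd.DataFrame
    n_truth: int
    n_detected: int
    n_matched: int
    rmse: float

    @property
    def all_correct(self) -> bool:
        return self.n_matched == self.n_truth == self.n_detected


def _as_xy(obj, cols: tuple[str, str]) -> np.ndarray:
    if isinstance(obj, pd.DataFrame):
        return obj[list(cols)].to_numpy(dtype=float)
    arr = np.atleast_2d(np.asarray(obj, dtype=float))
    if arr.shape[1] != 2:
        raise ValueError("coordinates must be (n, 2)")
    return arr


def match_truth(detections, truth, max_radius: float = 2.0) -> MatchReport:
    """Mutual-nearest-neighbour pairing of detections and truth positions.

    ``detections`` / ``truth`` may be ``(n, 2)`` arrays or DataFrames with
    columns ``x, y`` / ``mu_x, mu_y``.  A truth point and a detection are
    paired iff each is the other's nearest neighbour and their distance is
    within ``max_radius``; every point is used at most once.  The RMSE is
    computed over matched pair distances.
    """
    if not max_radius > 0:
        raise ValueError("max_radius must be > 0")
    det = _as_xy(detections, ("x", "y"))
    tru = _as_xy(truth, ("mu_x", "mu_y"))
    n_det, n_tru = det.shape[0], tru.shape[0]
    if n_det == 0 or n_tru == 0:
        return MatchReport(pairs=pd.DataFrame(columns=["truth_id", "det_id", "dist"]),
                           n_truth=n_tru, n_detected=n_det, n_matched=0,
                           rmse=float("nan"))
    det_tree = cKDTree(det)
    tru_tree = cKDTree(tru)
    d_t2d, nn_t2d = det_tree.query(tru, k=1, distance_upper_bound=max_radius)
    _, nn_d2t = tru_tree.query(det, k=1, distance_upper_bound=max_radius)
    rows = []
    for ti in range(n_tru):
        di = nn_t2d[ti]
        if di < n_det and nn_d2t[di] == ti:
            rows.append((ti, int(di), float(d_t2d[ti])))
    pairs = pd.DataFrame(rows, columns=["truth_id", "det_id", "dist"])
    rmse = float(np.sqrt(np.mean(pairs["dist"].to_numpy() ** 2))) if len(rows) else float("nan")
    return MatchReport(pairs=pairs, n_truth=n_tru, n_detected=n_det,
                       n_matched=len(rows), rmse=rmse)


def pixel_locking_curve(truth, detections, report: MatchReport) -> pd.DataFrame:
    """Per-axis ``(sub-pixel truth coordinate, absolute error)`` pairs for
    matched detections, suitable for a binned pixel-locking summary.

    The sub-pixel coordinate is ``coord - round(coord)`` in ``[-0.5, 0.5)``.
    A detector exhibits pixel locking when the error equals the sub-pixel
    offset itself (the detected coordinate is frozen at the pixel center).
    """
    det = _as_xy(detections, ("x", "y"))
    tru = _as_xy(truth, ("mu_x", "mu_y"))
    ti = report.pairs["truth_id"].to_numpy(dtype=int)
    di = report.pairs["det_id"].to_numpy(dtype=int)
    out = []
    for axis, name in ((0, "x"), (1, "y")):
        t = tru[ti, axis]
        frac = t - np.round(t)
        err = np.abs(det[di, axis] - t)
        out.append(pd.DataFrame({"axis": name, "subpixel": frac, "abs_error": err}))
    return pd.concat(out, ignore_index=True)


def angle_difference_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute orientation difference in degrees with 180-degree wrap (an
    axis has no direction: 89 and -89 differ by 2)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def streak_error_stats(results: pd.DataFrame,
                       by: list[str] | None = None) -> pd.DataFrame:
    """Mean absolute angle and length errors of streak descriptors.

    ``results`` needs columns ``angle_est, angle_true, length_est,
    length_true``; ``by`` optionally groups the summary (e.g. by true length
    or angle).
    """
    df = results.copy()
    df["angle_abs_err"] = angle_difference_deg(df["angle_est"], df["angle_true"])
    df["length_abs_err"] = np.abs(df["length_est"] - df["length_true"])
    cols = ["angle_abs_err", "length_abs_err"]
    if by:
        return df.groupby(by, as_index=False)[cols].mean()
    return df[cols].mean().to_frame().T


def velocity_uncertainty(pixel_error: float, spatial_resolution: float,
                         dt: float) -> float:
    """Velocity uncertainty (mm/s) from a per-frame position RMSE.

    A velocity is a difference of two positions, each with the same
    uncertainty, so the propagated error is ``2 * pixel_error`` pixels per
    frame interval: ``2 * pixel_error * spatial_resolution / dt`` with the
    resolution in mm/px and ``dt`` in seconds.
    """
    if not (pixel_error >= 0 and spatial_resolution > 0 and dt > 0):
        raise ValueError("pixel_error must be >= 0; resolution and dt > 0")
    return 2.0 * pixel_error * spatial_resolution / dt


def thermal_speed(diameter_um: float, density_g_cm3: float,
                  temperature_K: float = 293.0) -> float:
    """One-dimensional thermal speed sqrt(kB T / m) of a microsphere, in mm/s.

    The mass is ``density * (pi/6) * diameter^3``.  This sets the scale of
    Brownian velocities a tracking setup must resolve.
    """
    if not (diameter_um > 0 and density_g_cm3 > 0 and temperature_K > 0):
        raise ValueError("all inputs must be > 0")
    d_m = diameter_um * 1e-6
    rho = density_g_cm3 * 1000.0  # kg/m^3
    mass = rho * (math.pi / 6.0) * d_m ** 3
    return math.sqrt(BOLTZMANN * temperature_K / mass) * 1000.0  # m/s -> mm/s
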