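"""Clock synchronization of GPS and radar streams, pairing, nondetections.

The UAV's GPS clock and the radar system clock are not synchronized; the
per-test offset T is estimated by sliding the radar times and scoring how
well radar plots coincide with the (interpolated) GPS trajectory. The score
is the Gaussian log-likelihood of the linear model

    D² = β0 + β1·ΔR² + β2·ΔB²

where, for each radar plot paired with the GPS interpolant at its shifted
time, D is the planar distance between the pair, ΔR = R_radar − R_gps the
range difference from the radar, and ΔB = sin(α/2)·(R_radar + R_gps) the
transverse distance due to the bearing difference α. Maximizing the Gaussian
log-likelihood over T is equivalent to minimizing the residual variance of
this regression.

Once T is known, detections are paired by timestamp and nondetections are
derived by laying out the expected scan opportunities at the radar scan
cadence between the first and last detection of a flight: every opportunity
without a matched plot is a nondetection whose truth position comes from the
GPS track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .geometry import (RadarOrigin, orientation_class, range_bearing,
                       track_tortuosity, course as _course)
from .tracks import GpsTrack, RadarParameters, RadarTrack

__all__ = [
    "OffsetModel",
    "SyncError",
    "offset_objective",
    "estimate_offset",
    "pair_by_timestamp",
    "interpolate_nondetections",
    "build_observations",
]

#: Columns of the paired-observation table produced by this module.
OBS_COLUMNS = ["track_id", "t", "x", "y", "alt", "detected", "range",
               "bearing", "tortuosity", "in_clutter", "orientation"]


class SyncError(ValueError):
    """Raised when an offset cannot be estimated (too few pairs, flat objective)."""


@dataclass(frozen=True)
class OffsetModel:
    """Fit of the pairing regression at one candidate offset T."""

    T: float
    beta0: float
    beta1: float
    beta2: float
    loglik: float
    n_pairs: int
    rank_deficient: bool = False


def _pair_geometry(gps: GpsTrack, radar_tracks, origin: RadarOrigin, T: float):
    """Planar distances and range/bearing mismatch terms at offset T."""
    ts, xs, ys = [], [], []
    for rt in radar_tracks:
        shifted = rt.t - T
        lo, hi = gps.span
        keep = (shifted >= lo) & (shifted <= hi)
        ts.append(shifted[keep])
        xs.append(rt.x[keep])
        ys.append(rt.y[keep])
    if not ts:
        return None
    ts = np.concatenate(ts)
    xs = np.concatenate(xs)
    ys = np.concatenate(ys)
    if ts.size == 0:
        return None
    gx, gy, _ = gps.interp(ts)
    d2 = (xs - gx) ** 2 + (ys - gy) ** 2
    r_rad, b_rad = range_bearing(origin, xs, ys)
    r_gps, b_gps = range_bearing(origin, gx, gy)
    alpha = np.abs((b_rad - b_gps + 180.0) % 360.0 - 180.0)
    dr = r_rad - r_gps
    db = np.sin(np.radians(alpha) / 2.0) * (r_rad + r_gps)
    return d2, dr, db


def offset_objective(gps: GpsTrack, radar_tracks, origin: RadarOrigin,
                     T: float, min_pairs: int = 5) -> OffsetModel:
    """Score one candidate clock offset T (seconds, radar ahead of GPS).

    Radar plot times are shifted by −T; plots falling outside the GPS span
    are dropped. Ordinary least squares of D² on ΔR² and ΔB² is fitted over
    the remaining pairs and the Gaussian log-likelihood returned. A
    degenerate design (near-constant regressors) falls back to an
    intercept-only fit and is flagged.
    """
    if isinstance(radar_tracks, RadarTrack):
        radar_tracks = [radar_tracks]
    geom = _pair_geometry(gps, radar_tracks, origin, T)
    if geom is None:
        raise SyncError(f"no radar plots overlap the GPS span at T={T:.3f}")
    d2, dr, db = geom
    n = d2.size
    if n < max(3, min_pairs):
        raise SyncError(f"only {n} position pairs at T={T:.3f}; need >= {max(3, min_pairs)}")
    X = np.column_stack([np.ones(n), dr ** 2, db ** 2])
    rank_deficient = False
    coef, _, rank, _ = np.linalg.lstsq(X, d2, rcond=None)
    if rank < 3:
        rank_deficient = True
        coef = np.array([d2.mean(), 0.0, 0.0])
    resid = d2 - X @ coef
    sigma2 = max(float(np.mean(resid ** 2)), 1e-300)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return OffsetModel(T=float(T), beta0=float(coef[0]), beta1=float(coef[1]),
                       beta2=float(coef[2]), loglik=loglik, n_pairs=int(n),
                       rank_deficient=rank_deficient)


def estimate_offset(gps: GpsTrack, radar_tracks, origin: RadarOrigin,
                    window: tuple[float, float] = (0.0, 120.0),
                    grid_step: float = 1.0, tol: float = 1e-3,
                    min_pairs: int = 5) -> float:
    """Estimate the clock offset by grid search plus golden-section refinement.

    A coarse 1-s grid over the window locates the log-likelihood maximum;
    golden-section search then refines it to ``tol`` seconds on the
    bracketing interval. Ties on the grid break toward the smaller offset.
    """
    lo, hi = window
    if not hi > lo:
        raise SyncError("offset window is empty")
    if isinstance(radar_tracks, RadarTrack):
        radar_tracks = [radar_tracks]

    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    lls = np.full(grid.size, -np.inf)
    for i, T in enumerate(grid):
        try:
            lls[i] = offset_objective(gps, radar_tracks, origin, T,
                                      min_pairs=min_pairs).loglik
        except SyncError:
            continue
    if not np.any(np.isfinite(lls)):
        raise SyncError("offset objective undefined everywhere in the window")
    if np.ptp(lls[np.isfinite(lls)]) < 1e-9:
        raise SyncError("flat offset objective: no timing signal in the data")
    best = int(np.argmax(lls))  # argmax returns the first (smallest T) on ties

    a = max(lo, grid[best] - grid_step)
    b = min(hi, grid[best] + grid_step)

    def neg(T):
        try:
            return -offset_objective(gps, radar_tracks, origin, T,
                                     min_pairs=min_pairs).loglik
        except SyncError:
            return np.inf

    res = minimize_scalar(neg, bounds=(a, b), method="bounded",
                          options={"xatol": tol})
    if np.isfinite(res.fun) and -res.fun >= lls[best]:
        return float(res.x)
    return float(grid[best])


def pair_by_timestamp(gps: GpsTrack, radar_track: RadarTrack, offset: float):
    """Pair each radar plot with the GPS interpolant at its shifted time.

    Returns ``(pairs, n_dropped)`` where ``pairs`` is a DataFrame with the
    plot position, shifted time and the GPS truth position; plots whose
    shifted time falls outside the GPS span are dropped and counted.
    """
    shifted = radar_track.t - offset
    lo, hi = gps.span
    keep = (shifted >= lo) & (shifted <= hi)
    n_dropped = int(np.sum(~keep))
    ts = shifted[keep]
    gx, gy, galt = gps.interp(ts)
    pairs = pd.DataFrame({
        "t": ts,
        "radar_x": radar_track.x[keep],
        "radar_y": radar_track.y[keep],
        "gps_x": gx, "gps_y": gy, "gps_alt": galt,
    }).sort_values("t", ignore_index=True)
    return pairs, n_dropped


def interpolate_nondetections(pairs: pd.DataFrame, gps: GpsTrack,
                              params: RadarParameters,
                              tolerance: float | None = None,
                              track_id: str = "") -> pd.DataFrame:
    """Expand detections into the full grid of scan opportunities.

    Opportunities are laid out every scan interval from the first to the last
    detection of the flight. An opportunity with a paired plot within
    ±``tolerance`` (default: half the scan interval) is a detection; every
    other opportunity is a nondetection. Truth positions at every opportunity
    are GPS interpolants, so detections and nondetections are directly
    comparable.

    Returns a time-sorted DataFrame with columns ``t, x, y, alt, detected``.
    """
    dt = params.scan_interval
    if tolerance is None:
        tolerance = dt / 2.0
    if len(pairs) == 0:
        return pd.DataFrame(columns=["t", "x", "y", "alt", "detected"])
    t0 = float(pairs["t"].iloc[0])
    t1 = float(pairs["t"].iloc[-1])
    n_opp = int(math.floor((t1 - t0) / dt + 1e-9)) + 1
    times = t0 + dt * np.arange(n_opp)
    det_times = pairs["t"].to_numpy()
    # nearest detection to each opportunity
    idx = np.searchsorted(det_times, times)
    idx_lo = np.clip(idx - 1, 0, det_times.size - 1)
    idx_hi = np.clip(idx, 0, det_times.size - 1)
    gap = np.minimum(np.abs(times - det_times[idx_lo]),
                     np.abs(det_times[idx_hi] - times))
    detected = gap <= tolerance
    x, y, alt = gps.interp(times)
    ok = np.isfinite(x)  # opportunities outside the GPS span are unusable
    return pd.DataFrame({
        "track_id": track_id, "t": times[ok], "x": x[ok], "y": y[ok],
        "alt": alt[ok], "detected": detected[ok],
    })


def build_observations(gps: GpsTrack, radar_tracks, origin: RadarOrigin,
                       params: RadarParameters, offset: float,
                       tolerance: float | None = None) -> pd.DataFrame:
    """Full paired-observation table for one flight test.

    Pairs plots from all radar tracks of the test, derives nondetections at
    the scan cadence, and annotates every opportunity with range, bearing,
    tortuosity (turn statistic of the truth trajectory at the opportunity
    cadence; undefined at the ends), and orientation relative to the beam.
    The ``in_clutter`` flag is initialised False; the clutter module fills it.
    """
    if isinstance(radar_tracks, RadarTrack):
        radar_tracks = [radar_tracks]
    frames = []
    for rt in radar_tracks:
        p, _ = pair_by_timestamp(gps, rt, offset)
        if len(p):
            frames.append(p)
    if not frames:
        return pd.DataFrame(columns=OBS_COLUMNS)
    pairs = pd.concat(frames).sort_values("t", ignore_index=True)
    obs = interpolate_nondetections(pairs, gps, params, tolerance=tolerance,
                                    track_id=gps.test_id)
    if len(obs) == 0:
        return pd.DataFrame(columns=OBS_COLUMNS)
    rng, brg = range_bearing(origin, obs["x"].to_numpy(), obs["y"].to_numpy())
    obs["range"] = rng
    obs["bearing"] = brg
    obs["tortuosity"] = track_tortuosity(obs["x"].to_numpy(), obs["y"].to_numpy())
    crs = _course(obs["x"].to_numpy(), obs["y"].to_numpy())
    # course of the step arriving at each opportunity; first point inherits the
    # outgoing course so orientation is defined everywhere
    full_course = np.concatenate([[crs[0] if crs.size else np.nan], crs])
    ori = orientation_class(full_course, brg)
    ori = np.where(pd.isna(full_course), "along", ori)  # stationary: along
    obs["orientation"] = ori
    obs["in_clutter"] = False
    return obs[OBS_COLUMNS]
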