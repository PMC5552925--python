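"""Synthetic UAV flight tests and radar detections with known ground truth.

The generator reproduces the statistical structure the analysis assumes, so
every pipeline stage can be validated by parameter recovery:

* waypoint flights at cruise altitude (default 70 m AGL, hub height) sampled
  at 1 Hz, with an altitude ramp at take-off and landing so the low-altitude
  screen has something to find;
* a scanning radar producing one detection opportunity every 60/scan_rate
  seconds; at each opportunity the true detection probability is the same
  logistic model the analysis fits (range, clutter, orientation, tortuosity,
  plus a per-track Normal(0, sigma²) random intercept) and a Bernoulli draw
  decides detection;
* detected plots get isotropic Gaussian position noise and their timestamps
  are shifted by an unknown per-test clock offset in [0, 120] s;
* all truth (per-opportunity Pd, draws, offsets, random intercepts) is
  recorded, and everything is a deterministic function of (config, seed).

The default scenario mirrors a detection-verification campaign inside a
wind-power plant: seven range flights flown radially away from and toward
the radar out to ~3.1 km, and six flights zig-zagging across ground-clutter
areas. Its true coefficients put Pd = 0.5 at 2,340 m on the logit-linear
range model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .clutter import ClutterMask
from .geometry import RadarOrigin, orientation_class, range_bearing, course as _course, \
    track_tortuosity
from .tracks import GpsTrack, RadarParameters, RadarTrack

__all__ = ["ScenarioConfig", "simulate_flight", "simulate_radar",
           "generate_scenario", "default_campaign_config", "default_clutter_mask"]


@dataclass
class FlightPlan:
    """Waypoints (m) and role of one flight test."""

    waypoints: list
    test_type: str = "DR"          # DR: detection over range; DC: over clutter


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic verification campaign."""

    origin: RadarOrigin = field(default_factory=lambda: RadarOrigin(0.0, 0.0, 5.0))
    params: RadarParameters = field(default_factory=RadarParameters)
    flights: list = field(default_factory=list)
    speed: float = 20.0                 # m/s ground speed
    cruise_alt: float = 70.0            # m AGL
    gps_interval: float = 1.0           # s
    climb_rate: float = 1.2             # m/s for the take-off/landing ramp
    offset_range: tuple = (10.0, 110.0)  # true clock offsets drawn here, s
    # detection truth on the logit scale
    beta0: float = 3.136
    beta_range: float = -0.00134        # per metre; Pd=0.5 at 2,340 m
    beta_clutter: float = -0.615
    beta_orientation: float = -0.3      # across vs along
    beta_tortuosity: float = -0.5
    # terrain obscuration of low flight and tracker failure on sharp turns:
    # extra logit penalties below alt_cut / above tort_cut, giving the
    # altitude and tortuosity screens a real signature to find
    alt_cut: float = 27.0
    alt_penalty: float = -4.0
    tort_cut: float = 0.33
    tort_penalty: float = -4.0
    sigma_track: float = 0.4
    noise_sd: float = 5.0               # radar plot position noise, m
    clutter_mask: ClutterMask | None = None
    seed: int = 0

    def true_detection_range(self, pd_threshold: float = 0.5) -> float:
        """Range where the true logistic crosses the threshold (reference
        covariates: along, straight, outside clutter)."""
        return (math.log(pd_threshold / (1 - pd_threshold)) - self.beta0) \
            / self.beta_range


def _resample_path(waypoints, speed, interval):
    wp = np.asarray(waypoints, dtype=float)
    seg = np.diff(wp, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seglen == 0):
        raise ValueError("coincident consecutive waypoints")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total_t = cum[-1] / speed
    times = np.arange(0.0, total_t + interval / 2.0, interval)
    dist = np.minimum(times * speed, cum[-1])
    x = np.interp(dist, cum, wp[:, 0])
    y = np.interp(dist, cum, wp[:, 1])
    return times, x, y


def simulate_flight(config: ScenarioConfig, flight_index: int,
                    t_start: float = 0.0) -> GpsTrack:
    """Constant-speed piecewise-linear trajectory sampled at the GPS rate.

    Altitude climbs at ``climb_rate`` from 0 at take-off to cruise and
    descends symmetrically at landing, so early/late fixes sit below any
    sensible altitude screen.
    """
    plan = config.flights[flight_index]
    if len(plan.waypoints) < 2:
        raise ValueError("a flight needs at least two waypoints")
    times, x, y = _resample_path(plan.waypoints, config.speed,
                                 config.gps_interval)
    t_end = times[-1]
    alt = np.minimum(config.cruise_alt,
                     np.minimum(times * config.climb_rate,
                                (t_end - times) * config.climb_rate))
    alt = np.clip(alt, 0.0, None)
    return GpsTrack(test_id=str(flight_index + 1), t=times + t_start,
                    x=x, y=y, alt=alt, test_type=plan.test_type)


def _truth_covariates(config: ScenarioConfig, times, gps: GpsTrack):
    """Range, orientation and tortuosity of the truth path at scan cadence."""
    x, y, alt = gps.interp(times)
    rng, brg = range_bearing(config.origin, x, y)
    tort = track_tortuosity(x, y)
    crs = _course(x, y)
    full_course = np.concatenate([[crs[0] if crs.size else np.nan], crs])
    ori = orientation_class(np.nan_to_num(full_course), brg)
    across = (np.asarray(ori) == "across").astype(float)
    if config.clutter_mask is not None:
        g = config.clutter_mask._grid()
        xmin, ymin, xmax, ymax = g.extent
        inside = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
        clut = np.zeros(len(times), dtype=bool)
        if np.any(inside):
            clut[inside] = config.clutter_mask.lookup(x[inside], y[inside])
    else:
        clut = np.zeros(len(times), dtype=bool)
    return x, y, alt, rng, brg, across, np.nan_to_num(tort), clut


def simulate_radar(config: ScenarioConfig, gps: GpsTrack,
                   track_random_intercept: float, true_offset: float,
                   rng: np.random.Generator):
    """Generate the radar track and per-opportunity truth for one flight.

    Scan opportunities run every scan interval across the GPS span; at each
    the logistic detection model (with the supplied random intercept)
    gives the true Pd and a Bernoulli draw decides detection. Detected
    plots get isotropic Gaussian noise and timestamps shifted by the true
    clock offset.
    """
    dt = config.params.scan_interval
    lo, hi = gps.span
    if hi - lo < dt:
        raise ValueError("flight shorter than one scan interval")
    times = np.arange(lo, hi + 1e-9, dt)
    x, y, alt, rr, brg, across, tort, clut = _truth_covariates(config, times, gps)
    eta = (config.beta0 + config.beta_range * rr
           + config.beta_clutter * clut.astype(float)
           + config.beta_orientation * across
           + config.beta_tortuosity * tort
           + config.alt_penalty * (alt < config.alt_cut)
           + config.tort_penalty * (tort > config.tort_cut)
           + track_random_intercept)
    pd_true = expit(eta)
    detected = rng.random(len(times)) < pd_true
    noise = rng.normal(0.0, config.noise_sd, size=(len(times), 2))
    truth = pd.DataFrame({
        "test_id": gps.test_id, "t": times, "x": x, "y": y, "alt": alt,
        "range": rr, "across": across, "tortuosity": tort,
        "in_clutter": clut, "pd_true": pd_true, "detected": detected,
        "true_offset": true_offset,
        "random_intercept": track_random_intercept,
    })
    det = detected
    radar = RadarTrack(track_id=f"R{gps.test_id}",
                       t=times[det] + true_offset,
                       x=x[det] + noise[det, 0],
                       y=y[det] + noise[det, 1],
                       test_id=gps.test_id)
    return radar, truth


def generate_scenario(config: ScenarioConfig):
    """Generate all flights of a campaign: (gps tracks, radar tracks, truth).

    Deterministic in (config, config.seed): per-track random intercepts are
    Normal(0, sigma_track²), true offsets uniform over ``offset_range``.
    ``truth`` is one concatenated DataFrame plus per-test scalars accessible
    via its columns.
    """
    if not config.flights:
        raise ValueError("config has no flights")
    rng = np.random.default_rng(config.seed)
    gps_tracks, radar_tracks, truths = [], [], []
    t_start = 0.0
    for i in range(len(config.flights)):
        gps = simulate_flight(config, i, t_start=t_start)
        u = rng.normal(0.0, config.sigma_track)
        offset = rng.uniform(*config.offset_range)
        radar, truth = simulate_radar(config, gps, u, offset, rng)
        gps_tracks.append(gps)
        radar_tracks.append(radar)
        truths.append(truth)
        t_start = gps.t[-1] + 600.0  # tests separated by 10 min
    return gps_tracks, radar_tracks, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# default campaign

def default_clutter_mask(extent: float = 3600.0, cell: float = 100.0,
                         sector=(150.0, 210.0),
                         bands=((800.0, 1400.0), (2000.0, 2600.0))) -> ClutterMask:
    """Analytic clutter mask: annular bands within a bearing sector.

    Stands in for a GIS line-of-sight layer: clutter areas are patches, and
    flights crossing the sector alternate between inside and outside. The
    mask is supplied directly (the clutter module equally accepts
    terrain-derived viewsheds).
    """
    n = int(2 * extent / cell)
    xs = -extent + (np.arange(n) + 0.5) * cell
    X, Y = np.meshgrid(xs, xs[::-1])   # row 0 = north
    rng_ = np.hypot(X, Y)
    brg = np.mod(np.degrees(np.arctan2(X, Y)), 360.0)
    in_sector = (brg >= sector[0]) & (brg <= sector[1])
    in_band = np.zeros_like(rng_, dtype=bool)
    for lo, hi in bands:
        in_band |= (rng_ >= lo) & (rng_ < hi)
    return ClutterMask(-extent, -extent, cell, in_sector & in_band)


def _radial_flight(bearing_deg, r_near, r_far, cycles=2):
    """Out-and-back radial legs: away from and toward the radar."""
    b = math.radians(bearing_deg)
    u = np.array([math.sin(b), math.cos(b)])
    wps = []
    for _ in range(cycles):
        wps.append((r_near * u).tolist())
        wps.append((r_far * u).tolist())
    wps.append((r_near * u).tolist())
    return wps


def _zigzag_flight(bearing_deg, r_near, r_far, half_width=250.0, step=300.0):
    """Sawtooth path crossing clutter-band boundaries diagonally."""
    b = math.radians(bearing_deg)
    u = np.array([math.sin(b), math.cos(b)])       # radial unit
    v = np.array([math.cos(b), -math.sin(b)])      # tangential unit
    wps = []
    side = 1.0
    r = r_near
    while r <= r_far:
        wps.append((r * u + side * half_width * v).tolist())
        side = -side
        r += step
    # and back
    for p in wps[-2::-1]:
        wps.append(p)
    return wps


def default_campaign_config(seed: int = 0, clutter_mask: ClutterMask | None = None,
                      **overrides) -> ScenarioConfig:
    """The default verification campaign: 7 range flights + 6 clutter flights.

    Range flights fly two out-and-back radial cycles between 200 m and
    3,100 m at bearings clear of the clutter sector; clutter flights zigzag
    radially through the sector so each track mixes in- and out-of-clutter
    opportunities and along/across orientations.
    """
    if clutter_mask is None:
        clutter_mask = default_clutter_mask()
    flights = [FlightPlan(_radial_flight(b, 200.0, 3100.0), "DR")
               for b in (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0)]
    flights += [FlightPlan(_zigzag_flight(b, 300.0, 2900.0), "DC")
                for b in (160.0, 168.0, 176.0, 184.0, 192.0, 200.0)]
    cfg = ScenarioConfig(flights=flights, clutter_mask=clutter_mask, seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg
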