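"""End-to-end verification pipeline: sync → pair → screen → model → extrapolate.

Stages, in order, with every count logged:

1. per-test clock-offset estimation between GPS and radar streams;
2. timestamp pairing and nondetection interpolation at the scan cadence;
3. clutter flagging against the line-of-sight mask;
4. screening thresholds (altitude, tortuosity) by segmented regression —
   or fixed thresholds from the configuration — and exclusions;
5. binomial random-intercept models: clutter effect on the clutter-test
   (DC) tracks; detection over range on the range-test (DR) tracks using
   only positions outside clutter areas;
6. detection range at the Pd threshold, blip/scan table and its crossing;
7. extrapolation of the calibrated range to species of arbitrary RCS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import detection, screening, sync, theory
from .clutter import ClutterMask, flag_observations
from .geometry import RadarOrigin
from .tracks import GpsTrack, RadarParameters, RadarTrack

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    origin: RadarOrigin
    params: RadarParameters = field(default_factory=RadarParameters)
    clutter_mask: ClutterMask | None = None
    offset_window: tuple = (0.0, 120.0)
    known_offsets: dict | None = None      # test_id -> offset; skips estimation
    pairing_tolerance: float | None = None  # default: half the scan interval
    alt_min: float | None = None           # None: estimate by segmented regression
    tort_max: float | None = None
    pd_threshold: float = 0.5
    bin_width: float = 25.0
    clutter_covariates: tuple = ("range", "in_clutter", "orientation", "tortuosity")
    range_covariates: tuple = ("range", "orientation", "tortuosity")
    species: dict | None = None            # name -> RCS dBm² (or use weights)
    species_weights: dict | None = None    # name -> body mass g
    rcs_ref_db: float = theory.UAV_RCS_DB
    rcs_ref_quartiles_db: tuple = theory.UAV_RCS_QUARTILES_DB


@dataclass
class PipelineResult:
    offsets: dict
    observations: pd.DataFrame
    screening_report: dict
    thresholds: dict
    clutter_fit: object
    clutter_effect: object
    range_fit: object
    detection_range: object
    blip_scan: pd.DataFrame
    crossing_range_m: float
    extrapolation: pd.DataFrame
    log: list

    def report(self) -> dict:
        """Machine-readable summary (full precision)."""
        out = {
            "offsets": self.offsets,
            "thresholds": self.thresholds,
            "screening": self.screening_report,
            "crossing_range_m": self.crossing_range_m,
            "log": self.log,
        }
        if self.range_fit is not None:
            out["range_model"] = {
                "coefficients": self.range_fit.coefficients,
                "se": self.range_fit.se,
                "sigma_track": self.range_fit.sigma_track,
                "n_obs": self.range_fit.n_obs,
                "n_tracks": self.range_fit.n_tracks,
                "converged": self.range_fit.converged,
            }
        if self.detection_range is not None:
            out["detection_range_m"] = {
                "estimate": self.detection_range.range_at_pd,
                "ci_low": self.detection_range.ci_low,
                "ci_high": self.detection_range.ci_high,
                "pd_threshold": self.detection_range.pd_threshold,
            }
        if self.clutter_effect is not None:
            ce = self.clutter_effect
            out["clutter_effect"] = {
                "pd_outside": ce.pd_outside, "pd_inside": ce.pd_inside,
                "reduction": ce.reduction, "ci_reduction": list(ce.ci_reduction),
                "at_range_m": ce.at_range,
            }
        if len(self.extrapolation):
            out["extrapolation"] = self.extrapolation.to_dict(orient="records")
        return out


def run_pipeline(gps_tracks: list, radar_tracks: list,
                 config: PipelineConfig) -> PipelineResult:
    """Run the full verification analysis on GPS + radar track sets."""
    log = []

    def stage(name, **counts):
        log.append({"stage": name, **counts})

    by_test = {}
    for rt in radar_tracks:
        by_test.setdefault(rt.test_id or rt.track_id, []).append(rt)

    # 1-2: offsets, pairing, nondetection interpolation
    offsets, frames = {}, []
    for gps in gps_tracks:
        rts = by_test.get(gps.test_id, [])
        if not rts:
            stage("sync", test_id=gps.test_id, skipped="no radar tracks")
            continue
        if config.known_offsets and gps.test_id in config.known_offsets:
            T = float(config.known_offsets[gps.test_id])
        else:
            T = sync.estimate_offset(gps, rts, config.origin,
                                     window=config.offset_window)
        offsets[gps.test_id] = T
        obs = sync.build_observations(gps, rts, config.origin, config.params,
                                      T, tolerance=config.pairing_tolerance)
        obs["test_type"] = gps.test_type
        frames.append(obs)
        stage("sync", test_id=gps.test_id, offset_s=T, n_opportunities=len(obs),
              n_detections=int(obs["detected"].sum()))
    if not frames:
        raise RuntimeError("pipeline: no test produced observations")
    observations = pd.concat(frames, ignore_index=True)

    # 3: clutter flags
    observations = flag_observations(observations, config.clutter_mask)
    stage("clutter", n_in_clutter=int(observations["in_clutter"].sum()),
          n_total=len(observations))

    # 4: screening
    thresholds = {}
    det = observations["detected"].to_numpy(bool)
    if config.alt_min is None:
        fit_alt = screening.segmented_threshold(
            observations["alt"].to_numpy(float), det, side="lower")
        thresholds["alt_min"] = fit_alt.breakpoint
    else:
        thresholds["alt_min"] = float(config.alt_min)
    if config.tort_max is None:
        fit_tort = screening.segmented_threshold(
            observations["tortuosity"].to_numpy(float), det, side="upper")
        thresholds["tort_max"] = fit_tort.breakpoint
    else:
        thresholds["tort_max"] = float(config.tort_max)
    retained, screen_report = screening.apply_exclusions(
        observations, thresholds["alt_min"], thresholds["tort_max"])
    stage("screen", **screen_report)

    # 5a: clutter model on DC tracks
    clutter_fit = clutter_effect = None
    dc = retained[retained["test_type"] == "DC"]
    if len(dc) and dc["in_clutter"].nunique() > 1 and dc["track_id"].nunique() >= 2:
        clutter_fit = detection.fit_detection_glmm(
            dc, covariates=config.clutter_covariates)
        clutter_effect = detection.clutter_contrast(clutter_fit)
        stage("clutter_model", n_obs=clutter_fit.n_obs,
              n_tracks=clutter_fit.n_tracks, converged=clutter_fit.converged,
              reduction=clutter_effect.reduction)
    else:
        stage("clutter_model", skipped="no usable clutter-test tracks")

    # 5b-6: range model on DR tracks, outside clutter only
    range_fit = detection_range = None
    blip = pd.DataFrame(columns=["bin_left", "bin_width", "n_opportunities",
                                 "n_detections", "pd"])
    crossing = math.nan
    dr = retained[(retained["test_type"] == "DR") & (~retained["in_clutter"])]
    if len(dr) and dr["track_id"].nunique() >= 1:
        range_fit = detection.fit_detection_glmm(
            dr, covariates=config.range_covariates)
        detection_range = detection.detection_range_at(
            range_fit, pd_threshold=config.pd_threshold)
        blip = detection.blip_scan_ratio(dr, bin_width=config.bin_width)
        crossing = detection.crossing_range(blip, config.pd_threshold)
        stage("range_model", n_obs=range_fit.n_obs,
              n_tracks=range_fit.n_tracks, converged=range_fit.converged,
              detection_range_m=detection_range.range_at_pd,
              crossing_range_m=crossing)
    else:
        stage("range_model", skipped="no usable range-test tracks")

    # 7: species extrapolation
    species = dict(config.species or {})
    for name, w in (config.species_weights or {}).items():
        species.setdefault(name, theory.rcs_water_sphere(w))
    rows = []
    if species and detection_range is not None:
        r_ref = detection_range.range_at_pd
        for name, rcs in species.items():
            b = theory.extrapolation_bounds(
                rcs, config.rcs_ref_quartiles_db, r_ref, config.rcs_ref_db)
            rows.append({"name": name, "rcs_db": rcs, "modeled_m": b.range_m,
                         "lower_m": b.lower_m, "upper_m": b.upper_m})
        stage("extrapolate", n_species=len(rows), r_ref_m=r_ref)
    extrapolation = pd.DataFrame(rows)

    return PipelineResult(offsets=offsets, observations=observations,
                          screening_report=screen_report,
                          thresholds=thresholds, clutter_fit=clutter_fit,
                          clutter_effect=clutter_effect, range_fit=range_fit,
                          detection_range=detection_range, blip_scan=blip,
                          crossing_range_m=crossing,
                          extrapolation=extrapolation, log=log)
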