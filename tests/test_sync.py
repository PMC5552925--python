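import numpy as np
import pandas as pd
import pytest

from birdradar.geometry import RadarOrigin
from birdradar.sync import (SyncError, build_observations, estimate_offset,
                            interpolate_nondetections, offset_objective,
                            pair_by_timestamp)
from birdradar.simulate import default_campaign_config, simulate_flight, simulate_radar
from birdradar.tracks import GpsTrack, RadarParameters, RadarTrack

ORIGIN = RadarOrigin(0.0, 0.0, 5.0)
PARAMS = RadarParameters()


def straight_gps(n=300, speed=20.0):
    t = np.arange(n, dtype=float)
    return GpsTrack(test_id="g", t=t, x=200.0 + speed * t, y=np.zeros(n),
                    alt=np.full(n, 70.0))


def radar_from_gps(gps, offset, noise_sd=0.0, every=3, seed=0):
    rng = np.random.default_rng(seed)
    idx = np.arange(0, len(gps), every)
    return RadarTrack(track_id="r", t=gps.t[idx] + offset,
                      x=gps.x[idx] + rng.normal(0, noise_sd, idx.size),
                      y=gps.y[idx] + rng.normal(0, noise_sd, idx.size))


def test_objective_peaks_at_zero_for_coincident_plots():
    gps = straight_gps()
    radar = radar_from_gps(gps, offset=0.0)
    ll0 = offset_objective(gps, radar, ORIGIN, 0.0).loglik
    for T in (5.0, 20.0, 60.0):
        assert ll0 > offset_objective(gps, radar, ORIGIN, T).loglik


def test_objective_prefers_true_offset_under_noise():
    gps = straight_gps()
    radar = radar_from_gps(gps, offset=46.2, noise_sd=5.0, seed=1)
    ll_true = offset_objective(gps, radar, ORIGIN, 46.2).loglik
    assert ll_true > offset_objective(gps, radar, ORIGIN, 0.0).loglik
    assert ll_true > offset_objective(gps, radar, ORIGIN, 36.2).loglik
    assert ll_true > offset_objective(gps, radar, ORIGIN, 56.2).loglik


def test_objective_too_few_pairs_raises():
    gps = straight_gps(n=10)
    radar = RadarTrack(track_id="r", t=np.array([2.0, 5.0]),
                       x=np.zeros(2), y=np.zeros(2))
    with pytest.raises(SyncError):
        offset_objective(gps, radar, ORIGIN, 0.0)


def test_rank_deficient_design_falls_back_to_intercept():
    # all plots at the same position: ΔR², ΔB² constant -> rank deficient
    gps = GpsTrack(test_id="g", t=np.arange(20.0), x=np.full(20, 500.0),
                   y=np.zeros(20))
    radar = RadarTrack(track_id="r", t=np.arange(0.0, 20.0, 2.0),
                       x=np.full(10, 510.0), y=np.zeros(10))
    m = offset_objective(gps, radar, ORIGIN, 0.0)
    assert m.rank_deficient
    assert m.beta1 == 0.0 and m.beta2 == 0.0
    assert m.beta0 == pytest.approx(100.0)


def test_estimate_offset_recovers_injected_offset():
    gps = straight_gps(n=400)
    radar = radar_from_gps(gps, offset=46.2, noise_sd=5.0, seed=2)
    T = estimate_offset(gps, radar, ORIGIN)
    assert T == pytest.approx(46.2, abs=0.5)


def test_estimate_offset_zero_offset_data():
    gps = straight_gps(n=400)
    radar = radar_from_gps(gps, offset=0.0, noise_sd=3.0, seed=3)
    T = estimate_offset(gps, radar, ORIGIN)
    assert T == pytest.approx(0.0, abs=0.5)


def test_estimate_offset_empty_window_raises():
    gps = straight_gps()
    radar = radar_from_gps(gps, offset=10.0)
    with pytest.raises(SyncError):
        estimate_offset(gps, radar, ORIGIN, window=(5.0, 5.0))


def test_pairing_drops_out_of_span_plots():
    gps = straight_gps(n=100)
    t = np.concatenate([[-0.1], np.arange(10.0, 20.0)])
    radar = RadarTrack(track_id="r", t=t, x=np.zeros(t.size), y=np.zeros(t.size))
    pairs, dropped = pair_by_timestamp(gps, radar, offset=0.0)
    assert len(pairs) == 10 and dropped == 1


def test_pairing_matches_simulator_correspondence():
    """With zero noise and the true offset, every pair is exact."""
    cfg = default_campaign_config(seed=5, noise_sd=0.0)
    gps = simulate_flight(cfg, 0)
    rng = np.random.default_rng(0)
    radar, truth = simulate_radar(cfg, gps, 0.0, true_offset=33.0, rng=rng)
    pairs, dropped = pair_by_timestamp(gps, radar, offset=33.0)
    assert dropped == 0
    assert np.allclose(pairs["radar_x"], pairs["gps_x"], atol=1e-9)
    assert np.allclose(pairs["radar_y"], pairs["gps_y"], atol=1e-9)


def test_nondetection_interpolation_counts():
    gps = straight_gps(n=100)
    dt = PARAMS.scan_interval
    assert dt == pytest.approx(60.0 / 22.5)
    # detections at every scan time -> zero nondetections
    times = gps.t[0] + dt * np.arange(10)
    pairs = pd.DataFrame({"t": times})
    obs = interpolate_nondetections(pairs, gps, PARAMS)
    assert obs["detected"].all() and len(obs) == 10
    # two detections 8 s apart -> floor(8/2.667)-1 = 2 interior nondetections
    pairs2 = pd.DataFrame({"t": [10.0, 18.0]})
    obs2 = interpolate_nondetections(pairs2, gps, PARAMS)
    assert int(obs2["detected"].sum()) == 2
    assert int((~obs2["detected"]).sum()) == 2


def test_opportunity_spacing_invariant():
    """No two opportunities are closer than half the scan interval."""
    cfg = default_campaign_config(seed=6)
    gps = simulate_flight(cfg, 1)
    radar, _ = simulate_radar(cfg, gps, 0.0, 20.0, np.random.default_rng(1))
    obs = build_observations(gps, radar, ORIGIN, PARAMS, offset=20.0)
    gaps = np.diff(np.sort(obs["t"].to_numpy()))
    assert np.all(gaps > PARAMS.scan_interval / 2.0)
    assert set(obs["orientation"]) <= {"along", "across"}
    assert (obs["range"] >= 0).all()


def test_offset_recovery_across_seeds():
    """Injected offsets are recovered within ±0.5 s at 5 m plot noise."""
    errs = []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        true_T = rng.uniform(5.0, 115.0)
        gps = straight_gps(n=350)
        radar = radar_from_gps(gps, offset=true_T, noise_sd=5.0, seed=seed)
        errs.append(abs(estimate_offset(gps, radar, ORIGIN) - true_T))
    assert np.all(np.asarray(errs) <= 0.5)
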