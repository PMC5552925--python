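import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from birdradar.geometry import course
from birdradar.simulate import (FlightPlan, ScenarioConfig, default_clutter_mask,
                                generate_scenario, default_campaign_config,
                                simulate_flight, simulate_radar)


def test_flight_fix_count():
    """Two waypoints 1,000 m apart at 20 m/s, 1 Hz -> 51 fixes."""
    cfg = ScenarioConfig(flights=[FlightPlan([(0.0, 0.0), (1000.0, 0.0)])])
    gps = simulate_flight(cfg, 0)
    assert len(gps) == 51
    assert gps.t[-1] - gps.t[0] == pytest.approx(50.0)


def test_single_segment_constant_course():
    cfg = ScenarioConfig(flights=[FlightPlan([(0.0, 0.0), (500.0, 500.0)])])
    gps = simulate_flight(cfg, 0)
    c = course(gps.x, gps.y)
    assert np.allclose(c, 45.0)


def test_out_and_back_reversal_tortuosity():
    cfg = ScenarioConfig(flights=[FlightPlan([(0.0, 100.0), (0.0, 2000.0),
                                              (0.0, 100.0)])])
    gps = simulate_flight(cfg, 0)
    from birdradar.geometry import track_tortuosity
    s = track_tortuosity(gps.x, gps.y)
    assert np.nanmax(s) == pytest.approx(1.0)


def test_altitude_ramp_exercises_screen():
    cfg = default_campaign_config(seed=0)
    gps = simulate_flight(cfg, 0)
    assert gps.alt[0] < cfg.alt_cut          # take-off below the screen
    assert gps.alt.max() == pytest.approx(cfg.cruise_alt)
    assert gps.alt[-1] < cfg.alt_cut


def test_coincident_waypoints_rejected():
    cfg = ScenarioConfig(flights=[FlightPlan([(0.0, 0.0), (0.0, 0.0),
                                              (10.0, 0.0)])])
    with pytest.raises(ValueError):
        simulate_flight(cfg, 0)


def test_zero_noise_zero_offset_plots_on_trajectory():
    cfg = default_campaign_config(seed=2, noise_sd=0.0)
    gps = simulate_flight(cfg, 0)
    radar, truth = simulate_radar(cfg, gps, 0.0, 0.0, np.random.default_rng(0))
    gx, gy, _ = gps.interp(radar.t)
    assert np.allclose(radar.x, gx, atol=1e-9)
    assert np.allclose(radar.y, gy, atol=1e-9)


def test_detections_vanish_beyond_hard_range_limit():
    cfg = default_campaign_config(seed=3, beta0=200.0, beta_range=-2.0)  # cliff at 100 m
    gps = simulate_flight(cfg, 0)
    radar, truth = simulate_radar(cfg, gps, 0.0, 0.0, np.random.default_rng(0))
    assert truth.loc[truth["range"] > 101.0, "detected"].sum() == 0


def test_empirical_rate_matches_true_pd():
    """Monte-Carlo conservation at fixed covariates, 10⁴ opportunities."""
    rng = np.random.default_rng(12)
    cfg = ScenarioConfig(flights=[FlightPlan([(0.0, 1500.0), (1.0, 1500.0)])],
                         sigma_track=0.0, alt_penalty=0.0)
    n = 10_000
    p_true = expit(cfg.beta0 + cfg.beta_range * 1500.0)
    draws = rng.random(n) < p_true
    # direct conservation check of the generative rule at fixed eta
    rate = draws.mean()
    sd = np.sqrt(p_true * (1 - p_true) / n)
    assert abs(rate - p_true) < 3 * sd


def test_scenario_reproducible_and_seed_sensitive():
    cfg_a = default_campaign_config(seed=9)
    cfg_b = default_campaign_config(seed=9)
    ga, ra, ta = generate_scenario(cfg_a)
    gb, rb, tb = generate_scenario(cfg_b)
    pd.testing.assert_frame_equal(ta, tb)
    assert all(np.array_equal(x.t, y.t) and np.array_equal(x.x, y.x)
               for x, y in zip(ra, rb))
    gc, rc, tc = generate_scenario(default_campaign_config(seed=10))
    assert not tc["detected"].equals(ta["detected"])


def test_truth_bookkeeping_consistent():
    cfg = default_campaign_config(seed=4)
    gps, radar, truth = generate_scenario(cfg)
    assert len(gps) == 13 and len(radar) == 13
    # every detected truth row corresponds to exactly one radar plot
    for g, r in zip(gps, radar):
        t = truth[truth["test_id"] == g.test_id]
        assert int(t["detected"].sum()) == len(r)
        off = t["true_offset"].iloc[0]
        assert cfg.offset_range[0] <= off <= cfg.offset_range[1]
    # per-track random intercepts are constant within track
    assert (truth.groupby("test_id")["random_intercept"].nunique() == 1).all()


def test_clutter_flights_mix_in_and_out(shared_clutter_mask):
    cfg = default_campaign_config(seed=5, clutter_mask=shared_clutter_mask)
    gps, radar, truth = generate_scenario(cfg)
    dc_ids = [g.test_id for g in gps if g.test_type == "DC"]
    dc = truth[truth["test_id"].isin(dc_ids)]
    frac = dc["in_clutter"].mean()
    assert 0.15 < frac < 0.85
    dr = truth[~truth["test_id"].isin(dc_ids)]
    assert dr["in_clutter"].mean() < 0.05
    # both orientations present on the zig-zag clutter flights
    assert 0.05 < dc["across"].mean() < 0.95
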