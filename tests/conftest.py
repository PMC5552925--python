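import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from birdradar.simulate import (ScenarioConfig, FlightPlan, default_clutter_mask,
                                generate_scenario, default_campaign_config)


@pytest.fixture(scope="session")
def shared_clutter_mask():
    """The default analytic clutter mask, built once per session."""
    return default_clutter_mask()


@pytest.fixture(scope="session")
def small_scenario(shared_clutter_mask):
    """A reduced campaign (3 range + 2 clutter flights) for fast pipeline tests."""
    cfg = default_campaign_config(seed=11, clutter_mask=shared_clutter_mask)
    cfg.flights = cfg.flights[:3] + cfg.flights[7:9]
    gps, radar, truth = generate_scenario(cfg)
    return cfg, gps, radar, truth


def make_glmm_data(seed, n_tracks=6, per_track=80, beta0=0.0, beta_range=0.0,
                   beta_clutter=0.0, beta_orientation=0.0, beta_tortuosity=0.0,
                   sigma=0.4):
    """Random-covariate detection data with known truth (for model tests)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma, n_tracks)
    rows = []
    for j in range(n_tracks):
        r = rng.uniform(200.0, 3200.0, per_track)
        clut = rng.random(per_track) < 0.4
        ori = rng.random(per_track) < 0.35
        tort = np.abs(rng.normal(0.0, 0.12, per_track))
        eta = (beta0 + beta_range * r + beta_clutter * clut
               + beta_orientation * ori + beta_tortuosity * tort + u[j])
        rows.append(pd.DataFrame({
            "track_id": f"t{j}", "range": r, "in_clutter": clut,
            "orientation": np.where(ori, "across", "along"),
            "tortuosity": tort,
            "detected": rng.random(per_track) < expit(eta)}))
    return pd.concat(rows, ignore_index=True)
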