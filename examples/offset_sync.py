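"""Recover the unknown clock offset between a GPS track and radar plots.

The UAV's GPS and the radar system run on unsynchronized clocks. A
simulated flight is generated with a known offset; the estimator slides
the radar times over a [0, 120] s window and maximizes the Gaussian
log-likelihood of the distance-mismatch regression
D² = β0 + β1·ΔR² + β2·ΔB².
"""

import numpy as np

from birdradar import estimate_offset, offset_objective
from birdradar.simulate import default_campaign_config, simulate_flight, simulate_radar

cfg = default_campaign_config(seed=3)
gps = simulate_flight(cfg, 0)
true_offset = 46.2
radar, _ = simulate_radar(cfg, gps, 0.0, true_offset,
                          np.random.default_rng(3))

est = estimate_offset(gps, radar, cfg.origin)
print(f"true offset  : {true_offset:.3f} s")
print(f"estimated    : {est:.3f} s   (error {abs(est - true_offset):.3f} s)")

for T in (0.0, 30.0, true_offset, 60.0, 90.0):
    m = offset_objective(gps, radar, cfg.origin, T)
    print(f"  T = {T:6.1f} s  log-likelihood = {m.loglik:10.1f}  "
          f"(n = {m.n_pairs})")
# The objective peaks sharply at the true offset: a 1 s timing error already
# displaces the 20 m/s UAV by 20 m, far above the 5 m radar plot noise.
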