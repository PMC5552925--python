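"""Build a ground-clutter mask as the radar's viewshed over terrain.

Ground clutter arises where the radar has line-of-sight to the ground.
A small synthetic terrain with a ridge shows how the viewshed splits the
area into clutter (visible) and shadowed (clutter-free) zones.
"""

import numpy as np

from birdradar import RadarOrigin, TerrainGrid, build_clutter_mask, in_clutter

# 2 km × 2 km grid, 50 m cells; a 25 m ridge runs north-south at x ≈ 1200 m
n = 40
z = np.zeros((n, n))
z[:, 24] = 25.0
grid = TerrainGrid(xll=0.0, yll=0.0, cell_size=50.0, values=z)

radar = RadarOrigin(x=500.0, y=1000.0, antenna_height=5.0)
mask = build_clutter_mask(grid, radar, target_height=0.0)

total = mask.mask.size
visible = int(mask.mask.sum())
print(f"clutter (in line-of-sight) cells: {visible}/{total} "
      f"({100 * visible / total:.0f}% of the area)")
print("point west of the ridge  (800, 1000):",
      "clutter" if in_clutter(mask, 800.0, 1000.0) else "shadowed")
print("point east of the ridge (1600, 1000):",
      "clutter" if in_clutter(mask, 1600.0, 1000.0) else "shadowed")
# Flight positions falling in clutter cells carry the in_clutter flag in
# the detection model; the ridge's radar shadow is clutter-free but would
# also hide low-flying targets.
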