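"""Ground-clutter mapping by terrain line-of-sight (viewshed) analysis.

Ground clutter is modelled as the set of terrain cells in line-of-sight of
the radar antenna: where the radar can see the ground, ground returns
compete with the target and detection suffers. The viewshed is computed on
an ESRI ASCII terrain grid by sampling the terrain profile under each
sightline at half-cell steps with bilinear interpolation. Earth curvature
and refraction are ignored by default (sub-metre effect at the few-km
ranges involved); a 4/3-Earth-radius correction is available.

A pre-computed clutter mask (e.g. from an external GIS) may be supplied
directly instead of a terrain grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import RadarOrigin

__all__ = [
    "TerrainGrid",
    "ClutterMask",
    "read_ascii_grid",
    "write_ascii_grid",
    "line_of_sight",
    "build_clutter_mask",
    "in_clutter",
]

_EFFECTIVE_EARTH_RADIUS = 4.0 / 3.0 * 6371000.0


class OutsideGridError(ValueError):
    """A queried point lies outside the grid frame."""


@dataclass
class TerrainGrid:
    """A regular elevation grid in the ESRI ASCII (.asc) frame.

    ``values`` is stored with row 0 at the TOP (north), as in the file
    format. Cells are half-open: cell (col i, row j from the bottom) covers
    [xll + i·cs, xll + (i+1)·cs) × [yll + j·cs, yll + (j+1)·cs).
    """

    xll: float
    yll: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (self.xll, self.yll,
                self.xll + self.n_cols * self.cell_size,
                self.yll + self.n_rows * self.cell_size)

    def contains(self, x, y) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return bool(np.all((x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)))

    def cell_index(self, x, y):
        """(row, col) of the cell containing (x, y), half-open convention."""
        if not self.contains(x, y):
            raise OutsideGridError(f"point ({x}, {y}) outside grid extent")
        col = np.floor((np.asarray(x) - self.xll) / self.cell_size).astype(int)
        row_from_bottom = np.floor((np.asarray(y) - self.yll) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def cell_centers(self):
        """x-centres (n_cols,) and y-centres (n_rows,), y matching row order (top first)."""
        xs = self.xll + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys_bottom = self.yll + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys_bottom[::-1]

    def elevation_at(self, x, y):
        """Bilinear elevation at (x, y); nan where a nodata cell contributes."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not self.contains(x, y):
            raise OutsideGridError("point outside grid extent")
        z = np.where(self.values == self.nodata, np.nan, self.values)[::-1, :]  # row 0 = south
        fx = (x - self.xll) / self.cell_size - 0.5
        fy = (y - self.yll) / self.cell_size - 0.5
        i0 = np.clip(np.floor(fx).astype(int), 0, self.n_cols - 2) if self.n_cols > 1 else np.zeros_like(fx, int)
        j0 = np.clip(np.floor(fy).astype(int), 0, self.n_rows - 2) if self.n_rows > 1 else np.zeros_like(fy, int)
        tx = np.clip(fx - i0, 0.0, 1.0)
        ty = np.clip(fy - j0, 0.0, 1.0)
        i1 = np.minimum(i0 + 1, self.n_cols - 1)
        j1 = np.minimum(j0 + 1, self.n_rows - 1)
        out = ((1 - tx) * (1 - ty) * z[j0, i0] + tx * (1 - ty) * z[j0, i1]
               + (1 - tx) * ty * z[j1, i0] + tx * ty * z[j1, i1])
        return out


@dataclass
class ClutterMask:
    """Boolean grid in the same frame as its source terrain: True = in
    line-of-sight of the radar = clutter area."""

    xll: float
    yll: float
    cell_size: float
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    def _grid(self) -> TerrainGrid:
        return TerrainGrid(self.xll, self.yll, self.cell_size,
                           self.mask.astype(float))

    def contains(self, x, y) -> bool:
        return self._grid().contains(x, y)

    def lookup(self, x, y):
        """Clutter membership of the cell(s) containing the point(s)."""
        row, col = self._grid().cell_index(x, y)
        return self.mask[row, col]


def read_ascii_grid(path) -> TerrainGrid:
    """Read an ESRI ASCII grid (.asc). Supports xllcorner/yllcorner and
    xllcenter/yllcenter headers."""
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(lines[i:].__iter__(), ndmin=2)
    cs = header["cellsize"]
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cs / 2.0)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cs / 2.0)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data shape does not match header")
    return TerrainGrid(xll=xll, yll=yll, cell_size=cs, values=values,
                       nodata=header.get("nodata_value", -9999.0))


def write_ascii_grid(path, grid) -> None:
    """Write a TerrainGrid or ClutterMask as an ESRI ASCII grid (.asc)."""
    if isinstance(grid, ClutterMask):
        values = grid.mask.astype(int)
        nodata = -9999
    else:
        values = grid.values
        nodata = grid.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {values.shape[1]}\n")
        fh.write(f"nrows {values.shape[0]}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in values:
            fh.write(" ".join(repr(v) if isinstance(v, float) else str(v)
                              for v in row.tolist()) + "\n")


def mask_from_grid(grid: TerrainGrid, threshold: float = 0.5) -> ClutterMask:
    """Interpret a 0/1 ASCII grid as a clutter mask."""
    return ClutterMask(grid.xll, grid.yll, grid.cell_size,
                       grid.values > threshold)


def _sightline_clear(grid: TerrainGrid, x0, y0, z0, x1, y1, z1,
                     step: float, curvature: bool) -> bool:
    dist = float(np.hypot(x1 - x0, y1 - y0))
    if dist <= step:
        return True
    n = max(int(np.ceil(dist / step)), 2)
    f = np.linspace(0.0, 1.0, n + 1)[1:-1]  # interior samples only
    xs = x0 + f * (x1 - x0)
    ys = y0 + f * (y1 - y0)
    zs = z0 + f * (z1 - z0)
    if curvature:
        d = f * dist
        zs = zs - d * (dist - d) / (2.0 * _EFFECTIVE_EARTH_RADIUS)
    terr = grid.elevation_at(xs, ys)
    if np.any(np.isnan(terr)):
        warnings.warn("nodata cell along sight profile treated as blocking")
        return False
    return bool(np.all(terr <= zs + 1e-9))


def line_of_sight(grid: TerrainGrid, origin: RadarOrigin, target_x: float,
                  target_y: float, target_height: float = 0.0,
                  curvature: bool = False) -> bool:
    """Is the target visible from the antenna over the terrain profile?

    The sightline runs from (origin ground elevation + antenna height) to
    (target ground elevation + target height); the terrain is sampled at
    half-cell steps with bilinear interpolation and must stay at or below
    the sightline everywhere between the endpoints.
    """
    for px, py in ((origin.x, origin.y), (target_x, target_y)):
        if not grid.contains(px, py):
            raise OutsideGridError(f"point ({px}, {py}) outside terrain grid")
    z0 = float(grid.elevation_at(origin.x, origin.y)) + origin.antenna_height
    z1 = float(grid.elevation_at(target_x, target_y)) + target_height
    if np.isnan(z0) or np.isnan(z1):
        warnings.warn("nodata at sightline endpoint treated as blocking")
        return False
    return _sightline_clear(grid, origin.x, origin.y, z0, target_x, target_y,
                            z1, grid.cell_size / 2.0, curvature)


def build_clutter_mask(grid: TerrainGrid, origin: RadarOrigin,
                       target_height: float = 0.0,
                       curvature: bool = False) -> ClutterMask:
    """Viewshed of the radar over the terrain grid: per-cell line-of-sight
    to the cell centre at ``target_height`` above ground."""
    xs, ys = grid.cell_centers()
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, yc in enumerate(ys):
            for i, xc in enumerate(xs):
                mask[j, i] = line_of_sight(grid, origin, float(xc), float(yc),
                                           target_height, curvature)
    return ClutterMask(grid.xll, grid.yll, grid.cell_size, mask)


def in_clutter(mask: ClutterMask, x, y):
    """Clutter membership of the cell containing each point (half-open cells).

    Points are evaluated at their ground projection — the mask is a 2-D GIS
    layer, so flight altitude does not enter.
    """
    return mask.lookup(x, y)


def flag_observations(obs, mask: ClutterMask | None, outside_value: bool = False):
    """Fill the ``in_clutter`` column of an observation table from a mask.

    Points outside the mask frame get ``outside_value``. Returns the table
    (modified copy)."""
    import pandas as pd  # local: keep module import-light

    obs = obs.copy()
    if mask is None or len(obs) == 0:
        return obs
    x = obs["x"].to_numpy()
    y = obs["y"].to_numpy()
    g = mask._grid()
    xmin, ymin, xmax, ymax = g.extent
    inside = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
    flags = np.full(len(obs), outside_value, dtype=bool)
    if np.any(inside):
        flags[inside] = mask.lookup(x[inside], y[inside])
    obs["in_clutter"] = flags
    return obs
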