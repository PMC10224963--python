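"""Point-density hotspot rasters and count-per-km2 histograms.

The hotspot map follows the classic GIS point-density definition: the value
at each cell center is the number of points within a search radius divided
by the neighborhood area, expressed per km2. Defaults (100 m cells, 500 m
radius) suit herd-scale aggregation mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from wildcount.scene import PointSet


@dataclass
class DensityMap:
    values: np.ndarray  # (rows, cols), animals per km2
    cell_size: float  # meters
    radius: float  # meters
    origin: tuple  # world (x, y) of the top-left corner

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("densities must be non-negative")


def _extent_tuple(extent) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty extent {extent}")
    return float(x0), float(y0), float(x1), float(y1)


def point_density(
    points: PointSet,
    extent,
    cell_size: float = 100.0,
    radius: float = 500.0,
) -> DensityMap:
    """Neighborhood point density on a regular grid over ``extent``.

    ``extent`` is ``(x_min, y_min, x_max, y_max)`` in world meters. Each
    cell's value is the count of points within ``radius`` of the cell
    center, divided by the circular neighborhood area (pi * radius^2),
    reported in animals per km2.
    """
    x0, y0, x1, y1 = _extent_tuple(extent)
    if radius < cell_size / 2:
        raise ValueError("radius must be at least half the cell size")
    n_cols = max(1, math.ceil((x1 - x0) / cell_size))
    n_rows = max(1, math.ceil((y1 - y0) / cell_size))
    cols = x0 + (np.arange(n_cols) + 0.5) * cell_size
    rows = y1 - (np.arange(n_rows) + 0.5) * cell_size
    cx, cy = np.meshgrid(cols, rows)
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    if len(points) == 0:
        counts = np.zeros(len(centers))
    else:
        tree = cKDTree(points.points)
        counts = np.asarray(
            [len(idx) for idx in tree.query_ball_point(centers, r=radius)],
            dtype=float,
        )
    area_km2 = math.pi * (radius / 1000.0) ** 2
    values = (counts / area_km2).reshape(n_rows, n_cols)
    return DensityMap(values, cell_size, radius, (x0, y1))


def density_histogram(
    points: PointSet, extent, bin_cell: float = 1000.0
) -> pd.Series:
    """Histogram of per-cell point counts on a km2 grid over ``extent``.

    Cells of side ``bin_cell`` meters are anchored at the extent's top-left
    corner. Returns a Series indexed by count with the number of cells per
    count; the mass-weighted total equals the number of points inside the
    extent exactly.
    """
    x0, y0, x1, y1 = _extent_tuple(extent)
    n_cols = max(1, math.ceil((x1 - x0) / bin_cell))
    n_rows = max(1, math.ceil((y1 - y0) / bin_cell))
    per_cell = np.zeros((n_rows, n_cols), dtype=int)
    for x, y in points.points:
        if not (x0 <= x < x1 and y0 < y <= y1):
            continue
        col = min(int((x - x0) // bin_cell), n_cols - 1)
        row = min(int((y1 - y) // bin_cell), n_rows - 1)
        per_cell[row, col] += 1
    counts, freqs = np.unique(per_cell, return_counts=True)
    return pd.Series(freqs, index=counts, name="n_cells").rename_axis("count")
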