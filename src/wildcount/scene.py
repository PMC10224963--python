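"""Georeferenced raster and point I/O, the tiling grid, and patch extraction.

Conventions used throughout the package:

* pixel indices are 0-based ``(row, col)``; windows are half-open;
* the world coordinate of a pixel refers to its **center**;
* scenes are north-up: world ``x`` grows with ``col``, world ``y`` decreases
  with ``row``; ``origin`` is the world coordinate of the top-left corner of
  pixel ``(0, 0)``.

Rasters are stored as GeoTIFF through :mod:`tifffile`, carrying the standard
``ModelPixelScaleTag``/``ModelTiepointTag`` geo tags plus a JSON description
with the CRS label and nodata sentinel, so that world<->pixel conversion
round-trips exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

#: Default radiometric ceiling: WorldView-class sensors deliver 11-bit data.
DEFAULT_BIT_DEPTH_MAX = 2**11 - 1


@dataclass
class Scene:
    """A georeferenced multi-band raster; the unit of detection and counting.

    Parameters
    ----------
    bands
        Intensity array of shape ``(n_bands, height, width)``. Four bands
        (R, G, B, NIR) are expected for the detection pipeline but any
        count >= 1 is representable.
    pixel_size
        Ground sample distance in meters (square pixels).
    origin
        World ``(x, y)`` of the top-left corner of pixel ``(0, 0)``.
    crs_label
        Free-text identifier of the coordinate reference system.
    nodata_value
        Optional sentinel marking invalid pixels.
    """

    bands: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local-meters"
    nodata_value: float | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3:
            raise ValueError(
                f"bands must be 3-D (band, row, col); got shape {self.bands.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def height(self) -> int:
        return self.bands.shape[1]

    @property
    def width(self) -> int:
        return self.bands.shape[2]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """World extent ``(x_min, y_min, x_max, y_max)``."""
        ox, oy = self.origin
        return (
            ox,
            oy - self.height * self.pixel_size,
            ox + self.width * self.pixel_size,
            oy,
        )

    def pixel_to_world(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of the center(s) of pixel(s) ``(row, col)``."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        ox, oy = self.origin
        x = ox + (col + 0.5) * self.pixel_size
        y = oy - (row + 0.5) * self.pixel_size
        return x, y

    def world_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the pixel(s) containing world point(s) ``(x, y)``."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ox, oy = self.origin
        col = np.floor((x - ox) / self.pixel_size).astype(int)
        row = np.floor((oy - y) / self.pixel_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        x_min, y_min, x_max, y_max = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= x_min) & (x < x_max) & (y > y_min) & (y <= y_max)


@dataclass
class PointSet:
    """Georeferenced points: labels, consensus labels, or detections."""

    points: np.ndarray  # (N, 2) array of world (x, y)
    scores: np.ndarray | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
            if self.scores.shape[0] != self.points.shape[0]:
                raise ValueError("scores length must match number of points")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        df["score"] = self.scores if self.scores is not None else np.nan
        df["source"] = self.source_tag
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointSet":
        df = pd.read_csv(path)
        scores = None
        if "score" in df.columns and df["score"].notna().any():
            scores = df["score"].to_numpy(dtype=float)
        tag = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else ""
        return cls(df[["x", "y"]].to_numpy(dtype=float), scores, tag)

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for i in range(len(self)):
            props: dict = {"source": self.source_tag}
            if self.scores is not None:
                props["score"] = float(self.scores[i])
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(self.x[i]), float(self.y[i])],
                    },
                    "properties": props,
                }
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PointSet":
        data = json.loads(Path(path).read_text())
        pts, scores, tag = [], [], ""
        for feat in data.get("features", []):
            pts.append(feat["geometry"]["coordinates"][:2])
            props = feat.get("properties") or {}
            scores.append(props.get("score", np.nan))
            tag = props.get("source", tag)
        pts_arr = np.asarray(pts, dtype=float).reshape(-1, 2)
        scores_arr = np.asarray(scores, dtype=float)
        if scores_arr.size == 0 or np.isnan(scores_arr).all():
            return cls(pts_arr, None, tag)
        return cls(pts_arr, scores_arr, tag)


@dataclass
class GridCell:
    """One tile of the scene grid (half-open pixel window)."""

    row_index: int
    col_index: int
    row0: int
    col0: int
    height: int
    width: int
    full: bool = True

    @property
    def pixel_window(self) -> tuple[int, int, int, int]:
        return (self.row0, self.col0, self.height, self.width)

    def ground_extent(self, pixel_size: float) -> tuple[float, float]:
        """(width_m, height_m) of the cell footprint on the ground."""
        return (self.width * pixel_size, self.height * pixel_size)


def save_scene(scene: Scene, path: str | Path) -> None:
    """Write a scene as a GeoTIFF with geo tags and a JSON description."""
    ox, oy = scene.origin
    desc = json.dumps(
        {
            "crs_label": scene.crs_label,
            "nodata_value": scene.nodata_value,
        }
    )
    data = scene.bands if scene.n_bands > 1 else scene.bands[0]
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        planarconfig="separate" if scene.n_bands > 1 else None,
        description=desc,
        extratags=[
            (_MODEL_PIXEL_SCALE, "d", 3, (scene.pixel_size, scene.pixel_size, 0.0)),
            (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        ],
    )


def load_scene(path: str | Path, expected_bands: int | None = None) -> Scene:
    """Read a GeoTIFF written by :func:`save_scene` (or compatible tooling).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file has no geotransform tags, or the band count differs from
        ``expected_bands``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scene file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"file has no geotransform (geo tags missing): {path}")
        scale = tags[_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_MODEL_TIEPOINT].value
        desc = tags.get("ImageDescription")
        desc_value = desc.value if desc is not None else None
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    crs_label, nodata = "local-meters", None
    if desc_value is not None:
        try:
            meta = json.loads(desc_value)
            crs_label = meta.get("crs_label", crs_label)
            nodata = meta.get("nodata_value")
        except (json.JSONDecodeError, TypeError):
            pass
    px = float(scale[0])
    # tiepoint maps raster (i, j) to world (x, y); stored for raster origin (0, 0)
    i, j = float(tiepoint[0]), float(tiepoint[1])
    ox = float(tiepoint[3]) - i * px
    oy = float(tiepoint[4]) + j * px
    scene = Scene(data, px, (ox, oy), crs_label, nodata)
    if expected_bands is not None and scene.n_bands != expected_bands:
        raise ValueError(
            f"{path}: expected {expected_bands} bands, found {scene.n_bands}"
        )
    return scene


def build_grid(
    scene: Scene, patch_px: int = 336, include_partial: bool = True
) -> list[GridCell]:
    """Tile a scene into non-overlapping ``patch_px`` cells anchored at the
    scene's top-left corner.

    Cells on the right/bottom border that would extend past the scene are
    truncated and flagged ``full=False``; they are zero-padded at inference
    and excluded from training sampling.
    """
    if scene.height < patch_px or scene.width < patch_px:
        raise ValueError(
            f"scene ({scene.height}x{scene.width} px) smaller than one "
            f"{patch_px}-px patch"
        )
    cells = []
    n_rows = math.ceil(scene.height / patch_px)
    n_cols = math.ceil(scene.width / patch_px)
    for ri in range(n_rows):
        for ci in range(n_cols):
            r0, c0 = ri * patch_px, ci * patch_px
            h = min(patch_px, scene.height - r0)
            w = min(patch_px, scene.width - c0)
            full = h == patch_px and w == patch_px
            if not full and not include_partial:
                continue
            cells.append(GridCell(ri, ci, r0, c0, h, w, full))
    return cells


def extract_patch(scene: Scene, cell: GridCell, pad_to: int | None = None) -> Scene:
    """Extract the pixel window of ``cell`` as a sub-scene with its own
    geotransform. ``pad_to`` zero-pads partial border cells to a fixed size
    (the padding lies outside the scene and carries no labels)."""
    r0, c0, h, w = cell.pixel_window
    if r0 < 0 or c0 < 0 or r0 + h > scene.height or c0 + w > scene.width:
        raise ValueError(f"cell window {cell.pixel_window} outside scene bounds")
    patch = scene.bands[:, r0 : r0 + h, c0 : c0 + w]
    if pad_to is not None and (h < pad_to or w < pad_to):
        padded = np.zeros((scene.n_bands, pad_to, pad_to), dtype=scene.bands.dtype)
        padded[:, :h, :w] = patch
        patch = padded
    else:
        patch = patch.copy()
    ox, oy = scene.origin
    origin = (ox + c0 * scene.pixel_size, oy - r0 * scene.pixel_size)
    return Scene(patch, scene.pixel_size, origin, scene.crs_label, scene.nodata_value)


def normalize_image(
    bands: np.ndarray, bit_depth_max: float = DEFAULT_BIT_DEPTH_MAX
) -> np.ndarray:
    """Scale raw sensor counts to [0, 1] by the sensor bit-depth ceiling.

    A fixed global divisor (rather than per-image stretching) keeps training
    and inference radiometry consistent across scenes.
    """
    return np.asarray(bands, dtype=np.float32) / float(bit_depth_max)


def grid_to_geojson(cells: Iterable[GridCell], scene: Scene, path: str | Path) -> None:
    """Export grid cells as GeoJSON polygons for visual inspection."""
    ox, oy = scene.origin
    ps = scene.pixel_size
    features = []
    for cell in cells:
        r0, c0, h, w = cell.pixel_window
        x0, y0 = ox + c0 * ps, oy - r0 * ps
        x1, y1 = x0 + w * ps, y0 - h * ps
        ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "row_index": cell.row_index,
                    "col_index": cell.col_index,
                    "full": cell.full,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
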