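"""Seeded synthetic satellite-like scenes with ground-truth animal points.

The generator emulates the imaging conditions of sub-meter multispectral
wildlife surveys: 11-bit 4-band (R, G, B, NIR) radiometry, a low-frequency
savanna background texture, animals rendered as 3-4 pixel long, 1-3 pixel
wide dark blobs with 1-2 darker center pixels, herd aggregation that is
scattered, linear (trail-following) or clustered (parent-offspring Thomas
process), and confuser objects — small bushes, termite-mound shadows, roads
and riverbank shadows — that share the animals' tone but differ in size,
shape or spectrum.

Every pipeline stage is testable against these scenes without proprietary
imagery; what they deliberately do not model (sensor PSF, atmospheric
effects, photorealistic texture) is documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from wildcount.scene import Scene, PointSet, DEFAULT_BIT_DEPTH_MAX


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    width_px: int = 336
    height_px: int = 336
    pixel_size: float = 0.5
    n_animals: int = 60
    aggregation: str = "scattered"  # scattered | linear | clustered
    cluster_parents: int = 5
    cluster_spread: float = 10.0  # meters, offspring dispersion around parents
    animal_length_px: tuple = (3, 4)
    animal_width_px: tuple = (1, 3)
    dark_center_px: tuple = (1, 2)
    contrast: float = 0.45  # relative intensity drop of animal vs background
    confusers: dict = field(
        default_factory=lambda: {"bush": 3, "mound_shadow": 3, "road": 1, "river": 0}
    )
    background_texture_scale: float = 4.0  # meters
    min_separation_px: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")
        if self.aggregation not in ("scattered", "linear", "clustered"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        lo, hi = self.animal_length_px
        if not (3 <= lo <= hi <= 4):
            raise ValueError("animal length must stay within 3-4 pixels")
        lo, hi = self.animal_width_px
        if not (1 <= lo <= hi <= 3):
            raise ValueError("animal width must stay within 1-3 pixels")
        lo, hi = self.dark_center_px
        if not (1 <= lo <= hi <= 2):
            raise ValueError("dark center must stay within 1-2 pixels")


# per-band base reflectance levels of the dry-savanna background (11-bit)
_BAND_BASE = np.array([680.0, 640.0, 560.0, 900.0])
_MARGIN = 3  # px; keeps animal stamps inside the raster


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency textured background, (4, H, W) float."""
    h, w = spec.height_px, spec.width_px
    sigma = max(spec.background_texture_scale / spec.pixel_size, 1.0)
    coarse = gaussian_filter(rng.standard_normal((h, w)), sigma)
    coarse /= max(np.abs(coarse).max(), 1e-9)
    fine = rng.normal(0.0, 12.0, size=(h, w))
    bands = np.empty((4, h, w))
    for b in range(4):
        bands[b] = _BAND_BASE[b] * (1.0 + 0.06 * coarse) + fine
    return bands


def _place_points(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Animal center pixels (n, 2) of (row, col), respecting min separation."""
    n = spec.n_animals
    if n == 0:
        return np.empty((0, 2), dtype=int)
    h, w = spec.height_px, spec.width_px
    lo_r, hi_r = _MARGIN, h - _MARGIN
    lo_c, hi_c = _MARGIN, w - _MARGIN
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("scene too small to place animals")

    def propose() -> tuple[float, float]:
        if spec.aggregation == "scattered":
            return rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)
        if spec.aggregation == "clustered":
            pr, pc = parents[rng.integers(len(parents))]
            s = spec.cluster_spread / spec.pixel_size
            return pr + rng.normal(0, s), pc + rng.normal(0, s)
        # linear: jittered positions along a random polyline
        t = rng.uniform(0.0, 1.0)
        base = start + t * (end - start)
        jitter = rng.normal(0, 2.0, size=2)
        return base[0] + jitter[0], base[1] + jitter[1]

    if spec.aggregation == "clustered":
        k = max(1, spec.cluster_parents)
        parents = np.column_stack(
            [rng.uniform(lo_r, hi_r, size=k), rng.uniform(lo_c, hi_c, size=k)]
        )
    elif spec.aggregation == "linear":
        start = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
        angle = rng.uniform(0, 2 * math.pi)
        length = 0.8 * min(h, w)
        end = start + length * np.array([math.sin(angle), math.cos(angle)])
        end[0] = np.clip(end[0], lo_r, hi_r - 1)
        end[1] = np.clip(end[1], lo_c, hi_c - 1)

    placed: list[tuple[int, int]] = []
    max_tries = 400 * n
    tries = 0
    min_sep = spec.min_separation_px
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} animals with min separation "
                f"{min_sep} px in a {h}x{w} scene (aggregation="
                f"{spec.aggregation!r})"
            )
        r, c = propose()
        ri, ci = int(round(r)), int(round(c))
        if not (lo_r <= ri < hi_r and lo_c <= ci < hi_c):
            continue
        if any((ri - pr) ** 2 + (ci - pc) ** 2 < min_sep**2 for pr, pc in placed):
            continue
        placed.append((ri, ci))
    return np.asarray(placed, dtype=int)


def _stamp_animal(
    bands: np.ndarray, r: int, c: int, spec: SceneSpec, rng: np.random.Generator
) -> None:
    """Render one animal: a rotated dark ellipse with darker center pixels."""
    length = rng.integers(spec.animal_length_px[0], spec.animal_length_px[1] + 1)
    width = rng.integers(spec.animal_width_px[0], spec.animal_width_px[1] + 1)
    n_dark = rng.integers(spec.dark_center_px[0], spec.dark_center_px[1] + 1)
    theta = rng.uniform(0, math.pi)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    a, b = length / 2.0, max(width / 2.0, 0.5)
    body = [(0, 0)]
    for dr in range(-2, 3):
        for dc in range(-2, 3):
            if dr == 0 and dc == 0:
                continue
            u = dc * cos_t + dr * sin_t
            v = -dc * sin_t + dr * cos_t
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                body.append((dr, dc))
    drop = 1.0 - spec.contrast
    for dr, dc in body:
        bands[:, r + dr, c + dc] *= drop
    # darker neck/spine pixels: the center and, if asked, one along the axis
    centers = [(0, 0)]
    if n_dark == 2:
        step = (round(sin_t), round(cos_t))
        if step != (0, 0) and (step[0], step[1]) in body:
            centers.append(step)
        else:
            centers.append(body[1] if len(body) > 1 else (0, 0))
    for dr, dc in centers:
        bands[:, r + dr, c + dc] *= 0.6


def _stamp_confusers(
    bands: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> None:
    h, w = spec.height_px, spec.width_px
    counts = spec.confusers or {}
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(int(counts.get("bush", 0))):
        r, c = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        radius = rng.uniform(2.5, 4.0)
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
        bands[:3, disk] *= 0.75  # dark canopy in the visible bands
        bands[3, disk] *= 1.35  # vegetation is NIR-bright
    for _ in range(int(counts.get("mound_shadow", 0))):
        r, c = rng.uniform(8, h - 8), rng.uniform(8, w - 8)
        theta = rng.uniform(0, math.pi)
        a = rng.uniform(4.0, 7.0)  # half-length: clearly larger than an animal
        b = rng.uniform(1.5, 2.5)
        u = (xx - c) * math.cos(theta) + (yy - r) * math.sin(theta)
        v = -(xx - c) * math.sin(theta) + (yy - r) * math.cos(theta)
        ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        bands[:, ell] *= 0.55
    for _ in range(int(counts.get("road", 0))):
        # bright track crossing the scene
        r0, r1 = rng.uniform(0, h, size=2)
        t = np.linspace(0, 1, 4 * max(h, w))
        rr = r0 + t * (r1 - r0)
        cc = t * (w - 1)
        for dr in (-1, 0, 1):
            ri = np.clip(np.round(rr + dr).astype(int), 0, h - 1)
            ci = np.round(cc).astype(int)
            bands[:, ri, ci] *= 1.22
    for _ in range(int(counts.get("river", 0))):
        # dark wavy band with a shadowed bank
        c0 = rng.uniform(0.2 * w, 0.8 * w)
        amp = rng.uniform(5, 15)
        period = rng.uniform(0.5 * h, 1.5 * h)
        rr = np.arange(h)
        cc = c0 + amp * np.sin(2 * math.pi * rr / period)
        for dc in range(-2, 3):
            ci = np.clip(np.round(cc + dc).astype(int), 0, w - 1)
            bands[:, rr, ci] *= 0.6


def generate_scene(spec: SceneSpec) -> tuple[Scene, PointSet]:
    """Generate one synthetic scene and its ground-truth animal points.

    Deterministic for a fixed spec (bit-identical rasters and points).
    Raises if the requested animals cannot be placed at the configured
    minimum separation.
    """
    rng_scene = np.random.default_rng(spec.seed)
    rng_animals = np.random.default_rng(spec.seed + 1_000_003)
    bands = _background(spec, rng_scene)
    _stamp_confusers(bands, spec, rng_scene)
    centers = _place_points(spec, rng_animals)
    for r, c in centers:
        _stamp_animal(bands, r, c, spec, rng_animals)
    bands = np.clip(bands, 0, DEFAULT_BIT_DEPTH_MAX).astype(np.uint16)
    scene = Scene(
        bands,
        spec.pixel_size,
        origin=(0.0, spec.height_px * spec.pixel_size),
        crs_label="synthetic-meters",
    )
    if len(centers):
        x, y = scene.pixel_to_world(centers[:, 0], centers[:, 1])
        pts = np.column_stack([x, y])
    else:
        pts = np.empty((0, 2))
    return scene, PointSet(pts, source_tag="ground_truth")


def generate_reference_pair(spec: SceneSpec) -> tuple[Scene, Scene]:
    """Two scenes sharing background and confusers; animals only in the first.

    Emulates the cross-referencing workflow in which a second acquisition of
    the same landscape disambiguates moving animals from static look-alike
    objects: differencing the pair highlights only animal locations.
    """
    scene_a, _ = generate_scene(spec)
    rng_scene = np.random.default_rng(spec.seed)
    bands = _background(spec, rng_scene)
    _stamp_confusers(bands, spec, rng_scene)
    bands = np.clip(bands, 0, DEFAULT_BIT_DEPTH_MAX).astype(np.uint16)
    scene_b = Scene(
        bands,
        spec.pixel_size,
        origin=(0.0, spec.height_px * spec.pixel_size),
        crs_label="synthetic-meters",
    )
    return scene_a, scene_b


def generate_oracle_probmap(
    ground_truth: PointSet,
    scene: Scene,
    noise_level: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """A 'perfect segmentation' probability map from ground-truth points.

    Each ground-truth point contributes a 3x3 block of probability 0.95 at
    its pixel; uniform background noise in [0, noise_level) is added and the
    map clipped to [0, 1]. Substituting this map for the network isolates
    the post-processing chain (threshold, label, split, match) from
    learning.
    """
    if not 0 <= noise_level < 0.5:
        raise ValueError("noise_level must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    h, w = scene.height, scene.width
    prob = np.zeros((h, w), dtype=np.float32)
    if noise_level > 0:
        prob += rng.uniform(0, noise_level, size=(h, w)).astype(np.float32)
    for x, y in ground_truth.points:
        row, col = scene.world_to_pixel(x, y)
        row, col = int(row), int(col)
        if not (0 <= row < h and 0 <= col < w):
            continue
        r0, r1 = max(0, row - 1), min(h, row + 2)
        c0, c1 = max(0, col - 1), min(w, col + 2)
        prob[r0:r1, c0:c1] = 0.95
    return np.clip(prob, 0.0, 1.0)
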