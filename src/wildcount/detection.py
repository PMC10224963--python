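"""From fused probability maps to individual-animal points and counts.

The fused map is thresholded at 0.5; connected positive segments are split
into individuals by K-means on pixel coordinates, with the cluster count set
by ceiling division of the segment size by the typical animal footprint
(9 pixels at 0.38-0.50 m resolution). Cluster centroids become the detected
points. Per-scene counts over repeated training runs carry a t-based 95%
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import stats
from skimage import measure
from sklearn.cluster import MiniBatchKMeans

from wildcount.scene import Scene, PointSet, build_grid, extract_patch, normalize_image
from wildcount.scene import DEFAULT_BIT_DEPTH_MAX


@dataclass
class DetectConfig:
    prob_threshold: float = 0.5
    connectivity: int = 8
    object_size_px: int = 9
    kmeans_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.object_size_px < 1:
            raise ValueError("object_size_px must be >= 1")


@dataclass
class Segment:
    """A connected component of positive pixels."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    id: int


@dataclass
class CountEstimate:
    mean_count: float
    half_width_95: float
    n_runs: int


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties at the threshold count as positive."""
    return (np.asarray(p) >= threshold).astype(np.uint8)


def label_segments(mask: np.ndarray, connectivity: int = 8) -> list[Segment]:
    """Maximal connected components of a binary mask (4- or 8-neighborhood)."""
    conn = 2 if connectivity == 8 else 1
    labeled = measure.label(mask > 0, connectivity=conn)
    segments = []
    for region in measure.regionprops(labeled):
        segments.append(Segment(pixels=region.coords.copy(), id=region.label))
    return segments


def clusters_for_segment(n_pixels: int, object_size_px: int = 9) -> int:
    """Number of individuals in a segment: ceil(pixels / object footprint)."""
    if n_pixels < 1:
        raise ValueError("segment must be non-empty")
    return ceil(n_pixels / object_size_px)


def _kmeans_pp_init(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers by squared-distance weighting."""
    centers = np.empty((k, pts.shape[1]))
    centers[0] = pts[rng.integers(len(pts))]
    d2 = ((pts - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j:] = pts[rng.integers(len(pts), size=k - j)]
            break
        centers[j] = pts[rng.choice(len(pts), p=d2 / total)]
        d2 = np.minimum(d2, ((pts - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(pts: np.ndarray, k: int, seed: int, n_init: int,
           max_iter: int = 100) -> np.ndarray:
    """Best-of-restarts Lloyd's k-means, vectorized for small point sets."""
    rng = np.random.default_rng(seed)
    best_inertia, best_centers = np.inf, None
    for _ in range(n_init):
        centers = _kmeans_pp_init(pts, k, rng)
        for _ in range(max_iter):
            d = ((pts[:, None, :] - centers[None]) ** 2).sum(axis=-1)
            assign = d.argmin(axis=1)
            new = centers.copy()
            for j in range(k):
                members = assign == j
                if members.any():
                    new[j] = pts[members].mean(axis=0)
                else:  # re-seed an empty cluster at the worst-served point
                    new[j] = pts[d.min(axis=1).argmax()]
            if np.allclose(new, centers):
                break
            centers = new
        inertia = ((pts - centers[assign]) ** 2).sum()
        if inertia < best_inertia:
            best_inertia, best_centers = inertia, centers
    return best_centers


def split_segment(seg: Segment, k: int, seed: int = 0) -> np.ndarray:
    """K-means split of a segment's pixels into ``k`` cluster centroids.

    Returns a (k, 2) array of (row, col) centroids in pixel coordinates
    (fractional; a pixel's own coordinate marks its center in index space).
    Seeded k-means++ with 10 restarts keeps the result deterministic and
    robust on the tiny point sets that real animal segments produce; very
    large segments (only seen with degenerate thresholds that flood the
    probability map) fall back to a scalable mini-batch solver.
    """
    pts = np.asarray(seg.pixels, dtype=float)
    if k > len(pts):
        raise ValueError(f"cannot split {len(pts)} pixels into {k} clusters")
    if k == 1:
        return pts.mean(axis=0, keepdims=True)
    if len(pts) <= 400:
        centers = _lloyd(pts, k, seed, n_init=10)
    else:
        km = MiniBatchKMeans(n_clusters=k, n_init=1, random_state=seed,
                             batch_size=1024).fit(pts)
        centers = km.cluster_centers_
    # stable output order: sort centroids by (row, col)
    return centers[np.lexsort((centers[:, 1], centers[:, 0]))]


def detect_from_probmap(
    probmap: np.ndarray, scene: Scene, config: DetectConfig | None = None
) -> PointSet:
    """Post-process a fused probability map into animal points (world coords).

    Each detected point carries the mean fused probability of its segment's
    pixels as a score.
    """
    config = config or DetectConfig()
    mask = binarize(probmap, config.prob_threshold)
    segments = label_segments(mask, config.connectivity)
    pts, scores = [], []
    for seg in segments:
        k = clusters_for_segment(len(seg.pixels), config.object_size_px)
        centers = split_segment(seg, k, seed=config.kmeans_seed)
        score = float(probmap[seg.pixels[:, 0], seg.pixels[:, 1]].mean())
        for row, col in centers:
            x, y = scene.pixel_to_world(row, col)
            pts.append((float(x), float(y)))
            scores.append(score)
    if not pts:
        return PointSet(np.empty((0, 2)), None, "prediction")
    return PointSet(np.asarray(pts), np.asarray(scores), "prediction")


def predict_scene_probmap(
    scene: Scene,
    predictor,
    patch_px: int = 336,
    bit_depth_max: float = DEFAULT_BIT_DEPTH_MAX,
) -> np.ndarray:
    """Tile a scene (overlap-free), run the fused predictor on each tile, and
    stitch the full-scene probability map.

    ``predictor`` maps a normalized (bands, patch_px, patch_px) array to a
    (patch_px, patch_px) probability map — typically an
    :class:`~wildcount.ensemble.EnsemblePredictor`. Border tiles are
    zero-padded for inference and cropped back. Objects straddling a tile
    seam are predicted independently on each side; after stitching they
    usually reconnect, but seam splitting into two points is possible.
    """
    probmap = np.zeros((scene.height, scene.width), dtype=np.float32)
    for cell in build_grid(scene, patch_px):
        patch = extract_patch(scene, cell, pad_to=patch_px)
        image = normalize_image(patch.bands, bit_depth_max)
        tile_map = predictor(image)
        r0, c0, h, w = cell.pixel_window
        probmap[r0 : r0 + h, c0 : c0 + w] = tile_map[:h, :w]
    return probmap


def detect_scene(
    scene: Scene,
    predictor,
    config: DetectConfig | None = None,
    patch_px: int = 336,
    bit_depth_max: float = DEFAULT_BIT_DEPTH_MAX,
) -> PointSet:
    """Full detection pass: tile, predict, fuse, post-process to points."""
    probmap = predict_scene_probmap(scene, predictor, patch_px, bit_depth_max)
    return detect_from_probmap(probmap, scene, config)


def count_with_ci(counts: list[float], use_t: bool = True) -> CountEstimate:
    """Mean count over repeated runs with a 95% confidence half-width.

    Uses the t-distribution (appropriate for the small n=5 of repeated
    trainings); ``use_t=False`` switches to the normal approximation.
    """
    counts_arr = np.asarray(counts, dtype=float)
    n = counts_arr.size
    if n < 2:
        raise ValueError("at least 2 per-run counts are required")
    sd = counts_arr.std(ddof=1)
    crit = stats.t.ppf(0.975, n - 1) if use_t else stats.norm.ppf(0.975)
    return CountEstimate(
        mean_count=float(counts_arr.mean()),
        half_width_95=float(crit * sd / np.sqrt(n)),
        n_runs=int(n),
    )
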