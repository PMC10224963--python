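"""Label fusion, mask rasterization, augmentation, fold splits and strata.

Point annotations from several observers are fused by majority voting into a
consensus set; consensus points are expanded to 3x3-pixel blocks to form the
binary training masks (an animal occupies at most ~9 pixels at 0.38-0.50 m
resolution, so the block covers most of its footprint).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from wildcount.scene import PointSet, Scene

logger = logging.getLogger(__name__)

STRATUM_LABELS = ("low", "medium", "high", "very_high")


@dataclass
class PatchPair:
    """An image patch and its aligned binary mask; the training unit."""

    image: np.ndarray  # (bands, H, W) float32 in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    patch_id: str = ""
    group: str = ""  # e.g. acquisition year, for transfer protocols

    def __post_init__(self) -> None:
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} misaligned"
            )


def fuse_annotations(
    observer_sets: list[PointSet],
    radius: float,
    min_votes: int | None = None,
) -> PointSet:
    """Fuse multi-observer point labels by majority voting.

    Points from all observers are greedily agglomerated into clusters of
    diameter <= ``radius`` (complete linkage), seeded from the densest
    neighborhoods; a cluster takes at most one point per observer. Clusters
    marked by at least ``min_votes`` observers (default: strict majority,
    ``floor(n/2) + 1``) yield one consensus point at the cluster's coordinate
    mean. Seeding and tie-breaks depend only on coordinates, so the result is
    invariant to observer order.
    """
    n_obs = len(observer_sets)
    if n_obs < 2:
        raise ValueError("at least 2 observer sets are required")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if min_votes is None:
        min_votes = n_obs // 2 + 1
    if min_votes > n_obs:
        raise ValueError(f"min_votes={min_votes} exceeds {n_obs} observers")

    coords, owner = [], []
    for oi, ps in enumerate(observer_sets):
        for p in ps.points:
            coords.append(p)
            owner.append(oi)
    if not coords:
        return PointSet(np.empty((0, 2)), source_tag="consensus")
    coords_arr = np.asarray(coords, dtype=float)
    owner_arr = np.asarray(owner)
    n = len(coords_arr)
    tree = cKDTree(coords_arr)
    neighbor_lists = tree.query_ball_point(coords_arr, r=radius)
    unassigned = np.ones(n, dtype=bool)

    # deterministic seed order: densest neighborhood first, then coordinates
    def seed_key(i: int) -> tuple:
        return (-len(neighbor_lists[i]), coords_arr[i, 0], coords_arr[i, 1])

    order = sorted(range(n), key=seed_key)
    consensus = []
    for seed in order:
        if not unassigned[seed]:
            continue
        cand = [j for j in neighbor_lists[seed] if unassigned[j]]
        cand.sort(
            key=lambda j: (
                np.hypot(*(coords_arr[j] - coords_arr[seed])),
                coords_arr[j, 0],
                coords_arr[j, 1],
            )
        )
        members: list[int] = []
        used_obs: set[int] = set()
        for j in cand:
            if owner_arr[j] in used_obs:
                continue
            if all(
                np.hypot(*(coords_arr[j] - coords_arr[m])) <= radius for m in members
            ):
                members.append(j)
                used_obs.add(owner_arr[j])
        for m in members:
            unassigned[m] = False
        if len(used_obs) >= min_votes:
            consensus.append(coords_arr[members].mean(axis=0))
    pts = np.asarray(consensus, dtype=float).reshape(-1, 2)
    return PointSet(pts, source_tag="consensus")


def rasterize_points(
    points: PointSet, patch: Scene, size: int = 3, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Rasterize points into a binary mask: each in-patch point sets the
    ``size x size`` block centered on its pixel to 1, clipped at the borders.
    Overlapping blocks merge (the mask stays binary). Out-of-patch points are
    ignored with a logged count."""
    if size % 2 != 1:
        raise ValueError("block size must be odd")
    h, w = shape if shape is not None else (patch.height, patch.width)
    mask = np.zeros((h, w), dtype=np.uint8)
    half = size // 2
    skipped = 0
    for x, y in points.points:
        row, col = patch.world_to_pixel(x, y)
        row, col = int(row), int(col)
        if row < 0 or col < 0 or row >= h or col >= w:
            skipped += 1
            continue
        r0, r1 = max(0, row - half), min(h, row + half + 1)
        c0, c1 = max(0, col - half), min(w, col + half + 1)
        mask[r0:r1, c0:c1] = 1
    if skipped:
        logger.info("rasterize_points: %d point(s) outside patch ignored", skipped)
    return mask


def augment(pair: PatchPair) -> list[PatchPair]:
    """Return [identity, horizontal flip, vertical flip, 90-degree rotation],
    with image and mask transformed identically."""
    img, msk = pair.image, pair.mask
    variants = [
        (img, msk, "id"),
        (img[:, :, ::-1], msk[:, ::-1], "hflip"),
        (img[:, ::-1, :], msk[::-1, :], "vflip"),
        (np.rot90(img, axes=(1, 2)), np.rot90(msk), "rot90"),
    ]
    return [
        PatchPair(np.ascontiguousarray(i), np.ascontiguousarray(m),
                  f"{pair.patch_id}:{tag}", pair.group)
        for i, m, tag in variants
    ]


def split_folds(patch_ids: list, K: int = 10, seed: int = 0) -> dict:
    """Seeded balanced partition of patch ids into K folds (sizes differ by
    at most one). Returns a mapping patch id -> fold index."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if len(patch_ids) < K:
        raise ValueError(f"{len(patch_ids)} patches cannot fill K={K} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patch_ids))
    folds = {}
    for pos, idx in enumerate(order):
        folds[patch_ids[idx]] = pos % K
    return folds


@dataclass
class DensityStratum:
    label: str
    lower: float
    upper: float  # half-open [lower, upper)


def density_strata(density_per_cell: dict) -> list[DensityStratum]:
    """Breakpoints for the four density categories from the per-cell count
    distribution: low = [0, mu), medium = [mu, mu+sigma), high =
    [mu+sigma, mu+2*sigma), very_high = [mu+2*sigma, inf)."""
    counts = np.asarray(list(density_per_cell.values()), dtype=float)
    if counts.size == 0:
        raise ValueError("at least one cell is required")
    mu, sigma = counts.mean(), counts.std()
    return [
        DensityStratum("low", 0.0, mu),
        DensityStratum("medium", mu, mu + sigma),
        DensityStratum("high", mu + sigma, mu + 2 * sigma),
        DensityStratum("very_high", mu + 2 * sigma, math.inf),
    ]


def stratify_cells(density_per_cell: dict) -> dict:
    """Assign each cell one of four density categories based on the mean and
    standard deviation of per-cell animal counts. With zero spread every cell
    is assigned ``medium`` (degenerate but deterministic)."""
    strata = density_strata(density_per_cell)
    counts = np.asarray(list(density_per_cell.values()), dtype=float)
    sigma = counts.std()
    out = {}
    for cell, count in density_per_cell.items():
        if sigma == 0:
            out[cell] = "medium"
            continue
        for s in strata:
            if s.lower <= count < s.upper:
                out[cell] = s.label
                break
    return out


def sample_stratified(
    strata_of_cell: dict, n_samples: int, seed: int = 0
) -> list:
    """Proportionate stratified random sample of cells: each stratum
    contributes in proportion to its size (deviation <= 1 cell, largest
    remainders rounded up)."""
    rng = np.random.default_rng(seed)
    by_stratum: dict[str, list] = {}
    for cell, label in strata_of_cell.items():
        by_stratum.setdefault(label, []).append(cell)
    total = len(strata_of_cell)
    if n_samples > total:
        raise ValueError("cannot sample more cells than exist")
    labels = sorted(by_stratum)
    exact = {lab: n_samples * len(by_stratum[lab]) / total for lab in labels}
    take = {lab: int(math.floor(exact[lab])) for lab in labels}
    remainder = n_samples - sum(take.values())
    for lab in sorted(labels, key=lambda L: exact[L] - take[L], reverse=True):
        if remainder <= 0:
            break
        if take[lab] < len(by_stratum[lab]):
            take[lab] += 1
            remainder -= 1
    sampled = []
    for lab in labels:
        cells = sorted(by_stratum[lab], key=str)
        idx = rng.choice(len(cells), size=min(take[lab], len(cells)), replace=False)
        sampled.extend(cells[i] for i in sorted(idx))
    return sampled
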