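"""Point-based detection evaluation: radius matching, P/R/F1, PR curves.

Detections are scored per individual, not per pixel: a predicted point is a
true positive when it can be paired one-to-one with a reference point within
a small search radius — the diagonal of one pixel (0.71 m at 0.5 m
resolution), which tolerates the one-pixel shifts that survive centroid
extraction. Unmatched predictions are false positives, unmatched references
false negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from wildcount.scene import Scene, PointSet
from wildcount.detection import DetectConfig, detect_from_probmap


@dataclass
class EvalConfig:
    radius: float
    thresholds: tuple = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        th = np.asarray(self.thresholds, dtype=float)
        if th.size and not (np.diff(th) > 0).all():
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class MatchResult:
    """Partition of predictions and references into TP pairs, FP and FN."""

    tp_pairs: list  # list of (pred_index, ref_index)
    fp: list  # unmatched prediction indices
    fn: list  # unmatched reference indices

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float


@dataclass
class PRCurve:
    points: list  # (recall, precision) pairs, sorted by recall, with endpoints
    auc: float


def matching_radius(pixel_size: float) -> float:
    """Search radius for point matching: the diagonal of one pixel.

    Returns the full-precision value (sqrt(2) * pixel_size); display
    rounding to 2 decimals (0.71 m for 0.5 m pixels) is left to reporting.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return math.sqrt(2.0) * pixel_size


def match_points(pred: PointSet, ref: PointSet, radius: float) -> MatchResult:
    """One-to-one matching of predictions to references within ``radius``.

    Candidate pairs within the radius are processed globally in order of
    increasing distance (stable index tie-break) and accepted greedily while
    both endpoints are unmatched — closest pairs first, deterministic and
    independent of input ordering. Distances equal to the radius count as
    matches.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n_pred, n_ref = len(pred), len(ref)
    if n_pred == 0 or n_ref == 0:
        return MatchResult([], list(range(n_pred)), list(range(n_ref)))
    pred_tree = cKDTree(pred.points)
    ref_tree = cKDTree(ref.points)
    pairs = pred_tree.query_ball_tree(ref_tree, r=radius)
    candidates = []
    for pi, refs in enumerate(pairs):
        for ri in refs:
            d = float(np.hypot(*(pred.points[pi] - ref.points[ri])))
            candidates.append((d, pi, ri))
    candidates.sort()
    pred_used = np.zeros(n_pred, dtype=bool)
    ref_used = np.zeros(n_ref, dtype=bool)
    tp_pairs = []
    for _, pi, ri in candidates:
        if not pred_used[pi] and not ref_used[ri]:
            tp_pairs.append((pi, ri))
            pred_used[pi] = True
            ref_used[ri] = True
    fp = [i for i in range(n_pred) if not pred_used[i]]
    fn = [i for i in range(n_ref) if not ref_used[i]]
    return MatchResult(tp_pairs, fp, fn)


def compute_metrics(m: MatchResult) -> Metrics:
    """Precision, recall and F1 from a match partition (0/0 -> 0)."""
    tp, fp, fn = m.tp, len(m.fp), len(m.fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return Metrics(precision, recall, f1_score(precision, recall))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def trapezoid_auc(points: list) -> float:
    """Composite-trapezoid area under (recall, precision) points.

    Points are sorted by recall; ties keep the higher precision first, which
    follows threshold order (a higher threshold yields the same recall only
    with at least the precision of a lower one), so vertical segments
    contribute zero width rather than corrupting the sweep order.
    """
    pts = sorted(points, key=lambda p: (p[0], -p[1]))
    recalls = np.asarray([p[0] for p in pts], dtype=float)
    precisions = np.asarray([p[1] for p in pts], dtype=float)
    return float(np.trapezoid(precisions, recalls))


def pr_curve(
    tiles: list,
    radius: float,
    thresholds=None,
    dconfig: DetectConfig | None = None,
) -> PRCurve:
    """Precision-recall curve over detection thresholds.

    ``tiles`` is a list of ``(probmap, scene, reference PointSet)`` triples.
    For every threshold the full post-processing chain (binarize, label,
    K-means split) runs on each tile, matches are pooled over tiles, and one
    (recall, precision) pair is recorded. The conventional endpoints (0, 1)
    for threshold 1 and (1, 0) for threshold 0 are appended, and the AUC is
    the composite-trapezoid area over recall-sorted points.
    """
    dconfig = dconfig or DetectConfig()
    if thresholds is None:
        thresholds = EvalConfig(radius=radius).thresholds
    if len(thresholds) < 1:
        raise ValueError("at least one threshold is required")
    curve = []
    for th in thresholds:
        cfg = DetectConfig(
            prob_threshold=float(th),
            connectivity=dconfig.connectivity,
            object_size_px=dconfig.object_size_px,
            kmeans_seed=dconfig.kmeans_seed,
        )
        tp = fp = fn = 0
        for probmap, scene, ref in tiles:
            pred = detect_from_probmap(probmap, scene, cfg)
            m = match_points(pred, ref, radius)
            tp += m.tp
            fp += len(m.fp)
            fn += len(m.fn)
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        curve.append((recall, precision))
    curve.extend([(0.0, 1.0), (1.0, 0.0)])
    pts = sorted(set(curve), key=lambda p: (p[0], -p[1]))
    return PRCurve(points=pts, auc=trapezoid_auc(pts))


def transfer_protocol(hold_out_group: str, groups: dict) -> tuple[list, list]:
    """Leave-one-group-out split for transferability experiments.

    ``groups`` maps patch id -> group label (e.g. acquisition year). Returns
    ``(train_ids, test_ids)``: every patch of the held-out group is excluded
    from training (and hence from any fold split built on ``train_ids``),
    and evaluation is restricted to the held-out patches.
    """
    labels = set(groups.values())
    if hold_out_group not in labels:
        raise ValueError(f"hold-out group {hold_out_group!r} not in {sorted(labels)}")
    train_ids = [pid for pid, g in groups.items() if g != hold_out_group]
    test_ids = [pid for pid, g in groups.items() if g == hold_out_group]
    return train_ids, test_ids


def match_to_geojson(
    pred: PointSet, ref: PointSet, m: MatchResult, path
) -> None:
    """Export a match partition as GeoJSON points with a TP/FP/FN status."""
    import json
    from pathlib import Path

    features = []

    def feat(x, y, status):
        return {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"status": status},
        }

    for pi, _ in m.tp_pairs:
        features.append(feat(pred.x[pi], pred.y[pi], "TP"))
    for pi in m.fp:
        features.append(feat(pred.x[pi], pred.y[pi], "FP"))
    for ri in m.fn:
        features.append(feat(ref.x[ri], ref.y[ri], "FN"))
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
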