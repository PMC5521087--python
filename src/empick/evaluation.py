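"""Precision/recall accounting against ground truth and F-beta threshold
selection.

Picked coordinates are matched one-to-one to ground-truth coordinates within
a pixel tolerance; precision = TP/(TP+FP) and recall = TP/(TP+FN) are then
traced over a threshold grid, and the picking cutoff is defined at the
maximum of the F2 score, which weights recall above precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import NetworkState
from .recognition import Candidate, pick, scan_micrograph

__all__ = [
    "MatchResult",
    "PRCurve",
    "match_candidates",
    "precision_recall",
    "f_beta",
    "pr_curve",
    "select_threshold",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    threshold: float = float("nan")
    match_tolerance: float = float("nan")


@dataclass
class PRCurve:
    """Threshold-indexed points (threshold, precision, recall, f_beta)."""

    points: list[tuple[float, float, float, float]]
    beta: float = 2.0

    def thresholds(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    def recalls(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    def precisions(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def f_scores(self) -> np.ndarray:
        return np.array([p[3] for p in self.points])


def _greedy_assign(picked: Sequence[Candidate],
                   truth: Sequence[tuple[float, float]],
                   tolerance: float) -> tuple[list[int], list[bool]]:
    """Greedy one-to-one assignment: picks in descending score order each
    claim the nearest unclaimed truth within tolerance (lower-index truth
    wins an exact distance tie).  Returns (per-pick truth index or -1,
    per-truth claimed flags)."""
    truth_pts = [np.asarray(t, dtype=float) for t in truth]
    claimed = [False] * len(truth_pts)
    assignment = [-1] * len(picked)
    order = sorted(range(len(picked)), key=lambda i: -picked[i].score)
    for i in order:
        p = np.array([picked[i].x, picked[i].y], dtype=float)
        best, best_d = -1, float("inf")
        for j, t in enumerate(truth_pts):
            if claimed[j]:
                continue
            d = float(np.hypot(*(p - t)))
            if d <= tolerance and d < best_d:
                best, best_d = j, d
        if best >= 0:
            claimed[best] = True
            assignment[i] = best
    return assignment, claimed


def match_candidates(picked: Sequence[Candidate],
                     truth: Sequence[tuple[float, float]],
                     tolerance: float) -> MatchResult:
    """Greedy one-to-one matching of picks to ground-truth coordinates.

    Candidates are visited in descending score order; each claims the nearest
    unclaimed truth coordinate within the Euclidean tolerance (lower-index
    truth wins an exact distance tie).  Unmatched picks count as false
    positives, unmatched truths as false negatives.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    assignment, _ = _greedy_assign(picked, truth, tolerance)
    tp = sum(1 for j in assignment if j >= 0)
    return MatchResult(tp=tp, fp=len(picked) - tp, fn=len(truth) - tp,
                       match_tolerance=tolerance)


def refresh_additions(micrograph: np.ndarray, picked: Sequence[Candidate],
                      truth: Sequence[tuple[float, float]], box_side: int,
                      tolerance: float, micrograph_id: str = "refine"):
    """Verified training additions from one picked micrograph.

    Matches the picks against the ground truth and returns training samples
    for the next round: each false positive enters with target 0, each
    missed particle with target 1 (the synthetic ground truth plays the role
    of the manual verifier in the recursive training-set optimization).
    """
    from .training import BoxOrigin, TrainingSample

    m = np.asarray(micrograph, dtype=float)
    assignment, claimed = _greedy_assign(picked, truth, tolerance)
    additions = []
    for c, j in zip(picked, assignment):
        if j < 0:  # false positive
            additions.append(TrainingSample(
                box=m[c.y : c.y + box_side, c.x : c.x + box_side].copy(),
                target=0, origin=BoxOrigin(micrograph_id, c.x, c.y)))
    for j, (x, y) in enumerate(truth):
        if not claimed[j]:  # missed particle
            additions.append(TrainingSample(
                box=m[int(y) : int(y) + box_side,
                      int(x) : int(x) + box_side].copy(),
                target=1, origin=BoxOrigin(micrograph_id, int(x), int(y))))
    return additions


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); an empty denominator
    (nothing picked / nothing to find) counts as a perfect 1."""
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 1.0
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 1.0
    return float(precision), float(recall)


def f_beta(precision: float, recall: float, beta: float = 2.0) -> float:
    """Weighted harmonic combination of precision and recall,
    F_beta = (1 + beta^2) * P * R / (beta^2 * P + R); 0 when both are 0.
    beta = 2 (the default) weights recall above precision."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta * beta * precision + recall
    if denom == 0.0:
        return 0.0
    return float((1.0 + beta * beta) * precision * recall / denom)


def pr_curve(
    micrographs: Sequence[np.ndarray],
    truths: Sequence[Sequence[tuple[float, float]]],
    state: NetworkState,
    thresholds: Sequence[float] | None = None,
    beta: float = 2.0,
    tolerance: float | None = None,
    stride: int = 4,
    nms_radius: int | None = None,
    std_k: float | None = 2.0,
) -> PRCurve:
    """Precision-recall curve over a threshold grid.

    Runs the picker at every threshold on every micrograph, matches the
    picks to the ground truth, and aggregates TP/FP/FN over micrographs.
    Each micrograph is raster-scanned once (the score map does not depend on
    the threshold, so rescanning per threshold would change nothing), and the
    pixel-std acceptance band of each micrograph is fixed once, from its
    candidates at the lowest threshold evaluated.  This keeps the candidate
    sets nested as the threshold rises, so recall is monotone non-increasing
    by construction.

    thresholds default to 50 evenly spaced values in (0, 1); the match
    tolerance defaults to a quarter of the box side.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 52)[1:-1]
    thresholds = sorted(float(t) for t in thresholds)
    side = state.config.box_side
    if tolerance is None:
        tolerance = side / 4.0
    maps = [scan_micrograph(m, state, stride=stride) for m in micrographs]

    # per-micrograph absolute std band, frozen at the lowest threshold
    bands: list[tuple[float, float] | None] = []
    for m, smap in zip(micrographs, maps):
        if std_k is None:
            bands.append(None)
            continue
        base = pick(m, state, threshold=thresholds[0], stride=stride,
                    nms_radius=nms_radius, std_k=None, score_map=smap)
        if len(base) < 2:
            bands.append((-np.inf, np.inf))
        else:
            stds = np.array([c.pixel_std for c in base])
            bands.append((float(stds.mean() - std_k * stds.std()),
                          float(stds.mean() + std_k * stds.std())))

    points = []
    for thr in thresholds:
        tp = fp = fn = 0
        for m, smap, truth, band in zip(micrographs, maps, truths, bands):
            cands = pick(m, state, threshold=thr, stride=stride,
                         nms_radius=nms_radius, std_k=None, std_range=band,
                         score_map=smap)
            res = match_candidates(cands, truth, tolerance)
            tp, fp, fn = tp + res.tp, fp + res.fp, fn + res.fn
        p, r = precision_recall(MatchResult(tp, fp, fn))
        points.append((thr, p, r, f_beta(p, r, beta)))
    return PRCurve(points=points, beta=beta)


def select_threshold(curve: PRCurve) -> float:
    """The picking cutoff: the threshold with the highest F-beta value, ties
    broken toward the higher threshold (favoring precision at equal F2)."""
    if not curve.points:
        raise ValueError("empty precision-recall curve")
    best_thr, best_f = None, -1.0
    for thr, _, _, f in curve.points:
        if f >= best_f:
            best_thr, best_f = thr, f
    return float(best_thr)
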