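"""Raster-scan recognition: score maps, candidate selection, and filters.

A trained network is slid across the micrograph on a stride grid.  Each boxed
window is scored as the average network output over its four 90-degree
rotations, giving a score map.  Candidates are the grid positions whose score
clears the threshold and is the local maximum within a Chebyshev radius; a
final filter removes candidates whose pixel standard deviation falls outside
a narrow band around the micrograph's own candidate population (carbon edges
and contaminants sit well above or below clean ice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import network as net
from .network import NetworkState
from .training import _rotation_averaged_scores

__all__ = [
    "ScoreMap",
    "Candidate",
    "score_box",
    "scan_micrograph",
    "find_candidates",
    "filter_by_std",
    "pick",
    "bin_micrograph",
]


@dataclass
class ScoreMap:
    """Rotation-averaged scores on the raster grid.

    scores[r, c] belongs to the box whose top-left corner is at pixel
    (x, y) = (origin_offset[0] + c*stride, origin_offset[1] + r*stride).
    """

    scores: np.ndarray
    stride: int
    box_side: int
    origin_offset: tuple[int, int] = (0, 0)

    def position(self, r: int, c: int) -> tuple[int, int]:
        return (self.origin_offset[0] + c * self.stride,
                self.origin_offset[1] + r * self.stride)


@dataclass
class Candidate:
    """A picked box: top-left corner (x rightward, y downward, 0-based),
    its rotation-averaged score and the std of its raw pixel intensities."""

    x: int
    y: int
    score: float
    pixel_std: float = float("nan")


def score_box(box: np.ndarray, state: NetworkState) -> float:
    """Average network output over the four 90-degree rotations of the box."""
    box = np.asarray(box, dtype=float)
    if box.shape != (state.config.box_side,) * 2:
        raise ValueError(
            f"box must be {state.config.box_side} px square, got {box.shape}"
        )
    return float(_rotation_averaged_scores(box[None], state)[0])


def scan_micrograph(micrograph: np.ndarray, state: NetworkState,
                    stride: int = 4, chunk: int = 64) -> ScoreMap:
    """Score every stride-spaced box position, starting at the corner (0,0).

    Boxes are only placed fully inside the micrograph (no padding).  Windows
    are scored in batches; the result equals scoring each box with
    :func:`score_box` one at a time up to double-precision roundoff (batched
    FFTs accumulate in a different order).
    """
    if stride <= 0:
        raise net.ConfigurationError("stride must be positive")
    m = np.asarray(micrograph, dtype=float)
    side = state.config.box_side
    H, W = m.shape
    if H < side or W < side:
        raise ValueError("micrograph smaller than the box")
    n_rows = (H - side) // stride + 1
    n_cols = (W - side) // stride + 1
    scores = np.empty((n_rows, n_cols))
    windows = np.lib.stride_tricks.sliding_window_view(m, (side, side))
    for r in range(n_rows):
        row = windows[r * stride, ::stride][:n_cols]  # (n_cols, side, side)
        for lo in range(0, n_cols, chunk):
            b = np.ascontiguousarray(row[lo : lo + chunk])
            scores[r, lo : lo + b.shape[0]] = _rotation_averaged_scores(
                b, state, chunk=chunk)
    return ScoreMap(scores=scores, stride=stride, box_side=side)


def find_candidates(score_map: ScoreMap, threshold: float,
                    nms_radius: int) -> list[Candidate]:
    """Keep positions that clear the threshold and dominate their
    neighborhood.

    A position survives if its score is >= threshold and strictly greater
    than every neighbor within nms_radius (Chebyshev distance in micrograph
    pixels); on an exact score tie the earlier position in raster order
    (top-left first) wins and the later one is suppressed.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if nms_radius <= 0:
        raise ValueError("nms_radius must be positive")
    s = score_map.scores
    R = nms_radius // score_map.stride  # neighborhood radius in grid steps
    size = 2 * R + 1
    if R > 0:
        neighborhood_max = ndimage.maximum_filter(s, size=size, mode="constant",
                                                  cval=-np.inf)
    else:
        neighborhood_max = s
    rows, cols = np.nonzero((s >= threshold) & (s >= neighborhood_max))
    # resolve exact ties: raster-order first among equal local maxima
    kept: list[tuple[int, int]] = []
    out: list[Candidate] = []
    for r, c in zip(rows, cols):  # nonzero yields raster order
        suppressed = False
        for (kr, kc) in kept:
            if max(abs(kr - r), abs(kc - c)) <= R and s[kr, kc] >= s[r, c]:
                suppressed = True
                break
        if suppressed:
            continue
        kept.append((r, c))
        x, y = score_map.position(r, c)
        out.append(Candidate(x=x, y=y, score=float(s[r, c])))
    return out


def filter_by_std(candidates: list[Candidate], k: float = 2.0,
                  abs_range: tuple[float, float] | None = None) -> list[Candidate]:
    """Drop candidates whose box pixel-std lies outside a narrow band.

    The band is mean +/- k * std of the pixel_std values over this
    micrograph's own candidates, or an absolute [lo, hi] range if given.
    With fewer than two candidates the relative band is undefined and the
    filter is a no-op.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if abs_range is not None:
        lo, hi = abs_range
        return [c for c in candidates if lo <= c.pixel_std <= hi]
    if len(candidates) < 2:
        return list(candidates)
    stds = np.array([c.pixel_std for c in candidates])
    mu, sigma = stds.mean(), stds.std()
    return [c for c in candidates
            if mu - k * sigma <= c.pixel_std <= mu + k * sigma]


def _attach_pixel_std(candidates: list[Candidate], micrograph: np.ndarray,
                      box_side: int) -> None:
    m = np.asarray(micrograph, dtype=float)
    for c in candidates:
        c.pixel_std = float(m[c.y : c.y + box_side, c.x : c.x + box_side].std())


def pick(micrograph: np.ndarray, state: NetworkState, threshold: float,
         stride: int = 4, nms_radius: int | None = None,
         std_k: float | None = 2.0,
         std_range: tuple[float, float] | None = None,
         score_map: ScoreMap | None = None) -> list[Candidate]:
    """Full recognition pass: scan, threshold + local-maximum selection,
    pixel-std filter.  Deterministic given the inputs.

    nms_radius defaults to half the box side, so two accepted particles can
    overlap by at most half a box.  A precomputed score map for this
    micrograph/state/stride may be passed to avoid rescanning (the scan does
    not depend on the threshold).  Pass std_k=None to skip the std filter.
    """
    side = state.config.box_side
    if nms_radius is None:
        nms_radius = side // 2
    if score_map is None:
        score_map = scan_micrograph(micrograph, state, stride=stride)
    cands = find_candidates(score_map, threshold, nms_radius)
    _attach_pixel_std(cands, micrograph, side)
    if std_range is not None:
        cands = filter_by_std(cands, abs_range=std_range)
    elif std_k is not None:
        cands = filter_by_std(cands, k=std_k)
    return cands


def bin_micrograph(micrograph: np.ndarray, factor: int) -> np.ndarray:
    """Integer-factor binning: block-average factor x factor tiles, cropping
    trailing rows/columns that do not fill a tile."""
    if factor < 1:
        raise net.ConfigurationError("binning factor must be >= 1")
    m = np.asarray(micrograph, dtype=float)
    if factor == 1:
        return m.copy()
    H = (m.shape[0] // factor) * factor
    W = (m.shape[1] // factor) * factor
    m = m[:H, :W]
    return m.reshape(H // factor, factor, W // factor, factor).mean(axis=(1, 3))
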