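"""Tepal-overlap detection on a segmented flower.

Where two neighboring tepal margins cross, the flower silhouette has a
concave corner.  Corners are proposed by the Harris detector run on the
(smoothed) binary mask, then filtered by a chord rule: draw a circle of
fixed radius around the candidate, take its two intersections with the
mask contour, and sample the straight chord between them.  A chord lying
entirely over background marks a concave corner (an overlap point); a
chord entirely over foreground marks a convex false positive; mixed
chords are rejected conservatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import corner_harris, corner_peaks

from .errors import InvalidInputError
from .segmentation import SegmentedFlower

__all__ = [
    "CornerCandidate",
    "OverlapPoint",
    "Rejection",
    "DetectionEval",
    "detect_corners",
    "chord_endpoints",
    "classify_concavity",
    "detect_overlap_points",
    "overlap_f1",
]


@dataclass(frozen=True)
class CornerCandidate:
    """A Harris corner proposal, snapped onto the mask contour."""

    position: tuple[float, float]  # (x, y)
    response: float


@dataclass
class OverlapPoint:
    """An accepted concave corner where two tepal margins cross."""

    position: tuple[float, float]
    chord_endpoints: tuple[tuple[float, float], tuple[float, float]]
    label: str = "unknown"  # L | R | unknown
    confidence: float = 0.0
    corrected: bool = False
    response: float = 0.0


@dataclass(frozen=True)
class Rejection:
    """A candidate dismissed by the chord rule."""

    candidate: CornerCandidate
    reason: str  # "convex" | "mixed" | "no-chord"


@dataclass(frozen=True)
class DetectionEval:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


# Harris parameters tuned on binary-silhouette fixtures: pre-smoothing the
# mask suppresses the pixelation corners a rasterized boundary otherwise
# produces, and the absolute floor keeps smooth (disc-like) boundaries from
# yielding spurious peaks through the relative threshold alone.
_SMOOTH_SIGMA = 2.0
_HARRIS_SIGMA = 2.0
_HARRIS_K = 0.04
_THRESHOLD_ABS = 5e-3
_THRESHOLD_REL = 0.01
_NMS_RADIUS = 10


def _contour(mask: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of the mask as an ordered (N, 2) array of
    (x, y) points (sub-pixel)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise InvalidInputError("mask has no contour")
    longest = max(contours, key=len)
    return longest[:, ::-1].copy()  # (row, col) -> (x, y)


def detect_corners(
    flower: SegmentedFlower,
    *,
    min_distance: int = _NMS_RADIUS,
    threshold_abs: float = _THRESHOLD_ABS,
    snap_tolerance: float = 2.0,
) -> list[CornerCandidate]:
    """Harris corner candidates on the mask contour, strongest first.

    The detector runs on the binary mask (not the RGB image) so petal
    texture cannot trigger it.  Peaks farther than ``snap_tolerance`` from
    the contour are snapped to the nearest contour point.
    """
    mask = flower.mask
    if not mask.any():
        raise InvalidInputError("empty mask")
    smoothed = ndi.gaussian_filter(mask.astype(np.float64), _SMOOTH_SIGMA)
    response = corner_harris(smoothed, method="k", k=_HARRIS_K, sigma=_HARRIS_SIGMA)
    peaks = corner_peaks(
        response,
        min_distance=min_distance,
        threshold_abs=threshold_abs,
        threshold_rel=_THRESHOLD_REL,
    )
    if len(peaks) == 0:
        return []
    contour = _contour(mask)
    out = []
    for r, c in peaks:
        x, y = float(c), float(r)
        d = np.hypot(contour[:, 0] - x, contour[:, 1] - y)
        j = int(np.argmin(d))
        if d[j] > snap_tolerance:
            x, y = float(contour[j, 0]), float(contour[j, 1])
        out.append(CornerCandidate(position=(x, y), response=float(response[r, c])))
    out.sort(key=lambda cc: -cc.response)
    return out


def _circle_contour_crossings(
    contour: np.ndarray, center: tuple[float, float], radius: float
) -> list[tuple[float, np.ndarray]]:
    """All crossings of the radius-``radius`` circle about ``center`` with
    the closed contour polyline, as (fractional contour index, point)."""
    d = np.hypot(contour[:, 0] - center[0], contour[:, 1] - center[1]) - radius
    nxt = np.roll(d, -1)
    idx = np.nonzero((d * nxt < 0) | (d == 0))[0]
    crossings = []
    n = len(contour)
    for i in idx:
        a, b = d[i], nxt[i]
        t = 0.0 if a == 0 else a / (a - b)
        p = contour[i] + t * (contour[(i + 1) % n] - contour[i])
        crossings.append((i + t, p))
    return crossings


def chord_endpoints(
    flower: SegmentedFlower,
    p: CornerCandidate,
    radius: float = 15.0,
) -> tuple[tuple[float, float], tuple[float, float]] | None:
    """The two contour points at arc distance ``radius`` from the candidate.

    Intersects the radius-``radius`` circle centered on the candidate with
    the mask contour.  With more than two crossings the nearest crossing
    along the contour on each side of the candidate is chosen (extra
    crossings arise at deep narrow notches).  Returns ``None`` when fewer
    than two crossings exist (candidate rejected).
    """
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    contour = _contour(flower.mask)
    crossings = _circle_contour_crossings(contour, p.position, radius)
    if len(crossings) < 2:
        return None
    if len(crossings) == 2:
        (_, e0), (_, e1) = crossings
        return (tuple(e0), tuple(e1))
    # nearest crossing along the contour on each side of the candidate
    d = np.hypot(contour[:, 0] - p.position[0], contour[:, 1] - p.position[1])
    ip = float(np.argmin(d))
    n = len(contour)
    fwd = min(crossings, key=lambda c: (c[0] - ip) % n)
    bwd = min(crossings, key=lambda c: (ip - c[0]) % n)
    if fwd is bwd:
        return None
    return (tuple(fwd[1]), tuple(bwd[1]))


def classify_concavity(
    flower: SegmentedFlower,
    p: CornerCandidate,
    radius: float = 15.0,
    *,
    step: float = 0.25,
    guard: float = 1.0,
) -> OverlapPoint | Rejection:
    """Apply the concave/convex chord rule to one corner candidate.

    The open chord between the two circle-contour intersections is sampled
    every ``step`` pixels with bilinear mask lookups (>= 0.5 counts as
    foreground), excluding ``guard`` pixels at both ends since the
    endpoints themselves lie on the contour.  All-background chords are
    accepted as overlap points; all-foreground chords are convex false
    positives; mixed chords are rejected conservatively.
    """
    verdict, ends = _chord_rule(flower, p.position, radius, step=step, guard=guard)
    if verdict == "bg":
        return OverlapPoint(
            position=p.position,
            chord_endpoints=ends,
            confidence=1.0,
            response=p.response,
        )
    if verdict == "mixed":
        # the corner peak can land a few pixels off the wedge apex, which
        # clips the chord against one margin; probe nearby contour points
        # for a position where the rule holds cleanly
        contour = _contour(flower.mask)
        d = np.hypot(contour[:, 0] - p.position[0], contour[:, 1] - p.position[1])
        j = int(np.argmin(d))
        n = len(contour)
        for off in (1, -1, 2, -2, 3, -3, 4, -4, 5, -5):
            q = tuple(contour[(j + off) % n])
            v, e = _chord_rule(flower, q, radius, step=step, guard=guard)
            if v == "bg":
                return OverlapPoint(
                    position=q, chord_endpoints=e, confidence=1.0, response=p.response
                )
    return Rejection(candidate=p, reason="convex" if verdict == "fg" else verdict)


def _chord_rule(flower, position, radius, *, step=0.25, guard=1.0):
    """Evaluate the chord rule at one contour position.

    Returns (verdict, chord_endpoints) with verdict in {"bg", "fg",
    "mixed", "no-chord"}.
    """
    cand = CornerCandidate(position=tuple(position), response=0.0)
    ends = chord_endpoints(flower, cand, radius)
    if ends is None:
        return "no-chord", None
    e0 = np.array(ends[0])
    e1 = np.array(ends[1])
    length = float(np.hypot(*(e1 - e0)))
    if length <= 2 * guard:
        return "no-chord", None
    n_samples = max(3, int(np.ceil((length - 2 * guard) / step)) + 1)
    ts = np.linspace(guard / length, 1 - guard / length, n_samples)
    pts = e0[None, :] + ts[:, None] * (e1 - e0)[None, :]
    vals = ndi.map_coordinates(
        flower.mask.astype(np.float32), [pts[:, 1], pts[:, 0]], order=1, mode="constant"
    )
    fg = vals >= 0.5
    if not fg.any():
        return "bg", (tuple(e0), tuple(e1))
    if fg.all():
        return "fg", (tuple(e0), tuple(e1))
    return "mixed", (tuple(e0), tuple(e1))


def detect_overlap_points(
    flower: SegmentedFlower,
    radius: float = 15.0,
    *,
    min_separation: float = 10.0,
) -> list[OverlapPoint]:
    """Full overlap detection: Harris candidates, chord-rule filtering and
    greedy suppression so accepted points stay ``min_separation`` apart
    (strongest response wins).  Labels are left ``unknown``."""
    accepted: list[OverlapPoint] = []
    for cand in detect_corners(flower):
        result = classify_concavity(flower, cand, radius)
        if isinstance(result, OverlapPoint):
            accepted.append(result)
    kept: list[OverlapPoint] = []
    for op in sorted(accepted, key=lambda o: -o.response):
        if all(
            np.hypot(op.position[0] - k.position[0], op.position[1] - k.position[1])
            >= min_separation
            for k in kept
        ):
            kept.append(op)
    return kept


def overlap_f1(predicted, truth, tol: float = 10.0) -> DetectionEval:
    """Precision / recall / F1 of predicted overlap points against ground
    truth, with greedy one-to-one nearest matching under ``tol`` pixels.

    ``predicted`` may contain :class:`OverlapPoint` objects or (x, y)
    pairs; ``truth`` is a list of (x, y) coordinates.
    """
    if tol <= 0:
        raise InvalidInputError("tol must be positive")
    pred = [tuple(p.position) if hasattr(p, "position") else tuple(p) for p in predicted]
    gt = [tuple(t) for t in truth]
    pairs = []
    for i, p in enumerate(pred):
        for j, t in enumerate(gt):
            d = np.hypot(p[0] - t[0], p[1] - t[1])
            if d <= tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    fp = len(pred) - tp
    fn = len(gt) - tp
    precision = tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if tp + fn else (1.0 if fp == 0 else 0.0)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionEval(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)
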