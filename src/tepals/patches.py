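"""Oriented overlap patches and synthetic patch generation.

Interior-exterior classification works on small square crops around each
overlap point.  Every crop is put into a canonical orientation first: the
chord between the two circle-contour intersections is made horizontal
with the flower interior below, so the two tepal margins form an "X"
whose background wedge opens upward.

Labeled training data is synthesized from the flower itself: single-
margin patches are cropped where circles of fixed radii around the
overlap meet the contour (away from the overlap wedge), classified by the
slope of the margin they contain, and superimposed pairwise — one
rising-left arc over one rising-right arc — to fabricate overlap patches
whose front/back relation, and hence L/R label, is known by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import CompositionError, InvalidInputError, PatchSynthesisError
from .overlaps import CornerCandidate, OverlapPoint, chord_endpoints
from .segmentation import SegmentedFlower

__all__ = [
    "Patch",
    "SyntheticPatchSet",
    "crop_original_patch",
    "crop_synthesis_arcs",
    "compose_synthetic_patch",
    "generate_synthetic_patch_set",
]

PATCH_SIZE = 20
SLOPE_MIN = 0.05  # flatter fitted margins are ambiguous and discarded


@dataclass
class Patch:
    """A canonically oriented square crop (background black).

    ``slope_type`` applies to single-margin arc crops: ``left-up`` margins
    rise toward the upper-left of the patch, ``right-up`` toward the
    upper-right.  In the canonical orientation the left-up margin belongs
    to the left tepal of an overlap, so a synthetic patch with the left-up
    arc composited in front carries label ``L``.
    """

    pixels: np.ndarray  # (S, S, 3) uint8
    center: tuple[float, float]
    orientation_angle: float
    kind: str  # "original" | "synthetic"
    label: str = "unknown"  # L | R | unknown
    slope_type: str | None = None  # "left-up" | "right-up" | None
    fg: np.ndarray | None = None  # (S, S) bool foreground
    slope: float | None = None
    intercept: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.shape[0] != self.pixels.shape[1] or self.pixels.ndim != 3:
            raise InvalidInputError("patch must be square RGB")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SyntheticPatchSet:
    patches: list[Patch]
    source_overlaps: int
    per_class_counts: dict[str, int] = field(default_factory=dict)


def _overlap_frame(op: OverlapPoint) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotation frame (u right, v down, angle) putting the chord horizontal
    with the flower interior below the overlap point."""
    e0 = np.asarray(op.chord_endpoints[0], float)
    e1 = np.asarray(op.chord_endpoints[1], float)
    p = np.asarray(op.position, float)
    c = e1 - e0
    norm = np.hypot(*c)
    if norm < 1e-9:
        raise InvalidInputError("degenerate chord")
    u = c / norm
    mid = 0.5 * (e0 + e1) - p
    # v is u rotated by +90 degrees (pure rotation, y-down); flip u so the
    # chord midpoint (the background wedge) sits above the point (negative v)
    if mid @ np.array([-u[1], u[0]]) > 0:
        u = -u
    v = np.array([-u[1], u[0]])
    return u, v, float(np.arctan2(u[1], u[0]))


def _sample_patch(
    flower: SegmentedFlower,
    center: tuple[float, float],
    u: np.ndarray,
    v: np.ndarray,
    size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear crop of the masked image in the rotated frame; returns
    (pixels uint8, fg bool).  Off-image regions pad with black."""
    offs = np.arange(size) - (size - 1) / 2.0
    duu, dvv = np.meshgrid(offs, offs)  # duu: columns (x), dvv: rows (y)
    xs = center[0] + duu * u[0] + dvv * v[0]
    ys = center[1] + duu * u[1] + dvv * v[1]
    h, w = flower.mask.shape
    if xs.min() < -0.5 or ys.min() < -0.5 or xs.max() > w - 0.5 or ys.max() > h - 0.5:
        warnings.warn("patch window extends beyond the image; padding with black")
    coords = [ys.ravel(), xs.ravel()]
    fg = (
        ndi.map_coordinates(
            flower.mask.astype(np.float32), coords, order=1, mode="constant"
        ).reshape(size, size)
        >= 0.5
    )
    out = np.zeros((size, size, 3), dtype=np.uint8)
    masked = flower.masked_image()
    for ch in range(3):
        vals = ndi.map_coordinates(
            masked[:, :, ch].astype(np.float32), coords, order=1, mode="constant"
        ).reshape(size, size)
        out[:, :, ch] = np.clip(np.round(vals), 0, 255).astype(np.uint8)
    out[~fg] = 0
    return out, fg


def _fit_margin(fg: np.ndarray) -> tuple[float, float] | None:
    """Least-squares line fit (y = a*x + b, y down) to the foreground
    boundary inside the patch, window borders excluded."""
    edge = fg & ~ndi.binary_erosion(fg)
    edge[0, :] = edge[-1, :] = False
    edge[:, 0] = edge[:, -1] = False
    ys, xs = np.nonzero(edge)
    if len(xs) < 6 or xs.max() - xs.min() < 6:
        return None
    a, b = np.polyfit(xs, ys, 1)
    return float(a), float(b)


def _vshift(arr: np.ndarray, dy: int) -> np.ndarray:
    """Shift rows by ``dy`` (positive = down), replicating the edge row.

    Down-shifts replicate the (typically background) top row; up-shifts
    replicate the (interior) bottom row, so shifted crops stay plausible.
    """
    if dy == 0:
        return arr.copy()
    out = np.empty_like(arr)
    if dy > 0:
        out[dy:] = arr[:-dy]
        out[:dy] = arr[0]
    else:
        out[:dy] = arr[-dy:]
        out[dy:] = arr[-1]
    return out


def _margin_profile(fg: np.ndarray) -> np.ndarray:
    """Topmost foreground row per column (the tepal margin height), NaN
    where a column holds no foreground."""
    any_fg = fg.any(axis=0)
    top = fg.argmax(axis=0).astype(float)
    top[~any_fg] = np.nan
    return top


def crop_original_patch(
    flower: SegmentedFlower, op: OverlapPoint, size: int = PATCH_SIZE
) -> Patch:
    """Canonically oriented crop centered on an overlap point.

    The neighborhood is rotated so the chord runs horizontal with the
    interior below, then cropped ``size`` x ``size``; background pixels
    are black.
    """
    u, v, angle = _overlap_frame(op)
    pixels, fg = _sample_patch(flower, op.position, u, v, size)
    return Patch(
        pixels=pixels,
        center=tuple(op.position),
        orientation_angle=angle,
        kind="original",
        label=op.label,
        fg=fg,
    )


def _arc_crop(
    flower: SegmentedFlower,
    center: tuple[float, float],
    u: np.ndarray,
    v: np.ndarray,
    angle: float,
    size: int,
) -> Patch | None:
    pixels, fg = _sample_patch(flower, center, u, v, size)
    fit = _fit_margin(fg)
    if fit is None or abs(fit[0]) < SLOPE_MIN:
        return None
    slope_type = "left-up" if fit[0] > 0 else "right-up"
    return Patch(
        pixels=pixels,
        center=tuple(center),
        orientation_angle=angle,
        kind="original",
        slope_type=slope_type,
        fg=fg,
        slope=fit[0],
        intercept=fit[1],
    )


def crop_synthesis_arcs(
    flower: SegmentedFlower,
    op: OverlapPoint,
    radii: tuple[float, ...] = (10.0, 15.0),
    want: int | None = None,
    seed: int = 0,
    size: int = PATCH_SIZE,
) -> list[Patch]:
    """Single-margin crops centered where circles around the overlap point
    meet the contour, oriented in the overlap's canonical frame.

    Each radius contributes its two circle-contour intersections (one per
    tepal margin, away from the overlap wedge).  When ``want`` exceeds the
    base crops, seeded re-crops with uniform integer offsets in [-3, 3] px
    are added until the quota is met.  Crops whose fitted margin slope is
    ambiguous (|slope| < 0.05) are discarded.
    """
    u, v, angle = _overlap_frame(op)
    cand = CornerCandidate(position=tuple(op.position), response=0.0)
    anchors: list[tuple[float, float]] = []
    for r in radii:
        ends = chord_endpoints(flower, cand, r)
        if ends is not None:
            anchors.extend(ends)
    out: list[Patch] = []
    for pt in anchors:
        patch = _arc_crop(flower, pt, u, v, angle, size)
        if patch is not None:
            out.append(patch)
    if not anchors:
        warnings.warn("no circle-contour intersections around the overlap point")
        return out
    if want is not None and out:
        rng = np.random.default_rng(seed)
        attempts = 0
        while len(out) < want and attempts < 60 * want:
            attempts += 1
            base = anchors[int(rng.integers(len(anchors)))]
            dx, dy = rng.integers(-3, 4, size=2)
            if dx == 0 and dy == 0:
                continue
            patch = _arc_crop(flower, (base[0] + dx, base[1] + dy), u, v, angle, size)
            if patch is not None:
                out.append(patch)
    return out


def compose_synthetic_patch(front: Patch, back: Patch) -> Patch:
    """Superimpose two opposite-slope arc crops into a labeled synthetic
    overlap patch.

    The front patch's foreground (the interior side of its margin) is
    pasted over the back patch, so the two margins cross like a real
    overlap and the front margin continues across the composite — the same
    depth cue a real patch shows.  Label is ``L`` when the left-up arc is
    in front, ``R`` otherwise.
    """
    for p in (front, back):
        if p.slope_type not in ("left-up", "right-up") or p.slope is None or p.fg is None:
            raise InvalidInputError("compose requires classified arc crops")
    if front.slope_type == back.slope_type:
        raise InvalidInputError("front and back must have opposite slope types")
    if front.size != back.size:
        raise InvalidInputError("patch sizes differ")
    size = front.size
    prof_f = _margin_profile(front.fg)
    prof_b = _margin_profile(back.fg)
    # superimpose so the two margins intersect in the upper half at the
    # center column, as in a real overlap crop: shift the back patch to
    # meet the front's margin height and both toward the canonical height
    mid = size // 2
    if not (np.isfinite(prof_f[mid]) and np.isfinite(prof_b[mid])):
        raise CompositionError("margin leaves the patch at its center column")
    target = (size - 1) // 2
    dy_all = int(target - prof_f[mid])
    front_fg = _vshift(front.fg, dy_all)
    front_px = _vshift(front.pixels, dy_all)
    dy_b = int(round(prof_f[mid] - prof_b[mid])) + dy_all
    back_fg = _vshift(back.fg, dy_b)
    back_px = _vshift(back.pixels, dy_b)
    diff = _margin_profile(front_fg) - _margin_profile(back_fg)
    valid = np.nonzero(np.isfinite(diff))[0]
    x_cross = y_cross = None
    for c0, c1 in zip(valid, valid[1:]):
        if diff[c0] == 0 or diff[c0] * diff[c1] < 0:
            x_cross = float(c0)
            y_cross = float(_margin_profile(front_fg)[c0])
            break
    if x_cross is None or y_cross >= 0.75 * size:
        raise CompositionError("margins do not cross in the patch's upper region")
    pixels = back_px.copy()
    pixels[front_fg] = front_px[front_fg]
    fg = front_fg | back_fg
    label = "L" if front.slope_type == "left-up" else "R"
    return Patch(
        pixels=pixels,
        center=front.center,
        orientation_angle=0.0,
        kind="synthetic",
        label=label,
        fg=fg,
    )


def _balance(
    arcs: list[Patch],
    per_class: int,
    rng: np.random.Generator,
    pad,
) -> tuple[list[Patch], list[Patch]]:
    lefts = [p for p in arcs if p.slope_type == "left-up"]
    rights = [p for p in arcs if p.slope_type == "right-up"]
    for name, group in (("left-up", lefts), ("right-up", rights)):
        attempts = 0
        while len(group) < per_class and attempts < 80 * per_class:
            attempts += 1
            p = pad()
            if p is not None and p.slope_type == name:
                group.append(p)
        if len(group) < per_class:
            raise PatchSynthesisError(
                f"only {len(group)} {name} arc patches available, need {per_class}"
            )
    if len(lefts) > per_class:
        lefts = [lefts[i] for i in sorted(rng.choice(len(lefts), per_class, replace=False))]
    if len(rights) > per_class:
        rights = [rights[i] for i in sorted(rng.choice(len(rights), per_class, replace=False))]
    return lefts, rights


def generate_synthetic_patch_set(
    flower: SegmentedFlower,
    overlaps: list[OverlapPoint],
    seed: int = 0,
    *,
    per_class: int = 25,
    quota: int = 50,
    radii: tuple[float, ...] = (10.0, 15.0),
    size: int = PATCH_SIZE,
) -> SyntheticPatchSet:
    """Per-flower synthetic patch set: pool arc crops from every overlap,
    balance to ``per_class`` of each slope type (seeded subsampling or
    perturbation padding), and compose every cross-type pair in both depth
    orders — ``per_class**2 * 2`` labeled patches, exactly class-balanced.
    """
    if not overlaps:
        raise InvalidInputError("need at least one overlap point")
    rng = np.random.default_rng(seed)
    arcs: list[Patch] = []
    frames: list[tuple[np.ndarray, np.ndarray, float, list[tuple[float, float]]]] = []
    for op in overlaps:
        u, v, angle = _overlap_frame(op)
        cand = CornerCandidate(position=tuple(op.position), response=0.0)
        anchors = []
        for r in radii:
            ends = chord_endpoints(flower, cand, r)
            if ends is not None:
                anchors.extend(ends)
        if not anchors:
            continue
        frames.append((u, v, angle, anchors))
        for pt in anchors:
            patch = _arc_crop(flower, pt, u, v, angle, size)
            if patch is not None:
                arcs.append(patch)
    if not frames:
        raise PatchSynthesisError("no usable contour arcs around any overlap point")

    def pad() -> Patch | None:
        u, v, angle, anchors = frames[int(rng.integers(len(frames)))]
        base = anchors[int(rng.integers(len(anchors)))]
        dx, dy = rng.integers(-3, 4, size=2)
        if dx == 0 and dy == 0:
            return None
        return _arc_crop(flower, (base[0] + dx, base[1] + dy), u, v, angle, size)

    attempts = 0
    while len(arcs) < quota and attempts < 60 * quota:
        attempts += 1
        p = pad()
        if p is not None:
            arcs.append(p)

    lefts, rights = _balance(arcs, per_class, rng, pad)
    patches: list[Patch] = []
    for fl in lefts:
        for fr in rights:
            patches.append(compose_synthetic_patch(fl, fr))  # left-up front -> L
            patches.append(compose_synthetic_patch(fr, fl))  # right-up front -> R
    counts = {
        "L": sum(1 for p in patches if p.label == "L"),
        "R": sum(1 for p in patches if p.label == "R"),
    }
    return SyntheticPatchSet(
        patches=patches, source_overlaps=len(overlaps), per_class_counts=counts
    )
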