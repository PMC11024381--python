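"""Flower localization and color-model segmentation.

Coordinate conventions used across the whole package: 0-based pixel
coordinates, ``x`` to the right, ``y`` down; images are ``(H, W, 3)``
``uint8`` arrays; bounding boxes are half-open on their max edges.

The flower is localized either by a user-supplied detector backend (any
callable mapping an RGB image to a :class:`BoundingBox`; a fine-tuned
neural detector would plug in here) or by a naive color-saliency fallback
that exploits the fact that a flower photographed for arrangement scoring
contrasts with its background.  Segmentation follows the GrabCut recipe:
per-image Gaussian mixture color models for foreground and background,
initialized from the rectangle, refined for a fixed number of iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.transform import resize
from sklearn.mixture import GaussianMixture

from .errors import (
    DetectionFailureError,
    InvalidInputError,
    SegmentationFailureError,
    UndefinedMetricError,
)

__all__ = [
    "BoundingBox",
    "LetterboxSpec",
    "SegmentedFlower",
    "letterbox",
    "detect_flower",
    "segment_flower",
    "region_iou",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, half-open on the max edges."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidInputError(f"degenerate box {self}")
        if self.x_min < 0 or self.y_min < 0:
            raise InvalidInputError(f"box extends outside image bounds: {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def clip_to(self, width: int, height: int) -> "BoundingBox":
        return BoundingBox(
            max(0, self.x_min),
            max(0, self.y_min),
            min(width, self.x_max),
            min(height, self.y_max),
        )

    def check_within(self, width: int, height: int) -> None:
        if self.x_max > width or self.y_max > height:
            raise InvalidInputError(
                f"box {self} exceeds image bounds ({width}x{height})"
            )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class LetterboxSpec:
    """Geometry of an aspect-preserving rescale into a black square canvas.

    Content is anchored at the top-left corner; padding fills right/bottom.
    ``scale`` maps original to letterboxed coordinates exactly, so box
    coordinates predicted on the letterboxed image can be mapped back.
    """

    target_side: int
    scale: float
    content_size: tuple[int, int]  # (width, height) of the scaled content
    pad_value: int = 0

    def to_letterbox(self, xy: tuple[float, float]) -> tuple[float, float]:
        return (xy[0] * self.scale, xy[1] * self.scale)

    def to_original(self, xy: tuple[float, float]) -> tuple[float, float]:
        return (xy[0] / self.scale, xy[1] / self.scale)

    def box_to_original(self, box: BoundingBox, width: int, height: int) -> BoundingBox:
        x0, y0 = self.to_original((box.x_min, box.y_min))
        x1, y1 = self.to_original((box.x_max, box.y_max))
        return BoundingBox(
            int(round(x0)), int(round(y0)), int(round(x1)), int(round(y1))
        ).clip_to(width, height)


@dataclass
class SegmentedFlower:
    """One flower: source image, its bounding box and a foreground mask."""

    image: np.ndarray
    box: BoundingBox
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise InvalidInputError("image must be (H, W, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise InvalidInputError("mask dimensions must match the image")
        self.mask = self.mask.astype(bool)
        h, w = self.mask.shape
        self.box.check_within(w, h)
        outside = self.mask.copy()
        outside[self.box.y_min : self.box.y_max, self.box.x_min : self.box.x_max] = False
        if outside.any():
            raise InvalidInputError("foreground pixels outside the bounding box")

    @property
    def foreground_area(self) -> int:
        return int(self.mask.sum())

    def masked_image(self) -> np.ndarray:
        """Image with background pixels set to black."""
        out = self.image.copy()
        out[~self.mask] = 0
        return out


def letterbox(
    image: np.ndarray, target_side: int = 256
) -> tuple[np.ndarray, LetterboxSpec]:
    """Rescale ``image`` to fit a ``target_side`` square, padding with black.

    Bilinear interpolation, aspect ratio preserved, content anchored
    top-left.  A 1000x662 input at the default side becomes 256x169 content
    inside a 256x256 canvas.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError("expected an (H, W, 3) RGB image")
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise InvalidInputError("zero-dimension image")
    scale = target_side / max(h, w)
    cw = max(1, int(round(w * scale)))
    ch = max(1, int(round(h * scale)))
    content = resize(
        image.astype(np.float64),
        (ch, cw),
        order=1,
        anti_aliasing=scale < 1.0,
        preserve_range=True,
    )
    canvas = np.zeros((target_side, target_side, 3), dtype=np.uint8)
    canvas[:ch, :cw] = np.clip(np.round(content), 0, 255).astype(np.uint8)
    return canvas, LetterboxSpec(target_side, scale, (cw, ch))


def detect_flower(
    image: np.ndarray,
    backend=None,
    *,
    color_threshold: float = 40.0,
    border: int = 2,
) -> BoundingBox:
    """Locate the flower and return its bounding box.

    ``backend`` may be any callable ``image -> BoundingBox`` (e.g. a wrapper
    around a trained object detector).  Without one, a color-saliency
    fallback is used: the background color is estimated as the median of the
    image border, pixels whose RGB Euclidean distance from it exceeds
    ``color_threshold`` are marked salient, and the tight box of the largest
    8-connected salient component is returned.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError("expected an (H, W, 3) RGB image")
    if backend is not None:
        return backend(image)
    h, w = image.shape[:2]
    img = image.astype(np.float64)
    frame = np.concatenate(
        [
            img[:border].reshape(-1, 3),
            img[-border:].reshape(-1, 3),
            img[:, :border].reshape(-1, 3),
            img[:, -border:].reshape(-1, 3),
        ]
    )
    bg_color = np.median(frame, axis=0)
    dist = np.sqrt(((img - bg_color) ** 2).sum(axis=2))
    salient = dist > color_threshold
    if not salient.any():
        raise DetectionFailureError("no region contrasts with the border color")
    labels = measure.label(salient, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    ys, xs = np.nonzero(labels == biggest)
    return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


# sampling cap for the color-model fits; 15k pixels is ample for a
# 5-component RGB mixture and keeps per-image cost well under a second
_MAX_GMM_SAMPLES = 15_000


def _fit_gmm(pixels: np.ndarray, rng: np.random.Generator, n_components: int) -> GaussianMixture:
    if len(pixels) > _MAX_GMM_SAMPLES:
        pixels = pixels[rng.choice(len(pixels), _MAX_GMM_SAMPLES, replace=False)]
    k = min(n_components, len(np.unique(pixels, axis=0)), len(pixels))
    gmm = GaussianMixture(
        n_components=max(1, k),
        covariance_type="full",
        reg_covar=1.0,
        max_iter=60,
        random_state=0,
    )
    gmm.fit(pixels)
    return gmm


def segment_flower(
    image: np.ndarray,
    box: BoundingBox,
    iterations: int = 5,
    *,
    n_components: int = 5,
    seed: int = 0,
) -> SegmentedFlower:
    """Extract the flower's per-pixel region inside ``box``.

    GrabCut-style color modelling: everything outside the rectangle is
    definite background, the rectangle interior starts as probable
    foreground, and foreground/background Gaussian mixture color models are
    alternated with per-pixel reassignment for ``iterations`` rounds.

    Raises :class:`SegmentationFailureError` when the foreground collapses
    or when there is no background context to model — both symptoms of a
    foreground/background color collision.
    """
    if iterations < 1:
        raise InvalidInputError("iterations must be >= 1")
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError("expected an (H, W, 3) RGB image")
    h, w = image.shape[:2]
    box.check_within(w, h)
    rng = np.random.default_rng(seed)

    img = image.astype(np.float64)
    in_box = np.zeros((h, w), dtype=bool)
    in_box[box.y_min : box.y_max, box.x_min : box.x_max] = True
    if not (~in_box).any():
        raise SegmentationFailureError(
            "bounding box covers the whole image; no background to model"
        )

    fg = in_box.copy()
    pixels = img.reshape(-1, 3)
    inside_flat = in_box.ravel()
    for _ in range(iterations):
        fg_flat = fg.ravel()
        if not fg_flat.any():
            raise SegmentationFailureError("foreground model collapsed to empty")
        fg_gmm = _fit_gmm(pixels[fg_flat], rng, n_components)
        bg_gmm = _fit_gmm(pixels[~fg_flat], rng, n_components)
        scores_fg = fg_gmm.score_samples(pixels[inside_flat])
        scores_bg = bg_gmm.score_samples(pixels[inside_flat])
        new_fg = np.zeros(h * w, dtype=bool)
        new_fg[inside_flat] = scores_fg > scores_bg
        fg = new_fg.reshape(h, w)
    if not fg.any():
        raise SegmentationFailureError(
            "empty foreground after refinement (foreground/background colors collide)"
        )
    # drop speckle: keep the largest connected foreground component
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    fg = labels == int(np.argmax(counts))
    fg = ndi.binary_fill_holes(fg)
    return SegmentedFlower(image=image, box=box, mask=fg)


def region_iou(a, b) -> float:
    """Intersection-over-union of two regions of the same kind.

    Accepts two :class:`BoundingBox` instances or two binary masks of equal
    shape.  Raises :class:`UndefinedMetricError` when both regions are
    empty (the ratio 0/0).
    """
    if isinstance(a, BoundingBox) and isinstance(b, BoundingBox):
        ix = max(0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
        iy = max(0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
        inter = ix * iy
        union = a.area + b.area - inter
        if union == 0:
            raise UndefinedMetricError("IoU of two empty boxes is undefined")
        return inter / union
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError("masks must have identical dimensions")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedMetricError("IoU of two empty regions is undefined")
    return float(np.logical_and(a, b).sum() / union)
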