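"""Synthetic single-flower renderer with exact ground truth.

Tepals are drawn as rotated ellipses in an annulus around the flower
center (a central disc covers the region where all tepal bases converge,
as the receptacle does in a real flower).  Tepals sit at equal angular
spacing plus jitter, sized so that exactly the adjacent pairs intersect.
Each adjacent-pair intersection (lens) is repainted with the designated
front tepal's fill.  This per-region compositing — rather than one global
z-order — is what makes cyclic "spiral" depth patterns renderable: a
pattern in which every tepal covers its clockwise neighbor admits no
total ordering, but local repainting of the pairwise lenses is exact when
only neighbors intersect.

The renderer emits the image plus ground truth for every pipeline stage:
foreground mask, bounding box, overlap corner coordinates with their
L (left-tepal-forward) / R (right-tepal-forward) labels, and the
resulting arrangement.  Depth labels follow the pipeline's convention:
for the overlap between tepals ``i`` and ``i+1`` (clockwise order),
``lr_pattern[i] == "L"`` puts tepal ``i`` — the one on the left when the
overlap is viewed with the flower interior below — in front.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from shapely.affinity import rotate as shp_rotate
from shapely.affinity import scale as shp_scale
from shapely.affinity import translate as shp_translate
from shapely.geometry import Point, Polygon

from .arrangement import (
    ArrangementCatalog,
    TepalClassSequence,
    iea_to_lr,
    load_catalog,
    lr_to_iea,
    order_overlaps_by_angle,
)
from .errors import InvalidInputError, RendererInfeasibleError
from .segmentation import BoundingBox

__all__ = ["FlowerSpec", "GroundTruth", "render_flower", "make_dataset", "balanced_specs"]


@dataclass(frozen=True)
class FlowerSpec:
    """Parameters of one synthetic flower.

    ``lr_pattern[i]`` gives the depth relation at the overlap between
    tepals ``i`` and ``i+1 (mod n)``.  Colors are RGB; the tepal /
    background contrast must exceed 60 intensity units so that
    color-saliency detection and color-model segmentation are meaningful.
    """

    n_tepals: int = 6
    lr_pattern: str = "LLLLLL"
    canvas: tuple[int, int] = (1000, 662)  # (width, height)
    tepal_color: tuple[int, int, int] = (225, 85, 95)
    background_color: tuple[int, int, int] = (38, 66, 42)
    center_color: tuple[int, int, int] = (238, 200, 70)
    distinct_shades: bool = True
    shade_spread: int = 40
    radius_frac: float = 0.44  # flower radius as a fraction of min(canvas)/2
    jitter_angle: float = 0.04  # radians, per tepal
    jitter_scale: float = 0.04  # fractional, per tepal axis
    rotation: float = 0.0  # whole-flower rotation, radians
    notch_depth: float = 0.0  # >0 cuts an indentation into one tepal margin
    seed: int = 0
    arrangement_id: str | None = None

    def __post_init__(self) -> None:
        if not 3 <= self.n_tepals <= 9:
            raise InvalidInputError("n_tepals must be in 3..9")
        if len(self.lr_pattern) != self.n_tepals or not set(self.lr_pattern) <= set("LR"):
            raise InvalidInputError(
                f"lr_pattern must be {self.n_tepals} letters over L/R, got {self.lr_pattern!r}"
            )
        dist = np.linalg.norm(
            np.array(self.tepal_color, float) - np.array(self.background_color, float)
        )
        if dist <= 60:
            raise InvalidInputError(
                f"tepal/background color distance {dist:.0f} must exceed 60"
            )

    @classmethod
    def from_arrangement(
        cls, arrangement_id: str, catalog: ArrangementCatalog | None = None, **kwargs
    ) -> "FlowerSpec":
        """Build a spec realizing a named catalog arrangement."""
        catalog = catalog if catalog is not None else load_catalog()
        entry = catalog.get(arrangement_id)
        lr = iea_to_lr(entry.canonical)
        return cls(
            n_tepals=len(lr),
            lr_pattern=lr,
            arrangement_id=arrangement_id,
            **kwargs,
        )


@dataclass
class GroundTruth:
    """Exact per-stage ground truth for one rendered flower."""

    mask: np.ndarray
    box: BoundingBox
    overlap_points: list[tuple[tuple[float, float], str]]  # ((x, y), L/R)
    arrangement: TepalClassSequence
    arrangement_id: str | None
    tepal_shades: list[tuple[int, int, int]] = field(default_factory=list)
    tepal_polygons: list[np.ndarray] = field(default_factory=list)  # exterior (x, y)

    @property
    def positions(self) -> list[tuple[float, float]]:
        return [p for p, _ in self.overlap_points]

    @property
    def labels(self) -> list[str]:
        return [l for _, l in self.overlap_points]


def _ellipse(cx: float, cy: float, a: float, b: float, angle_rad: float) -> Polygon:
    circ = Point(0.0, 0.0).buffer(1.0, quad_segs=64)
    e = shp_scale(circ, a, b)
    e = shp_rotate(e, np.degrees(angle_rad), origin=(0, 0))
    return shp_translate(e, cx, cy)


def _boundary_crossings(p: Polygon, q: Polygon) -> list[tuple[float, float]]:
    """Crossing points of two polygon boundaries, clustered (discretized
    ellipses can yield tight clusters of near-duplicate intersections)."""
    inter = p.exterior.intersection(q.exterior)
    geoms = list(inter.geoms) if hasattr(inter, "geoms") else [inter]
    pts = []
    for g in geoms:
        if g.geom_type == "Point":
            pts.append((g.x, g.y))
        elif g.geom_type in ("LineString", "MultiPoint"):
            pts.extend((c[0], c[1]) for c in getattr(g, "coords", []))
    clusters: list[list[tuple[float, float]]] = []
    for pt in pts:
        for cl in clusters:
            if np.hypot(pt[0] - cl[0][0], pt[1] - cl[0][1]) < 3.0:
                cl.append(pt)
                break
        else:
            clusters.append([pt])
    return [tuple(np.mean(cl, axis=0)) for cl in clusters]


def _layout(n: int) -> tuple[float, float]:
    # (inner-tip radius fraction of flower radius, tangential width factor)
    return (0.10, 1.20) if n == 3 else (0.22, 1.45)


def _shades(spec: FlowerSpec, rng: np.random.Generator) -> list[tuple[int, int, int]]:
    base = np.array(spec.tepal_color, float)
    if not spec.distinct_shades:
        return [spec.tepal_color] * spec.n_tepals
    bg = np.array(spec.background_color, float)
    shades: list[np.ndarray] = []
    for _ in range(spec.n_tepals):
        for _attempt in range(200):
            s = np.clip(
                base + rng.integers(-spec.shade_spread, spec.shade_spread + 1, 3), 0, 255
            )
            if np.linalg.norm(s - bg) > 60 and all(
                np.linalg.norm(s - t) >= 15 for t in shades
            ):
                shades.append(s)
                break
        else:
            raise RendererInfeasibleError("could not draw pairwise-distinct tepal shades")
    return [tuple(int(v) for v in s) for s in shades]


def _draw_poly(draw: ImageDraw.ImageDraw, poly: Polygon, color) -> None:
    coords = [(float(x), float(y)) for x, y in poly.exterior.coords]
    draw.polygon(coords, fill=color)


def render_flower(spec: FlowerSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one flower; deterministic for a fixed spec (seed included).

    Raises :class:`RendererInfeasibleError` when the requested geometry
    would make non-adjacent tepals intersect, lose the two-crossing lens
    structure of an adjacent pair, or leave the central disc uncovered.
    """
    n = spec.n_tepals
    rng = np.random.default_rng(spec.seed)
    w, h = spec.canvas
    cx, cy = w / 2.0, h / 2.0
    R = spec.radius_frac * min(w, h) / 1.0
    R = min(R, min(w, h) / 2.0 - 4)
    r0f, width_factor = _layout(n)
    r0 = r0f * R
    a0 = (R - r0) / 2.0
    d0 = r0 + a0
    b0 = d0 * np.sin(np.pi / n) * width_factor

    max_jit = min(spec.jitter_angle, 0.3 * np.pi / n)
    tepals: list[Polygon] = []
    thetas: list[float] = []
    for i in range(n):
        th = spec.rotation + i * 2 * np.pi / n + rng.uniform(-max_jit, max_jit)
        a = a0 * (1 + rng.uniform(-spec.jitter_scale, spec.jitter_scale))
        b = b0 * (1 + rng.uniform(-spec.jitter_scale, spec.jitter_scale))
        d = r0 + a
        tepals.append(_ellipse(cx + d * np.cos(th), cy + d * np.sin(th), a, b, th))
        thetas.append(th)

    # adjacency structure: neighbors must overlap in a single lens, others miss
    for i in range(n):
        for k in range(i + 1, n):
            adj = (k - i == 1) or (i == 0 and k == n - 1)
            if not adj and tepals[i].intersection(tepals[k]).area > 1e-6:
                raise RendererInfeasibleError(f"non-adjacent tepals {i} and {k} intersect")
    lenses: list[Polygon] = []
    outer_pts: list[tuple[float, float]] = []
    inner_radii: list[float] = []
    outer_radii: list[float] = []
    for i in range(n):
        j = (i + 1) % n
        crossings = _boundary_crossings(tepals[i], tepals[j])
        if len(crossings) != 2:
            raise RendererInfeasibleError(
                f"adjacent tepals {i},{j} cross {len(crossings)} times (need 2)"
            )
        rads = [np.hypot(px - cx, py - cy) for px, py in crossings]
        inner_radii.append(min(rads))
        outer_radii.append(max(rads))
        outer_pts.append(crossings[int(np.argmax(rads))])
        lens = tepals[i].intersection(tepals[j])
        if lens.geom_type != "Polygon" or lens.area < 10:
            raise RendererInfeasibleError(f"degenerate overlap between tepals {i},{j}")
        lenses.append(lens)

    disc_r = max(inner_radii) + 5.0
    if disc_r >= min(outer_radii) - 8.0:
        raise RendererInfeasibleError("no central-disc radius separates the crossings")
    disc = Point(cx, cy).buffer(disc_r, quad_segs=64)
    union_cover = np.array(
        [
            any(
                t.covers(Point(cx + disc_r * np.cos(t_ang), cy + disc_r * np.sin(t_ang)))
                for t in tepals
            )
            for t_ang in np.linspace(0, 2 * np.pi, 360, endpoint=False)
        ]
    )
    if not union_cover.all():
        raise RendererInfeasibleError("central disc boundary not covered by tepals")

    if spec.notch_depth > 0:  # margin indentation on tepal 0 (false-positive fixture)
        tip = (cx + (r0 + 2 * a0) * np.cos(thetas[0]), cy + (r0 + 2 * a0) * np.sin(thetas[0]))
        bite = Point(tip).buffer(spec.notch_depth, quad_segs=32)
        cut = tepals[0].difference(bite)
        if cut.geom_type == "Polygon" and cut.area > 0.5 * tepals[0].area:
            tepals[0] = cut

    shades = _shades(spec, rng)
    img = Image.new("RGB", (w, h), spec.background_color)
    draw = ImageDraw.Draw(img)
    mimg = Image.new("L", (w, h), 0)
    mdraw = ImageDraw.Draw(mimg)
    _draw_poly(draw, disc, spec.center_color)
    _draw_poly(mdraw, disc, 255)
    for i, t in enumerate(tepals):
        _draw_poly(draw, t, shades[i])
        _draw_poly(mdraw, t, 255)
    for i, lens in enumerate(lenses):
        j = (i + 1) % n
        front = i if spec.lr_pattern[i] == "L" else j
        _draw_poly(draw, lens, shades[front])

    image = np.asarray(img, dtype=np.uint8).copy()
    mask = np.asarray(mimg) > 0
    ys, xs = np.nonzero(mask)
    box = BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)

    points = [(outer_pts[i], spec.lr_pattern[i]) for i in range(n)]
    ordered = order_overlaps_by_angle(points, mask)
    arrangement = lr_to_iea(ordered)
    arrangement_id = spec.arrangement_id
    if arrangement_id is None:
        from .arrangement import match_arrangement

        m = match_arrangement(arrangement, load_catalog())
        arrangement_id = m.best.id if m.distance == 0 and not m.ambiguous else None
    truth = GroundTruth(
        mask=mask,
        box=box,
        overlap_points=points,
        arrangement=arrangement,
        arrangement_id=arrangement_id,
        tepal_shades=shades,
        tepal_polygons=[np.asarray(t.exterior.coords) for t in tepals],
    )
    return image, truth


def balanced_specs(
    catalog: ArrangementCatalog | None = None,
    count: int = 52,
    seed: int = 0,
    **kwargs,
) -> list[FlowerSpec]:
    """Round-robin specs over the catalog entries (class-balanced when
    ``count`` is a multiple of the catalog size)."""
    catalog = catalog if catalog is not None else load_catalog()
    rng = np.random.default_rng(seed)
    specs = []
    entries = list(catalog)
    for i in range(count):
        entry = entries[i % len(entries)]
        specs.append(
            FlowerSpec.from_arrangement(
                entry.id,
                catalog,
                seed=int(rng.integers(0, 2**31 - 1)),
                rotation=float(rng.uniform(0, 2 * np.pi)),
                **kwargs,
            )
        )
    return specs


def make_dataset(specs: list[FlowerSpec], out_dir: str | Path) -> list[dict]:
    """Render every spec into ``out_dir`` (image, mask, ground-truth JSON)
    and write a TSV manifest; returns the manifest rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        stem = f"flower_{i:04d}"
        image, truth = render_flower(spec)
        Image.fromarray(image).save(out / f"{stem}.png")
        Image.fromarray((truth.mask * 255).astype(np.uint8)).save(out / f"{stem}_mask.png")
        record = {
            "image": f"{stem}.png",
            "mask": f"{stem}_mask.png",
            "n_tepals": spec.n_tepals,
            "lr_pattern": spec.lr_pattern,
            "seed": spec.seed,
            "box": truth.box.as_tuple(),
            "overlap_points": [
                {"position": [float(x), float(y)], "label": lab}
                for (x, y), lab in truth.overlap_points
            ],
            "arrangement": truth.arrangement.classes,
            "arrangement_id": truth.arrangement_id,
        }
        (out / f"{stem}_truth.json").write_text(json.dumps(record, indent=1))
        rows.append(record)
    lines = ["image\tn_tepals\tarrangement\tarrangement_id\tseed"]
    for r in rows:
        lines.append(
            f"{r['image']}\t{r['n_tepals']}\t{r['arrangement']}\t{r['arrangement_id']}\t{r['seed']}"
        )
    (out / "manifest.tsv").write_text("\n".join(lines) + "\n")
    return rows
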