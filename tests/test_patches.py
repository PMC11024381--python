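"""Oriented patch cropping and synthetic overlap-patch generation."""

import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate

import tepals as tp
from tepals.errors import InvalidInputError
from tepals.patches import _margin_profile, compose_synthetic_patch


@pytest.fixture(scope="module")
def flower_and_points(six_tepal_segmented, six_tepal_points):
    assert len(six_tepal_points) == 6
    return six_tepal_segmented, six_tepal_points


def test_original_patch_shape_and_background(flower_and_points):
    flower, points = flower_and_points
    for op in points:
        patch = tp.crop_original_patch(flower, op)
        assert patch.pixels.shape == (20, 20, 3)
        assert patch.kind == "original"
        assert (patch.pixels[~patch.fg] == 0).all()


def test_original_patch_contour_in_upper_half(flower_and_points):
    """Canonical orientation: the background wedge opens upward, so the
    margin crossing sits at the patch center with contour above it."""
    flower, points = flower_and_points
    for op in points:
        patch = tp.crop_original_patch(flower, op)
        upper = patch.fg[:10]
        lower = patch.fg[10:]
        assert lower.mean() > upper.mean()  # interior below
        assert (~upper).any()  # wedge present on top


def test_rotated_source_gives_same_patch(six_tepal):
    """Cropping from a 90-degree-rotated image must reproduce the same
    canonical patch up to interpolation noise."""
    _, image, truth = six_tepal
    flower = tp.SegmentedFlower(image=image, box=truth.box, mask=truth.mask)
    points = tp.detect_overlap_points(flower)
    ref = tp.crop_original_patch(flower, points[0])

    rot_img = np.rot90(image, k=-1).copy()  # 90 deg clockwise
    rot_mask = np.rot90(truth.mask, k=-1).copy()
    h = image.shape[0]
    ys, xs = np.nonzero(rot_mask)
    box = tp.BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    rot_flower = tp.SegmentedFlower(image=rot_img, box=box, mask=rot_mask)
    rot_points = tp.detect_overlap_points(rot_flower)
    # (x, y) -> (h - 1 - y, x) under clockwise rotation
    rx, ry = h - 1 - ref.center[1], ref.center[0]
    match = min(
        rot_points, key=lambda p: np.hypot(p.position[0] - rx, p.position[1] - ry)
    )
    assert np.hypot(match.position[0] - rx, match.position[1] - ry) <= 2
    rot_patch = tp.crop_original_patch(rot_flower, match)
    diff = np.abs(
        rot_patch.pixels.astype(float) - ref.pixels.astype(float)
    ).mean()
    assert diff < 10


def test_canonical_neighborhood_is_fixed_point():
    """A patch whose chord is already horizontal with interior below must
    come out with rotation angle 0."""
    mask = np.zeros((100, 100), dtype=bool)
    mask[50:, :] = True
    mask[30:50, 40:60] = True  # a notch-less bump; we only test the frame
    img = np.zeros((100, 100, 3), dtype=np.uint8)
    img[mask] = (200, 50, 50)
    flower = tp.SegmentedFlower(
        image=img, box=tp.BoundingBox(0, 0, 100, 100), mask=mask
    )
    from tepals.overlaps import OverlapPoint

    op = OverlapPoint(position=(50.0, 50.0), chord_endpoints=((35.0, 45.0), (65.0, 45.0)))
    patch = tp.crop_original_patch(flower, op)
    assert abs(patch.orientation_angle) < 1e-6


def test_synthesis_arcs_base_count_and_slopes(flower_and_points):
    """Two radii x two circle-contour intersections give at least 4 base
    crops per overlap, split between the two slope classes."""
    flower, points = flower_and_points
    arcs = tp.crop_synthesis_arcs(flower, points[0])
    assert len(arcs) >= 4
    kinds = {a.slope_type for a in arcs}
    assert kinds == {"left-up", "right-up"}
    for a in arcs:
        assert a.pixels.shape == (20, 20, 3)
        assert (a.slope > 0) == (a.slope_type == "left-up")


def test_synthesis_arcs_quota_padding_reproducible(flower_and_points):
    flower, points = flower_and_points
    a1 = tp.crop_synthesis_arcs(flower, points[0], want=12, seed=5)
    a2 = tp.crop_synthesis_arcs(flower, points[0], want=12, seed=5)
    assert len(a1) == 12
    assert all(
        np.array_equal(x.pixels, y.pixels) and x.center == y.center
        for x, y in zip(a1, a2)
    )


def test_compose_label_follows_front_slope(flower_and_points):
    flower, points = flower_and_points
    arcs = []
    for op in points:
        arcs.extend(tp.crop_synthesis_arcs(flower, op))
    left = next(a for a in arcs if a.slope_type == "left-up")
    right = next(a for a in arcs if a.slope_type == "right-up")
    assert compose_synthetic_patch(right, left).label == "R"
    assert compose_synthetic_patch(left, right).label == "L"  # swap flips


def test_compose_crossing_in_composite(flower_and_points):
    """The composite contains an X-like margin crossing: foreground from
    both arcs is present above the crossing row."""
    flower, points = flower_and_points
    arcs = tp.crop_synthesis_arcs(flower, points[0])
    left = next(a for a in arcs if a.slope_type == "left-up")
    right = next(a for a in arcs if a.slope_type == "right-up")
    comp = compose_synthetic_patch(left, right)
    prof = _margin_profile(comp.fg)
    finite = prof[np.isfinite(prof)]
    cross_row = np.nanmin(prof[8:12])
    assert finite.min() < cross_row  # contour extends above the crossing
    assert comp.fg[:int(cross_row), :].any()


def test_compose_requires_opposite_slopes(flower_and_points):
    flower, points = flower_and_points
    arcs = tp.crop_synthesis_arcs(flower, points[0])
    lefts = [a for a in arcs if a.slope_type == "left-up"]
    if len(lefts) < 2:
        lefts = lefts * 2
    with pytest.raises(InvalidInputError):
        compose_synthetic_patch(lefts[0], lefts[1])


def test_generate_patch_set_counts_and_balance(flower_and_points):
    flower, points = flower_and_points
    s = tp.generate_synthetic_patch_set(flower, points, seed=1)
    assert len(s.patches) == 1250
    assert s.per_class_counts == {"L": 625, "R": 625}
    assert s.source_overlaps == 6
    assert all(p.kind == "synthetic" for p in s.patches)
    assert all(p.pixels.shape == (20, 20, 3) for p in s.patches)


def test_generate_patch_set_deterministic(flower_and_points):
    flower, points = flower_and_points
    s1 = tp.generate_synthetic_patch_set(flower, points, seed=2)
    s2 = tp.generate_synthetic_patch_set(flower, points, seed=2)
    assert all(
        np.array_equal(a.pixels, b.pixels) for a, b in zip(s1.patches, s2.patches)
    )
    s3 = tp.generate_synthetic_patch_set(flower, points, seed=3)
    assert s3.per_class_counts == {"L": 625, "R": 625}
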