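"""Circular-permutation logic: conversion, cyclic edit distance, matching.

The cyclic edit distance is cross-checked against an independent oracle:
a textbook dynamic-programming Levenshtein distance minimized by brute
force over every rotation of the query and of its reversal.
"""

import math

import numpy as np
import pytest

from tepals import (
    ArrangementCatalog,
    ArrangementClass,
    TepalClassSequence,
    canonical_form,
    cyclic_edit_distance,
    enumerate_arrangements,
    iea_to_lr,
    load_catalog,
    lr_to_iea,
    match_arrangement,
    order_overlaps_by_angle,
)
from tepals.errors import CatalogError, TooFewOverlapsError


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic program, unit costs."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_cyclic(a: str, b: str) -> int:
    """Oracle: minimum DP distance over all rotations x {identity, reversal}."""
    best = math.inf
    for s in (a, a[::-1]):
        for i in range(len(s)):
            best = min(best, dp_levenshtein(s[i:] + s[:i], b))
    return best


# --- L/R -> I/E/A conversion -------------------------------------------------


@pytest.mark.parametrize(
    "lr,expected",
    [
        ("LLLL", "AAAA"),
        ("LRLR", "EIEI"),
        ("RRR", "AAA"),
        ("LLR", "AEI"),
    ],
)
def test_lr_to_iea_examples(lr, expected):
    assert lr_to_iea(lr).classes == expected


def test_lr_to_iea_conserves_internal_external_counts():
    """Around a circle, L/R boundaries alternate, so every sequence has as
    many internal as external tepals."""
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(3, 12))
        lr = "".join(rng.choice(["L", "R"], n))
        iea = lr_to_iea(lr).classes
        assert iea.count("I") == iea.count("E")
        assert len(iea) == n


def test_iea_to_lr_round_trips_catalog_entries():
    for entry in load_catalog():
        lr = iea_to_lr(entry.canonical)
        assert lr_to_iea(lr).canonical() == entry.canonical.classes


# --- angular ordering --------------------------------------------------------


def test_order_overlaps_compass_points():
    """With image axes (y down) the angle grows clockwise on screen:
    east, south, west, north."""
    pts = [((0, -10), "R"), ((10, 0), "L"), ((-10, 0), "R"), ((0, 10), "L")]
    seq = order_overlaps_by_angle(pts)
    assert seq.labels == ("L", "L", "R", "R")  # E, S, W, N
    assert np.allclose(seq.angles, [0, np.pi / 2, np.pi, 3 * np.pi / 2])


def test_order_overlaps_rotation_preserves_cyclic_order():
    rng = np.random.default_rng(1)
    angs = np.sort(rng.uniform(0, 2 * np.pi, 6))
    pts = [((np.cos(a) * 50, np.sin(a) * 50), lab) for a, lab in zip(angs, "LRLRLR")]
    base = order_overlaps_by_angle(pts).labels
    theta = 0.5
    rot = [
        (
            (
                x * np.cos(theta) - y * np.sin(theta),
                x * np.sin(theta) + y * np.cos(theta),
            ),
            lab,
        )
        for (x, y), lab in pts
    ]
    rotated = order_overlaps_by_angle(rot).labels
    doubled = base + base
    assert any(
        rotated == doubled[i : i + len(base)] for i in range(len(base))
    )


def test_order_overlaps_matches_bruteforce_sort():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(3, 9))
        pts = [
            ((float(rng.uniform(-40, 40)), float(rng.uniform(-40, 40))), "L")
            for _ in range(n)
        ]
        seq = order_overlaps_by_angle(pts)
        ox, oy = np.mean([p for p, _ in pts], axis=0)
        oracle = sorted(
            (math.atan2(y - oy, x - ox) % (2 * math.pi)) for (x, y), _ in pts
        )
        assert np.allclose(sorted(seq.angles), oracle, atol=1e-6)


def test_order_overlaps_too_few_points():
    with pytest.raises(TooFewOverlapsError):
        order_overlaps_by_angle([((0, 0), "L"), ((1, 1), "R")])


# --- cyclic edit distance ----------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("AAEI", "AAEI", 0),
        ("AAEI", "IEAA", 0),  # flip equivalence
        ("AAAA", "AAEI", 2),
        ("AAAA", "AAAAA", 1),
    ],
)
def test_cyclic_edit_distance_examples(a, b, expected):
    assert brute_cyclic(a, b) == expected  # oracle confirms the frozen value
    assert cyclic_edit_distance(a, b) == expected


def test_cyclic_edit_distance_agrees_with_oracle():
    rng = np.random.default_rng(3)
    letters = np.array(list("IEA"))
    for _ in range(150):
        a = "".join(rng.choice(letters, int(rng.integers(3, 10))))
        b = "".join(rng.choice(letters, int(rng.integers(3, 10))))
        assert cyclic_edit_distance(a, b) == brute_cyclic(a, b)


def test_cyclic_edit_distance_zero_iff_same_bracelet():
    rng = np.random.default_rng(4)
    letters = np.array(list("IEA"))
    for _ in range(100):
        a = "".join(rng.choice(letters, int(rng.integers(3, 9))))
        b = "".join(rng.choice(letters, len(a)))
        d = cyclic_edit_distance(a, b)
        same = canonical_form(a) == canonical_form(b)
        assert (d == 0) == same


def test_cyclic_edit_distance_length_bound():
    assert cyclic_edit_distance("III", "AAAAAAA") <= 7


# --- matching ----------------------------------------------------------------


def test_match_exact_entry_any_transform(catalog):
    entry = catalog.get("C1")  # EIEIEI
    s = entry.canonical.classes
    for q in (s, s[2:] + s[:2], s[::-1]):
        m = match_arrangement(TepalClassSequence(q), catalog)
        assert m.best.id == "C1"
        assert m.distance == 0


def test_match_tie_sets_ambiguous_flag():
    cat = ArrangementCatalog(
        [
            ArrangementClass("X1", TepalClassSequence("AAAA")),
            ArrangementClass("X2", TepalClassSequence("AAEI")),
        ]
    )
    # AAEA is one substitution from both AAAA and AAEI
    m = match_arrangement(TepalClassSequence("AAEA"), cat)
    assert m.distance == 1
    assert m.ambiguous
    assert m.best.id == "X1"  # first co-minimal entry wins
    assert {e.id for e in m.runners_up} == {"X1", "X2"}


def test_single_corruption_recovers_entry(catalog):
    """Corrupting one label of an entry whose nearest neighbor is >= 2
    edits away must still recover the original entry."""
    entry = catalog.get("E1")  # EIEIEIEI
    others = [e for e in catalog if e.id != "E1"]
    corrupted = "IIEIEIEI"
    assert min(cyclic_edit_distance(corrupted, e.canonical) for e in others) >= 2
    m = match_arrangement(TepalClassSequence(corrupted), catalog)
    assert m.best.id == "E1"
    assert not m.ambiguous


def test_match_dihedral_invariance(catalog):
    rng = np.random.default_rng(5)
    letters = np.array(list("IEA"))
    for _ in range(40):
        q = "".join(rng.choice(letters, int(rng.integers(4, 10))))
        ref = match_arrangement(TepalClassSequence(q), catalog).best.id
        for i in range(len(q)):
            rot = q[i:] + q[:i]
            for t in (rot, rot[::-1]):
                assert match_arrangement(TepalClassSequence(t), catalog).best.id == ref


# --- enumeration -------------------------------------------------------------


def test_enumerate_arrangements_counts():
    def brute(n):
        seen = set()
        for bits in range(2**n):
            lr = "".join("LR"[(bits >> i) & 1] for i in range(n))
            seen.add(canonical_form(lr_to_iea(lr).classes))
        return len(seen)

    assert len(enumerate_arrangements(3)) == brute(3) == 2
    assert len(enumerate_arrangements(4)) == brute(4) == 4


def test_enumerate_arrangements_canonical_and_monotone():
    prev = 0
    for n in range(3, 10):
        classes = enumerate_arrangements(n)
        for c in classes:
            assert c.canonical.classes == canonical_form(c.canonical.classes)
        assert len(classes) >= prev
        prev = len(classes)


# --- catalog loading ---------------------------------------------------------


def test_default_catalog_shape(catalog):
    assert len(catalog) == 13
    lengths = [len(e.canonical.classes) for e in catalog]
    assert set(lengths) == {4, 5, 6, 7, 8, 9}
    for n in range(4, 10):
        assert 1 <= lengths.count(n) <= 3
    for e in catalog:
        s = e.canonical.classes
        assert s.count("I") == s.count("E")


def test_catalog_rejects_rotated_duplicates(tmp_path):
    f = tmp_path / "cat.tsv"
    f.write_text("X1\tIIEE\nX2\tIEEI\n")
    with pytest.raises(CatalogError, match="X2"):
        load_catalog(f)


def test_catalog_rejects_unbalanced_entry(tmp_path):
    f = tmp_path / "cat.tsv"
    f.write_text("X1\tIIAA\n")
    with pytest.raises(CatalogError, match="IIAA"):
        load_catalog(f)


def test_catalog_parse_error_names_line(tmp_path):
    f = tmp_path / "cat.tsv"
    f.write_text("X1\tAAEI\nnonsense line here extra\n")
    with pytest.raises(CatalogError, match="2"):
        load_catalog(f)
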