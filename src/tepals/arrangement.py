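"""Circular tepal-arrangement representation and catalog matching.

An arrangement is read off a flower as follows: each detected overlap
between two neighboring tepals carries an interior-exterior label, ``L``
(left tepal in front) or ``R`` (right tepal in front).  Ordering the
labels clockwise by angle around the flower centroid gives a circular
``L/R`` permutation; consecutive label pairs convert to per-tepal classes
``I`` (internal: the tepal sits above both neighbors), ``E`` (external:
below both) or ``A`` (alternating).  The resulting circular ``I/E/A``
string, considered up to rotation and reflection (bracelet equivalence),
is matched against a catalog of named reference arrangements by cyclic
edit distance.

The local linear edit distance is delegated to :mod:`edlib`; the cyclic
and dihedral minimization over rotations and the reversal is done here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import edlib
import numpy as np

from .errors import CatalogError, InvalidInputError, TooFewOverlapsError

__all__ = [
    "OverlapSequence",
    "TepalClassSequence",
    "ArrangementClass",
    "ArrangementCatalog",
    "MatchResult",
    "canonical_form",
    "order_overlaps_by_angle",
    "lr_to_iea",
    "iea_to_lr",
    "cyclic_edit_distance",
    "match_arrangement",
    "enumerate_arrangements",
    "load_catalog",
]

_LR = frozenset("LR")
_IEA = frozenset("IEA")


@dataclass(frozen=True)
class OverlapSequence:
    """Circular ``L/R`` labels sorted by increasing angle about ``origin``.

    Angles are ``atan2`` with image axes (y down), measured from the
    rightward horizontal; increasing angle is clockwise on screen.
    """

    labels: tuple[str, ...]
    angles: tuple[float, ...]
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.labels) < 3:
            raise TooFewOverlapsError(
                f"need at least 3 labeled overlaps, got {len(self.labels)}"
            )
        if len(self.labels) != len(self.angles):
            raise InvalidInputError("one angle per label required")
        if not set(self.labels) <= _LR:
            raise InvalidInputError(f"labels must be L or R, got {self.labels}")
        if any(b <= a for a, b in zip(self.angles, self.angles[1:])):
            raise InvalidInputError("angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TepalClassSequence:
    """Circular permutation of per-tepal ``I/E/A`` classes."""

    classes: str

    def __post_init__(self) -> None:
        if not self.classes:
            raise InvalidInputError("empty class sequence")
        if not set(self.classes) <= _IEA:
            raise InvalidInputError(f"classes must be I, E or A: {self.classes!r}")

    def __len__(self) -> int:
        return len(self.classes)

    def __str__(self) -> str:
        return self.classes

    def canonical(self) -> str:
        return canonical_form(self.classes)


def canonical_form(s: str) -> str:
    """Lexicographically least string over all rotations of ``s`` and of
    its reversal — a canonical representative of the bracelet class."""
    n = len(s)
    variants = [s[i:] + s[:i] for i in range(n)]
    r = s[::-1]
    variants += [r[i:] + r[:i] for i in range(n)]
    return min(variants)


@dataclass(frozen=True)
class ArrangementClass:
    """A named reference arrangement, stored in canonical dihedral form."""

    id: str
    canonical: TepalClassSequence

    def __post_init__(self) -> None:
        c = self.canonical.classes
        if c != canonical_form(c):
            object.__setattr__(self, "canonical", TepalClassSequence(canonical_form(c)))


@dataclass
class ArrangementCatalog:
    entries: list[ArrangementClass] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            c = e.canonical.classes
            if c in seen:
                raise CatalogError(
                    f"entries {seen[c]!r} and {e.id!r} are the same arrangement ({c})"
                )
            seen[c] = e.id

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, entry_id: str) -> ArrangementClass:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)


@dataclass(frozen=True)
class MatchResult:
    best: ArrangementClass
    distance: int
    ambiguous: bool
    runners_up: tuple[ArrangementClass, ...] = ()


def order_overlaps_by_angle(points, mask: np.ndarray | None = None) -> OverlapSequence:
    """Sort labeled overlap points clockwise about the flower centroid.

    ``points`` is a sequence of objects with ``position`` (x, y) and
    ``label`` attributes (or ``(position, label)`` pairs).  The origin is
    the foreground-mask centroid when a mask is given, otherwise the
    centroid of the points themselves.  Ties in angle break by radius,
    then x.
    """
    items = []
    for p in points:
        if hasattr(p, "position"):
            items.append((tuple(p.position), p.label))
        else:
            pos, label = p
            items.append((tuple(pos), label))
    if len(items) < 3:
        raise TooFewOverlapsError(f"need at least 3 points, got {len(items)}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise InvalidInputError("empty mask")
        ys, xs = np.nonzero(mask)
        origin = (float(xs.mean()), float(ys.mean()))
    else:
        arr = np.array([pos for pos, _ in items], dtype=float)
        origin = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
    keyed = []
    for (x, y), label in items:
        dx, dy = x - origin[0], y - origin[1]
        ang = math.atan2(dy, dx) % (2 * math.pi)
        keyed.append((ang, math.hypot(dx, dy), x, label))
    keyed.sort()
    eps = 1e-12
    angles, labels = [], []
    for ang, _r, _x, label in keyed:
        if angles and ang <= angles[-1]:
            ang = angles[-1] + eps  # strictly increasing after tie-break
        angles.append(ang)
        labels.append(label)
    return OverlapSequence(tuple(labels), tuple(angles), origin)


_PAIR_TO_CLASS = {("R", "L"): "I", ("L", "R"): "E", ("L", "L"): "A", ("R", "R"): "A"}


def lr_to_iea(seq) -> TepalClassSequence:
    """Convert a circular ``L/R`` overlap permutation to per-tepal classes.

    Tepal ``i`` sits between consecutive overlaps ``(o_i, o_{i+1 mod n})``;
    with clockwise ordering, ``(R, L) -> I``, ``(L, R) -> E`` and
    homogeneous pairs ``-> A``.  The mirrored reading differs from this one
    by a flip of the whole sequence, which downstream matching absorbs.
    """
    labels = seq.labels if isinstance(seq, OverlapSequence) else tuple(seq)
    if not set(labels) <= _LR:
        raise InvalidInputError(f"labels must be L or R: {labels}")
    n = len(labels)
    out = [_PAIR_TO_CLASS[(labels[i], labels[(i + 1) % n])] for i in range(n)]
    return TepalClassSequence("".join(out))


def iea_to_lr(arrangement) -> str:
    """A circular ``L/R`` string whose conversion realizes ``arrangement``
    (up to rotation/reflection).  Raises if the arrangement is not
    realizable (its non-A classes must alternate I/E around the circle)."""
    target = arrangement.classes if isinstance(arrangement, TepalClassSequence) else str(arrangement)
    want = canonical_form(target)
    n = len(target)
    for bits in range(2 ** n):
        lr = "".join("LR"[(bits >> i) & 1] for i in range(n))
        if lr_to_iea(lr).canonical() == want:
            return lr
    raise InvalidInputError(f"arrangement {target!r} has no L/R realization")


def _linear_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def cyclic_edit_distance(a, b) -> int:
    """Minimum unit-cost edit distance between circular sequences ``a`` and
    ``b`` over all rotations of ``a`` and of its reversal (the query is
    rotated/flipped; ``b`` stays fixed)."""
    sa = a.classes if isinstance(a, TepalClassSequence) else str(a)
    sb = b.classes if isinstance(b, TepalClassSequence) else str(b)
    if not sa or not sb:
        raise InvalidInputError("sequences must be non-empty")
    best = None
    for s in (sa, sa[::-1]):
        for i in range(len(s)):
            d = _linear_distance(s[i:] + s[:i], sb)
            if best is None or d < best:
                best = d
                if best == 0:
                    return 0
    return best


def match_arrangement(seq, catalog: ArrangementCatalog) -> MatchResult:
    """Nearest catalog entry by cyclic edit distance.

    Ties set the ``ambiguous`` flag; the winner is the first co-minimal
    entry in catalog order and all co-minimal entries are reported as
    runners-up.
    """
    if len(catalog) == 0:
        raise InvalidInputError("empty catalog")
    dists = [(cyclic_edit_distance(seq, e.canonical), e) for e in catalog]
    dmin = min(d for d, _ in dists)
    winners = [e for d, e in dists if d == dmin]
    return MatchResult(
        best=winners[0],
        distance=dmin,
        ambiguous=len(winners) > 1,
        runners_up=tuple(winners),
    )


def enumerate_arrangements(n: int) -> list[ArrangementClass]:
    """All conceivable arrangements of ``n`` tepals: every circular ``L/R``
    string converted to classes and deduplicated under rotation+reflection.
    Entry ids are the canonical strings themselves."""
    if n < 3:
        raise InvalidInputError("need at least 3 tepals")
    seen = set()
    out = []
    for bits in range(2 ** n):
        lr = "".join("LR"[(bits >> i) & 1] for i in range(n))
        c = lr_to_iea(lr).canonical()
        if c not in seen:
            seen.add(c)
            out.append(ArrangementClass(id=c, canonical=TepalClassSequence(c)))
    return sorted(out, key=lambda e: e.id)


_DEFAULT_CATALOG = "data/default_catalog.tsv"


def load_catalog(path: str | Path | None = None) -> ArrangementCatalog:
    """Load an arrangement catalog from a tab-separated file.

    Format: one ``ID<TAB>IEA-string`` entry per line, ``#`` comments.
    Entries are validated (``I``/``E`` counts must balance — every circular
    L/R permutation yields as many internal as external tepals) and
    canonicalized; duplicate bracelet classes are rejected.  Without a
    path, the package's default 13-entry catalog (4-9 tepals) is loaded.
    """
    if path is None:
        text = (resources.files("tepals") / _DEFAULT_CATALOG).read_text()
        source = "<default catalog>"
    else:
        text = Path(path).read_text()
        source = str(path)
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise CatalogError(f"{source}:{lineno}: expected 'ID<TAB>IEA-string': {raw!r}")
        entry_id, classes = parts[0], parts[1].upper()
        if not set(classes) <= _IEA:
            raise CatalogError(f"{source}:{lineno}: entry {entry_id!r} has invalid classes {classes!r}")
        if classes.count("I") != classes.count("E"):
            raise CatalogError(
                f"{source}:{lineno}: entry {entry_id!r} ({classes}) violates count(I) == count(E)"
            )
        entries.append(ArrangementClass(id=entry_id, canonical=TepalClassSequence(classes)))
    try:
        return ArrangementCatalog(entries)
    except CatalogError as exc:
        raise CatalogError(f"{source}: {exc}") from None
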