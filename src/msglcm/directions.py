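"""Enumeration of canonical digital directions on the 2D/3D voxel lattice.

A *digital direction* is a nonzero integer offset vector.  Because the
co-occurrence measures used downstream are symmetric, a direction and its
antipode produce identical statistics once the matrix is symmetrized, so
only one representative per antipodal pair is kept.  The canonical
half-space rule (see :func:`canonicalize`) is chosen so that the familiar
13-vector set of 3D texture analysis comes out verbatim:

    (0,0,1) (0,1,0) (1,0,0) (0,1,1) (1,0,1) (1,1,0) (-1,1,0)
    (0,1,-1) (1,0,-1) (1,1,1) (-1,1,1) (1,1,-1) (-1,1,-1)

Offsets are written ``(dx, dy)`` in 2D and ``(dx, dy, dz)`` in 3D and are
applied in array-index space (axis 0 = x, axis 1 = y, axis 2 = z).

"Displacement <= D" is measured in the Chebyshev (max-component) norm: the
set of directions reachable at displacement D is the half of the punctured
Chebyshev ball of radius D, giving 13 / 62 / 171 directions in 3D for
D = 1 / 2 / 3 with collinear duplicates, and 13 / 49 / 145 without.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Sequence

__all__ = [
    "Direction",
    "DirectionSet",
    "canonicalize",
    "is_primitive",
    "enumerate_directions",
]

Direction = tuple[int, ...]


def _validate_vector(v: Sequence[int]) -> tuple[int, ...]:
    t = tuple(int(c) for c in v)
    if len(t) not in (2, 3):
        raise ValueError(f"direction must have 2 or 3 components, got {len(t)}")
    if all(c == 0 for c in t):
        raise ValueError("zero vector is not a valid direction")
    return t


def canonicalize(v: Sequence[int]) -> Direction:
    """Return the canonical representative of the antipodal pair {v, -v}.

    3D rule: keep ``v`` if ``dy > 0``, or ``dy == 0 and dx > 0``, or
    ``dx == dy == 0 and dz > 0``; otherwise return ``-v``.
    2D rule: keep ``v`` if ``dx > 0``, or ``dx == 0 and dy > 0``.

    ``canonicalize(v) == canonicalize(-v)`` for every nonzero integer
    vector.
    """
    t = _validate_vector(v)
    if len(t) == 2:
        dx, dy = t
        keep = dx > 0 or (dx == 0 and dy > 0)
    else:
        dx, dy, dz = t
        keep = dy > 0 or (dy == 0 and dx > 0) or (dy == 0 and dx == 0 and dz > 0)
    return t if keep else tuple(-c for c in t)


def is_canonical(v: Sequence[int]) -> bool:
    """True iff ``v`` already is the canonical member of its antipodal pair."""
    t = _validate_vector(v)
    return canonicalize(t) == t


def is_primitive(v: Sequence[int]) -> bool:
    """True iff the components of ``v`` have greatest common divisor 1.

    Non-primitive vectors are integer multiples of a shorter direction and
    sample the same lattice ray; they are the "duplicate angles" removed by
    the dedup option of :func:`enumerate_directions`.
    """
    t = _validate_vector(v)
    return math.gcd(*(abs(c) for c in t)) == 1


def _sort_key(v: Direction) -> tuple:
    cheb = max(abs(c) for c in v)
    if len(v) == 2:
        return (cheb, v[1], v[0])
    return (cheb, v[1], v[0], v[2])


@dataclass(frozen=True)
class DirectionSet:
    """An ordered set of canonical directions up to a Chebyshev bound.

    Members are sorted by (Chebyshev norm, then lexicographically on
    (dy, dx, dz)), which makes the enumeration deterministic and makes the
    set for displacement ``D`` a prefix-closed subset of the set for
    ``D + 1``.
    """

    dims: int
    max_displacement: int
    dedup: bool
    members: tuple[Direction, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Direction]:
        return iter(self.members)

    def __getitem__(self, i: int) -> Direction:
        return self.members[i]

    def to_text(self) -> str:
        """One space-separated integer vector per line."""
        return "\n".join(" ".join(str(c) for c in v) for v in self.members)

    @classmethod
    def from_text(cls, text: str) -> "DirectionSet":
        members = tuple(
            _validate_vector(line.split())
            for line in text.strip().splitlines()
            if line.strip()
        )
        if not members:
            raise ValueError("empty direction table")
        dims = len(members[0])
        maxd = max(max(abs(c) for c in v) for v in members)
        dedup = all(is_primitive(v) for v in members)
        return cls(dims=dims, max_displacement=maxd, dedup=dedup, members=members)


def enumerate_directions(
    dims: int, max_displacement: int, dedup: bool = False
) -> DirectionSet:
    """Enumerate canonical lattice directions with Chebyshev norm <= D.

    Parameters
    ----------
    dims
        2 or 3.
    max_displacement
        Chebyshev radius D >= 1 of the enumeration.
    dedup
        If True, drop non-primitive vectors (collinear duplicates of a
        shorter direction), e.g. (2, 0, 0) which repeats the (1, 0, 0) ray.

    Returns
    -------
    DirectionSet
        Without dedup the 3D count is ((2D+1)^3 - 1) / 2; at D = 1 this is
        the classical 13-direction set (4 directions in 2D).
    """
    if dims not in (2, 3):
        raise ValueError(f"dims must be 2 or 3, got {dims}")
    if max_displacement < 1:
        raise ValueError(f"max_displacement must be >= 1, got {max_displacement}")
    rng = range(-max_displacement, max_displacement + 1)
    seen: set[Direction] = set()
    for v in product(rng, repeat=dims):
        if all(c == 0 for c in v):
            continue
        c = canonicalize(v)
        if dedup and not is_primitive(c):
            continue
        seen.add(c)
    members = tuple(sorted(seen, key=_sort_key))
    return DirectionSet(
        dims=dims, max_displacement=max_displacement, dedup=dedup, members=members
    )
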