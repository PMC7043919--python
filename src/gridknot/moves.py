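"""Grid moves: strand passages, juxtaposition geometry, simplification.

A type II topoisomerase action (a strand passage, i.e. a crossing change)
is modelled by an *interleaving commutation*: exchanging two adjacent rows
or columns whose segment intervals partially overlap -- each interval
contains exactly one endpoint of the other in its open interior.
Commuting a non-interleaved adjacent pair deforms the curve without
changing its knot type; commuting an interleaved pair passes one strand
through the other.

Adjacency is non-cyclic: the candidate pairs are ``(i, i+1)`` for
``0 <= i < n-1`` only (the board is planar, there is no wrap-around pair).

The local geometry of an interleaved pair is classified by where the two
*inner* endpoints' perpendicular segments go:

* ``hooked`` -- both bend across the neighbouring line; the two resulting
  crossings bound a width-1 rectangle whose integer area (= the distance
  between the inner endpoints) quantifies how tightly hooked the site is;
* ``free``   -- both bend away (no crossings between the pair);
* ``mixed``  -- one of each.

``strongly hooked`` means hooked with the rectangle an elementary square
(area 1).  Restricting passages to (strongly) hooked sites is the
geometric-selection model of topoisomerase II unknotting.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .grid import GridDiagram, transpose

__all__ = [
    "Juxtaposition",
    "interleaved",
    "commute",
    "classify_juxtaposition",
    "passage_sites",
    "destabilize_once",
    "simplify",
]

Axis = Literal["col", "row"]


@dataclass(frozen=True)
class Juxtaposition:
    """Classification of one adjacent row/column pair."""

    axis: Axis
    index: int
    interleaved: bool
    geometry: Literal["hooked", "mixed", "free", "not-interleaved"]
    area: Optional[int]  # defined iff hooked
    strongly_hooked: bool  # hooked with area 1


def _check_index(g: GridDiagram, i: int) -> None:
    if not 0 <= i < g.n - 1:
        raise IndexError(f"adjacent-pair index {i} out of range for n={g.n}")


def _col_intervals(g: GridDiagram, i: int) -> tuple[int, int, int, int]:
    lo1, hi1 = g.col_span(i)
    lo2, hi2 = g.col_span(i + 1)
    return lo1, hi1, lo2, hi2


def interleaved(g: GridDiagram, axis: Axis, i: int) -> bool:
    """True iff lines ``i`` and ``i+1`` strictly interleave.

    The closed intervals must each contain exactly one endpoint of the
    other in their open interior; a shared endpoint (the interiors then
    meet trivially) disqualifies the pair.
    """
    _check_index(g, i)
    h = g if axis == "col" else transpose(g)
    lo1, hi1, lo2, hi2 = _col_intervals(h, i)
    return (lo1 < lo2 < hi1 < hi2) or (lo2 < lo1 < hi2 < hi1)


def commute(g: GridDiagram, axis: Axis, i: int) -> GridDiagram:
    """Exchange adjacent lines ``i`` and ``i+1``; an involution.

    At an interleaved pair this is a strand passage (the knot type may
    change); otherwise it is a topology-preserving deformation.  Grid
    number and component count are always preserved.
    """
    _check_index(g, i)
    if axis == "col":
        xs = list(g.xs)
        os_ = list(g.os)
        xs[i], xs[i + 1] = xs[i + 1], xs[i]
        os_[i], os_[i + 1] = os_[i + 1], os_[i]
        return GridDiagram(n=g.n, xs=tuple(xs), os=tuple(os_))
    swap = {i: i + 1, i + 1: i}
    return GridDiagram(
        n=g.n,
        xs=tuple(swap.get(r, r) for r in g.xs),
        os=tuple(swap.get(r, r) for r in g.os),
    )


def classify_juxtaposition(g: GridDiagram, axis: Axis, i: int) -> Juxtaposition:
    """Geometry class (hooked / mixed / free) of an adjacent pair."""
    _check_index(g, i)
    h = g if axis == "col" else transpose(g)
    lo1, hi1, lo2, hi2 = _col_intervals(h, i)
    case1 = lo1 < lo2 < hi1 < hi2
    case2 = lo2 < lo1 < hi2 < hi1
    if not (case1 or case2):
        return Juxtaposition(axis, i, False, "not-interleaved", None, False)
    # Inner endpoints: the endpoint of each segment lying strictly inside
    # the other's interval.
    y1 = hi1 if case1 else lo1  # inner endpoint of line i
    y2 = lo2 if case1 else hi2  # inner endpoint of line i+1
    # Perpendicular segment attached at each inner endpoint: find the
    # partner marking of that row; "inward" = it extends across the
    # neighbouring line (producing a crossing with it).
    d1 = h.o_col(y1) if h.xs[i] == y1 else h.x_col(y1)
    d2 = h.o_col(y2) if h.xs[i + 1] == y2 else h.x_col(y2)
    inward1 = d1 > i + 1
    inward2 = d2 < i
    if inward1 and inward2:
        area = abs(y1 - y2)
        return Juxtaposition(axis, i, True, "hooked", area, area == 1)
    if not inward1 and not inward2:
        return Juxtaposition(axis, i, True, "free", None, False)
    return Juxtaposition(axis, i, True, "mixed", None, False)


def passage_sites(
    g: GridDiagram,
    policy: str = "unbiased",
    max_area: int = 1,
) -> list[tuple[Axis, int]]:
    """Sites where the passage policy permits a strand passage.

    ``unbiased`` fires at every interleaved adjacent pair (both axes);
    ``hooked`` only at pairs classified hooked with rectangle area at most
    ``max_area`` (``max_area=1`` is the strongly hooked restriction).
    """
    if policy not in ("unbiased", "hooked"):
        raise ValueError(f"unknown passage policy {policy!r}")
    sites: list[tuple[Axis, int]] = []
    for axis in ("col", "row"):
        for i in range(g.n - 1):
            j = classify_juxtaposition(g, axis, i)
            if policy == "unbiased":
                if j.interleaved:
                    sites.append((axis, i))
            else:
                if j.geometry == "hooked" and j.area is not None and j.area <= max_area:
                    sites.append((axis, i))
    return sites


# -- destabilization and simplification ---------------------------------


def destabilize_once(g: GridDiagram) -> Optional[GridDiagram]:
    """Remove one row and one column if a destabilizing corner exists.

    A destabilizable corner is a 2x2 block of squares holding exactly
    three markings.  The marking diagonally opposite the empty square is
    the corner of an L; deleting the L's three markings and placing a
    single marking in the (former) empty square merges the two lines,
    producing an equivalent diagram of grid number n-1.  Returns ``None``
    when no such block exists.
    """
    if g.n < 3:
        return None
    n = g.n
    mark: dict[tuple[int, int], str] = {}
    for c in range(n):
        mark[(c, g.xs[c])] = "X"
        mark[(c, g.os[c])] = "O"
    for c in range(n - 1):
        for r in range(n - 1):
            block = [(c, r), (c, r + 1), (c + 1, r), (c + 1, r + 1)]
            occupied = [p for p in block if p in mark]
            if len(occupied) != 3:
                continue
            (hole,) = (p for p in block if p not in mark)
            ha, hb = hole
            a = c + 1 if ha == c else c  # column holding two markings
            b = r + 1 if hb == r else r  # row holding two markings
            t_new = mark[(a, hb)]  # == mark[(ha, b)], opposite of corner
            assert mark[(ha, b)] == t_new and mark[(a, b)] != t_new
            new_marks = dict(mark)
            for p in occupied:
                del new_marks[p]
            new_marks[hole] = t_new
            xs = [-1] * (n - 1)
            os_ = [-1] * (n - 1)
            for (cc, rr), t in new_marks.items():
                c2 = cc - (cc > a)
                r2 = rr - (rr > b)
                if t == "X":
                    xs[c2] = r2
                else:
                    os_[c2] = r2
            return GridDiagram(n=n - 1, xs=tuple(xs), os=tuple(os_))
    return None


def _topology_preserving_sites(g: GridDiagram) -> list[tuple[Axis, int]]:
    sites: list[tuple[Axis, int]] = []
    for axis in ("col", "row"):
        for i in range(g.n - 1):
            if not interleaved(g, axis, i):
                sites.append((axis, i))
    return sites


def simplify(
    g: GridDiagram,
    max_steps: Optional[int] = None,
    seed: int = 0,
) -> GridDiagram:
    """Reduce grid number by destabilizations, searching with a bounded
    seeded random walk over topology-preserving commutations.

    The output represents the same knot as the input and has grid number
    at most the input's.  This is a heuristic reducer (typical-case GN
    reduction before exponential-cost invariant computation), not a
    normal-form algorithm: it never certifies minimality.
    """
    rng = random.Random(seed)
    best = g
    steps_left = max_steps if max_steps is not None else 10_000
    while steps_left > 0:
        d = destabilize_once(best)
        if d is not None:
            best = d
            steps_left -= 1
            continue
        walk = best
        found = None
        budget = min(50 * best.n, steps_left)
        for _ in range(budget):
            steps_left -= 1
            sites = _topology_preserving_sites(walk)
            if not sites:
                break
            axis, i = rng.choice(sites)
            walk = commute(walk, axis, i)
            d = destabilize_once(walk)
            if d is not None:
                found = d
                break
        if found is None:
            return best
        best = found
    return best
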