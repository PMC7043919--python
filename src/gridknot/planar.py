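"""Planar-diagram (PD) codes extracted from grid diagrams.

A PD code lists the diagram's crossings as 4-valent vertices with the
incident arcs recorded in geometric (compass) order, plus the over-strand
flag; arcs are the pieces of the curve between consecutive crossing
passages.  The grid convention makes the vertical strand the overpass at
every crossing, so the over strand always occupies the N/S slots and the
under strand the E/W slots.

This is the bridge from the grid's combinatorics to invariants computed
by skein-type state sums (the Kauffman bracket) and to the Wirtinger /
Fox-calculus Alexander matrix, which serves as an independent cross-check
of the winding-number-matrix Alexander computation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grid import GridDiagram, MultiComponentError, component_count, crossings

__all__ = ["PDCrossing", "PlanarDiagram", "to_planar_diagram"]


@dataclass(frozen=True)
class PDCrossing:
    """One crossing: arc ids at the four compass slots, plus strand data.

    ``north``/``south`` carry the (over) vertical strand, ``east``/``west``
    the (under) horizontal strand.  ``v_up`` / ``h_right`` give the travel
    direction of each strand under the X->O (vertical), O->X (horizontal)
    orientation; ``sign`` is the usual oriented crossing sign.
    """

    north: int
    east: int
    south: int
    west: int
    v_up: bool
    h_right: bool

    @property
    def sign(self) -> int:
        # Over strand vertical: rotating it onto the under strand tells
        # the handedness; equal "directions" give one sign, opposite the
        # other.  (A global sign flip is a mirror image; knot types are
        # mirror-lumped downstream, but the convention must be internally
        # consistent with the bracket smoothing rule in invariants.py.)
        return 1 if self.v_up == self.h_right else -1

    @property
    def over_in(self) -> int:
        return self.south if self.v_up else self.north

    @property
    def over_out(self) -> int:
        return self.north if self.v_up else self.south

    @property
    def under_in(self) -> int:
        return self.west if self.h_right else self.east

    @property
    def under_out(self) -> int:
        return self.east if self.h_right else self.west


@dataclass(frozen=True)
class PlanarDiagram:
    crossings: tuple[PDCrossing, ...]
    arc_count: int
    components: int

    @property
    def writhe(self) -> int:
        return sum(c.sign for c in self.crossings)


def to_planar_diagram(g: GridDiagram) -> PlanarDiagram:
    """Traverse the grid's knot and emit its PD code.

    Raises :class:`MultiComponentError` on links.  A crossing-free
    diagram yields an empty PD (``arc_count`` 0): the round unknot.
    """
    if component_count(g) != 1:
        raise MultiComponentError("PD extraction requires a single component")
    n = g.n
    cross_at = {(c.col, c.row): k for k, c in enumerate(crossings(g))}
    ncross = len(cross_at)
    if ncross == 0:
        return PlanarDiagram(crossings=(), arc_count=0, components=1)

    # Walk the curve: X -> O along each column, then O -> X along the row
    # of that O, and so on until closure.  Record every crossing passage
    # as (crossing id, role, direction flag) in traversal order.
    passages: list[tuple[int, str, bool]] = []
    c = 0
    for _ in range(n):
        r_from, r_to = g.xs[c], g.os[c]
        up = r_to > r_from
        rows = range(r_from + 1, r_to) if up else range(r_from - 1, r_to, -1)
        for r in rows:
            if (c, r) in cross_at:
                passages.append((cross_at[(c, r)], "v", up))
        r = r_to
        c_from, c_to = g.o_col(r), g.x_col(r)
        right = c_to > c_from
        cols = range(c_from + 1, c_to) if right else range(c_from - 1, c_to, -1)
        for cc in cols:
            if (cc, r) in cross_at:
                passages.append((cross_at[(cc, r)], "h", right))
        c = c_to

    assert len(passages) == 2 * ncross
    # Arc k runs from passage k to passage k+1 (cyclically): arc k is the
    # *outgoing* arc of passage k and the *incoming* arc of passage k+1.
    incoming: dict[tuple[int, str], int] = {}
    outgoing: dict[tuple[int, str], int] = {}
    m = len(passages)
    for k, (cid, role, _) in enumerate(passages):
        outgoing[(cid, role)] = k
        incoming[(cid, role)] = (k - 1) % m

    pd: list[PDCrossing] = []
    for cid in range(ncross):
        _, _, v_up = next(p for p in passages if p[0] == cid and p[1] == "v")
        _, _, h_right = next(p for p in passages if p[0] == cid and p[1] == "h")
        v_in, v_out = incoming[(cid, "v")], outgoing[(cid, "v")]
        h_in, h_out = incoming[(cid, "h")], outgoing[(cid, "h")]
        north = v_out if v_up else v_in
        south = v_in if v_up else v_out
        east = h_out if h_right else h_in
        west = h_in if h_right else h_out
        pd.append(
            PDCrossing(
                north=north, east=east, south=south, west=west,
                v_up=v_up, h_right=h_right,
            )
        )
    return PlanarDiagram(crossings=tuple(pd), arc_count=m, components=1)
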