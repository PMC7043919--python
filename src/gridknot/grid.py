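"""Grid diagrams (arc presentations) of knots.

A grid diagram of size ``n`` is an ``n x n`` board carrying ``2n`` markings:
one X and one O in every row and every column.  Joining the two markings of
each column by a vertical segment and the two markings of each row by a
horizontal segment, with the convention that vertical segments always pass
*over* horizontal ones, yields a knot (or link) projection.  The whole
diagram is therefore determined by a pair of permutations:

* ``xs[c]`` -- the row of the X marking in column ``c``;
* ``os[c]`` -- the row of the O marking in column ``c``.

Indexing is 0-based with row 0 at the bottom of the board.  Orientation is
never used downstream (knot types are mirror-lumped), but when one is
needed internally the curve is directed X -> O along columns and O -> X
along rows.

A grid with ``n`` columns models a closed polymer of roughly ``2n``
statistical segments; ``n`` is called the grid number (GN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "GridError",
    "NotAPermutation",
    "CoincidentMarkings",
    "MultiComponentError",
    "GridDiagram",
    "Crossing",
    "validate",
    "component_count",
    "canonical_form",
    "crossings",
    "transpose",
    "mirror",
    "render_ascii",
    "parse_ascii",
    "parse_grid_string",
    "format_grid_string",
]


class GridError(ValueError):
    """Base class for malformed grid-diagram input."""


class NotAPermutation(GridError):
    """A marking sequence repeats or omits a row."""


class CoincidentMarkings(GridError):
    """A column's X and O occupy the same square."""


class MultiComponentError(GridError):
    """An operation restricted to knots received a multi-component link."""


@dataclass(frozen=True)
class Crossing:
    """A transverse intersection of a vertical and a horizontal segment.

    The vertical segment (in column ``col``) is always the overpass.
    """

    col: int
    row: int


@dataclass(frozen=True)
class GridDiagram:
    """An immutable, validated grid diagram.

    Use :func:`validate` (or :meth:`GridDiagram.from_sequences`) to build
    one from raw sequences; the constructor itself performs no checks.
    """

    n: int
    xs: tuple[int, ...]
    os: tuple[int, ...]

    # -- construction ----------------------------------------------------

    @classmethod
    def from_sequences(cls, xs: Sequence[int], os: Sequence[int]) -> "GridDiagram":
        return validate(xs, os)

    # -- basic queries ---------------------------------------------------

    @property
    def components(self) -> int:
        return component_count(self)

    @property
    def is_knot(self) -> bool:
        """True when the diagram has a single closed component."""
        return component_count(self) == 1

    def x_col(self, row: int) -> int:
        """Column of the X marking in ``row``."""
        return self.xs.index(row)

    def o_col(self, row: int) -> int:
        """Column of the O marking in ``row``."""
        return self.os.index(row)

    def col_span(self, c: int) -> tuple[int, int]:
        """(low, high) rows of the vertical segment in column ``c``."""
        a, b = self.xs[c], self.os[c]
        return (a, b) if a < b else (b, a)

    def row_span(self, r: int) -> tuple[int, int]:
        """(low, high) columns of the horizontal segment in row ``r``."""
        a, b = self.x_col(r), self.o_col(r)
        return (a, b) if a < b else (b, a)

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        yield self.xs
        yield self.os

    def __repr__(self) -> str:  # compact; the board itself via render_ascii
        return f"GridDiagram(n={self.n}, xs={self.xs}, os={self.os})"


def validate(xs: Sequence[int], os: Sequence[int]) -> GridDiagram:
    """Check and wrap a pair of marking sequences.

    Raises :class:`NotAPermutation` when a sequence is not a bijection on
    ``{0..n-1}`` and :class:`CoincidentMarkings` when a column's X and O
    coincide.  Multi-component diagrams (links) are *valid* here -- they
    are merely flagged and excluded from knot analyses downstream.
    """
    xs = tuple(int(v) for v in xs)
    os = tuple(int(v) for v in os)
    n = len(xs)
    if len(os) != n:
        raise GridError(f"marking sequences differ in length: {len(xs)} vs {len(os)}")
    if n < 2:
        raise GridError(f"grid number must be >= 2, got {n}")
    for name, seq in (("xs", xs), ("os", os)):
        if sorted(seq) != list(range(n)):
            raise NotAPermutation(f"{name}={seq} is not a permutation of 0..{n - 1}")
    for c in range(n):
        if xs[c] == os[c]:
            raise CoincidentMarkings(f"column {c}: X and O both in row {xs[c]}")
    return GridDiagram(n=n, xs=xs, os=os)


def component_count(g: GridDiagram) -> int:
    """Number of closed components: cycles of the permutation xs o os^-1."""
    o_inv = [0] * g.n
    for c, r in enumerate(g.os):
        o_inv[r] = c
    seen = [False] * g.n
    cycles = 0
    for start in range(g.n):
        if seen[start]:
            continue
        cycles += 1
        r = start
        while not seen[r]:
            seen[r] = True
            r = g.xs[o_inv[r]]
    return cycles


def canonical_form(g: GridDiagram) -> GridDiagram:
    """Representative of ``g`` modulo exchanging the X and O marking sets.

    Swapping X and O markings leaves the projected curve unchanged, so
    diagrams are counted modulo that swap: the canonical form is the
    lexicographically smaller of ``(xs, os)`` and ``(os, xs)``.  No further
    quotient (no translation or rotation) is taken; this is the convention
    under which there are ``n!(n-1)!/2`` distinct knot diagrams of size n.
    """
    if (g.os, g.xs) < (g.xs, g.os):
        return GridDiagram(n=g.n, xs=g.os, os=g.xs)
    return g


def crossings(g: GridDiagram) -> list[Crossing]:
    """All segment intersections, ordered by (col, row).

    A crossing sits at ``(c, r)`` when row ``r`` lies strictly inside the
    vertical segment of column ``c`` and column ``c`` lies strictly inside
    the horizontal segment of row ``r``.
    """
    out: list[Crossing] = []
    spans = [g.row_span(r) for r in range(g.n)]
    for c in range(g.n):
        lo, hi = g.col_span(c)
        for r in range(lo + 1, hi):
            a, b = spans[r]
            if a < c < b:
                out.append(Crossing(col=c, row=r))
    return out


def transpose(g: GridDiagram) -> GridDiagram:
    """Reflect across the main diagonal: marking (c, r) -> (r, c).

    Rows become columns, so row-pair operations on ``g`` are column-pair
    operations on ``transpose(g)``.  (The reflection also exchanges the
    over/under convention, i.e. it mirrors the knot; mirror types are
    lumped throughout, so this is harmless.)
    """
    xi = [0] * g.n
    oi = [0] * g.n
    for c in range(g.n):
        xi[g.xs[c]] = c
        oi[g.os[c]] = c
    return GridDiagram(n=g.n, xs=tuple(xi), os=tuple(oi))


def mirror(g: GridDiagram) -> GridDiagram:
    """Mirror image: reverse the column order."""
    return GridDiagram(n=g.n, xs=tuple(reversed(g.xs)), os=tuple(reversed(g.os)))


# -- text round-trip -----------------------------------------------------


def render_ascii(g: GridDiagram) -> str:
    """Fixed-width board drawing, top row printed first (row 0 at bottom).

    ``X``/``O`` are markings, ``|`` and ``-`` the segments, ``+`` a
    crossing (the vertical strand is the overpass).  ``parse_ascii``
    inverts this rendering exactly.
    """
    n = g.n
    board = [["." for _ in range(n)] for _ in range(n)]  # board[row][col]
    for r in range(n):
        a, b = g.row_span(r)
        for c in range(a + 1, b):
            board[r][c] = "-"
    for c in range(n):
        lo, hi = g.col_span(c)
        for r in range(lo + 1, hi):
            board[r][c] = "+" if board[r][c] == "-" else "|"
    for c in range(n):
        board[g.xs[c]][c] = "X"
        board[g.os[c]][c] = "O"
    return "\n".join(" ".join(board[r]) for r in range(n - 1, -1, -1))


def parse_ascii(text: str) -> GridDiagram:
    """Inverse of :func:`render_ascii` (only X/O positions are read)."""
    rows = [line.split() for line in text.strip("\n").splitlines()]
    n = len(rows)
    xs = [-1] * n
    os_ = [-1] * n
    for printed_r, cells in enumerate(rows):
        if len(cells) != n:
            raise GridError(f"line {printed_r}: expected {n} cells, got {len(cells)}")
        r = n - 1 - printed_r
        for c, ch in enumerate(cells):
            if ch == "X":
                xs[c] = r
            elif ch == "O":
                os_[c] = r
    return validate(xs, os_)


def parse_grid_string(text: str) -> GridDiagram:
    """Parse the compact CLI form ``"x=1,2,0;o=0,1,2"``."""
    parts: dict[str, list[int]] = {}
    for chunk in text.strip().split(";"):
        if "=" not in chunk:
            raise GridError(f"malformed grid string chunk: {chunk!r}")
        key, vals = chunk.split("=", 1)
        parts[key.strip().lower()] = [int(v) for v in vals.split(",")]
    if set(parts) != {"x", "o"}:
        raise GridError(f"grid string must define exactly x=... and o=..., got {sorted(parts)}")
    return validate(parts["x"], parts["o"])


def format_grid_string(g: GridDiagram) -> str:
    return "x=" + ",".join(map(str, g.xs)) + ";o=" + ",".join(map(str, g.os))
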