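"""Generate the packaged knot-invariant lookup table.

Writes src/gridknot/tables/knot_table.json: for every knot type with
minimal crossing number <= 8, plus the connected sums of two trefoils,
the normalized Alexander polynomial (standard published coefficient
vectors, sanity-checked here by Delta(1) = 1, palindromicity and odd
determinant) and, where a reference grid diagram is available to us,
the mirror-normalized Jones polynomial computed with the package's own
Kauffman bracket.

Jones entries exist for the knots realizable on small grids (torus
grids for 3_1, 5_1, 7_1, 8_19; small-census searches for 4_1 and 5_2)
and for the trefoil connected sums (granny and square forms, both under
the single mirror-lumped label 3_1#3_1, via multiplicativity of V under
connected sum).  They are only consulted to break the one Alexander
collision in the table, 8_20 vs 3_1#3_1.

Run from the repository root:  python scripts/build_knot_table.py
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gridknot.grid import validate
from gridknot.laurent import LaurentPolynomial
from gridknot.planar import to_planar_diagram
from gridknot.invariants import (
    _jones_from_bracket,
    alexander_poly,
    fingerprint_of_poly,
)
from gridknot.census import enumerate_grids

# Normalized Alexander polynomials: ascending coefficients and minimum
# exponent, centered, Delta(1) = +1.  Standard table values.
ALEXANDER = {
    "0_1": ([1], 0),
    "3_1": ([1, -1, 1], -1),
    "4_1": ([-1, 3, -1], -1),
    "5_1": ([1, -1, 1, -1, 1], -2),
    "5_2": ([2, -3, 2], -1),
    "6_1": ([-2, 5, -2], -1),
    "6_2": ([-1, 3, -3, 3, -1], -2),
    "6_3": ([1, -3, 5, -3, 1], -2),
    "7_1": ([1, -1, 1, -1, 1, -1, 1], -3),
    "7_2": ([3, -5, 3], -1),
    "7_3": ([2, -3, 3, -3, 2], -2),
    "7_4": ([4, -7, 4], -1),
    "7_5": ([2, -4, 5, -4, 2], -2),
    "7_6": ([-1, 5, -7, 5, -1], -2),
    "7_7": ([1, -5, 9, -5, 1], -2),
    "8_1": ([-3, 7, -3], -1),
    "8_2": ([-1, 3, -3, 3, -3, 3, -1], -3),
    "8_3": ([-4, 9, -4], -1),
    "8_4": ([-2, 5, -5, 5, -2], -2),
    "8_5": ([-1, 3, -4, 5, -4, 3, -1], -3),
    "8_6": ([-2, 6, -7, 6, -2], -2),
    "8_7": ([1, -3, 5, -5, 5, -3, 1], -3),
    "8_8": ([2, -6, 9, -6, 2], -2),
    "8_9": ([-1, 3, -5, 7, -5, 3, -1], -3),
    "8_10": ([1, -3, 6, -7, 6, -3, 1], -3),
    "8_11": ([-2, 7, -9, 7, -2], -2),
    "8_12": ([1, -7, 13, -7, 1], -2),
    "8_13": ([2, -7, 11, -7, 2], -2),
    "8_14": ([-2, 8, -11, 8, -2], -2),
    "8_15": ([3, -8, 11, -8, 3], -2),
    "8_16": ([1, -4, 8, -9, 8, -4, 1], -3),
    "8_17": ([-1, 4, -8, 11, -8, 4, -1], -3),
    "8_18": ([-1, 5, -10, 13, -10, 5, -1], -3),
    "8_19": ([1, -1, 0, 1, 0, -1, 1], -3),
    "8_20": ([1, -2, 3, -2, 1], -2),
    "8_21": ([-1, 4, -5, 4, -1], -2),
    "3_1#3_1": ([1, -2, 3, -2, 1], -2),
}


def torus_grid(n, shift):
    return validate(tuple(range(n)), tuple((c + shift) % n for c in range(n)))


def find_by_alexander(n, target):
    for g in enumerate_grids(n):
        if alexander_poly(g) == target:
            return g
    raise LookupError(f"no grid of size {n} with Alexander {target}")


def normalized(v):
    return min(v, v.reciprocal(), key=lambda p: (p.minexp, p.coeffs))


def main():
    polys = {}
    for name, (coeffs, minexp) in ALEXANDER.items():
        p = LaurentPolynomial(coeffs, minexp)
        assert p(1) == 1, name
        assert p.is_palindromic(), name
        assert abs(p(-1)) % 2 == 1, name
        polys[name] = p

    # The evaluation fingerprint must separate everything except the one
    # genuine Alexander collision.
    fps = {}
    for name, p in polys.items():
        fps.setdefault(fingerprint_of_poly(p), []).append(name)
    collisions = {k: v for k, v in fps.items() if len(v) > 1}
    assert collisions == {fingerprint_of_poly(polys["8_20"]): ["8_20", "3_1#3_1"]}, collisions

    # Reference diagrams for Jones entries.
    refs = {
        "3_1": torus_grid(5, 2),
        "5_1": torus_grid(7, 2),
        "7_1": torus_grid(9, 2),
        "8_19": torus_grid(7, 3),
        "4_1": find_by_alexander(6, polys["4_1"]),
        "5_2": find_by_alexander(7, polys["5_2"]),
    }
    jones = {"0_1": [LaurentPolynomial.one()]}
    raw = {}
    for name, g in refs.items():
        assert alexander_poly(g) == polys[name], name
        v = _jones_from_bracket(to_planar_diagram(g))
        raw[name] = v
        jones[name] = [normalized(v)]
    v3 = raw["3_1"]
    granny = normalized(v3 * v3)
    square = normalized(v3 * v3.reciprocal())
    assert granny != square
    jones["3_1#3_1"] = [granny, square]

    # Known published values as independent anchors.
    assert jones["3_1"] == [LaurentPolynomial([-1, 1, 0, 1], -4)]
    assert jones["4_1"] == [LaurentPolynomial([1, -1, 1, -1, 1], -2)]

    knots = []
    for name, p in polys.items():
        rec = {
            "name": name,
            "alexander": {"coeffs": list(p.coeffs), "minexp": p.minexp},
            "jones": [
                {"coeffs": list(v.coeffs), "minexp": v.minexp}
                for v in jones.get(name, [])
            ],
        }
        knots.append(rec)
    payload = {"version": 1, "knots": knots}
    out = Path(__file__).resolve().parents[1] / "src" / "gridknot" / "tables" / "knot_table.json"
    out.write_text(json.dumps(payload, indent=1) + "\n")
    print(f"wrote {out} with {len(knots)} entries")


if __name__ == "__main__":
    main()
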