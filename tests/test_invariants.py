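"""Alexander/Jones invariants, fingerprints, and knot identification."""

import random
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from _strategies import random_grids
from gridknot.grid import GridDiagram, mirror, transpose, validate
from gridknot.laurent import LaurentPolynomial
from gridknot.invariants import (
    OTHER,
    alexander_eval,
    alexander_poly,
    alexander_poly_from_pd,
    determinant,
    fingerprint,
    fingerprint_of_poly,
    identify,
    jones_normalized,
    kauffman_bracket,
)
from gridknot.moves import commute, interleaved, simplify
from gridknot.planar import to_planar_diagram
from gridknot.census import enumerate_grids

TORUS_TREFOIL = validate(tuple(range(5)), tuple((c + 2) % 5 for c in range(5)))
TORUS_5_1 = validate(tuple(range(7)), tuple((c + 2) % 7 for c in range(7)))
TORUS_8_19 = validate(tuple(range(7)), tuple((c + 3) % 7 for c in range(7)))
GRANNY = validate((0, 1, 2, 3, 6, 7, 8, 4, 5), (2, 3, 4, 0, 1, 5, 6, 7, 8))
SQUARE = validate((0, 1, 2, 3, 6, 5, 4, 8, 7), (2, 3, 4, 0, 1, 8, 7, 6, 5))
UNKNOT_GN3 = validate((1, 2, 0), (0, 1, 2))


class TestLaurentPolynomial:
    def test_arithmetic_round_trip(self):
        p = LaurentPolynomial((1, -1, 1), -1)  # trefoil Alexander
        q = LaurentPolynomial((2, 0, -3), -2)
        assert (p * q).exact_div(q) == p
        assert (p + q) - q == p
        assert p(2) == Fraction(3, 2)

    def test_exact_div_detects_remainder(self):
        p = LaurentPolynomial((1, 1))
        with pytest.raises(ArithmeticError):
            LaurentPolynomial((1, 0, 1)).exact_div(p)

    def test_reciprocal_and_palindromy(self):
        p = LaurentPolynomial((1, -3, 1), -1)
        assert p.reciprocal() == p
        assert p.is_palindromic()
        q = LaurentPolynomial((1, 2), 0)
        assert q.reciprocal().reciprocal() == q

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=6),
           st.integers(-3, 3))
    def test_normalization_strips_zeros(self, coeffs, minexp):
        p = LaurentPolynomial(coeffs, minexp)
        if p.coeffs:
            assert p.coeffs[0] != 0 and p.coeffs[-1] != 0


class TestAlexander:
    def test_unknot_is_trivial(self):
        assert alexander_poly(UNKNOT_GN3) == LaurentPolynomial.one()
        assert alexander_eval(UNKNOT_GN3, -1) == 1

    def test_trefoil(self):
        assert alexander_poly(TORUS_TREFOIL) == LaurentPolynomial((1, -1, 1), -1)
        assert determinant(TORUS_TREFOIL) == 3

    def test_torus_knots_5_1_and_8_19(self):
        assert alexander_poly(TORUS_5_1) == LaurentPolynomial((1, -1, 1, -1, 1), -2)
        assert determinant(TORUS_8_19) == 3  # same determinant as the trefoil
        assert alexander_poly(TORUS_8_19) == LaurentPolynomial((1, -1, 0, 1, 0, -1, 1), -3)

    @given(random_grids(min_n=8, max_n=10))
    def test_delta_at_one_is_one(self, g):
        assert alexander_poly(g)(1) == 1

    @given(random_grids())
    def test_palindromic_and_symmetric(self, g):
        p = alexander_poly(g)
        assert p.is_palindromic()
        assert p.reciprocal() == p

    def test_grid_and_pd_routes_agree_exhaustively_at_gn5(self, gn5_diagrams):
        for g in gn5_diagrams:
            assert alexander_poly_from_pd(to_planar_diagram(g)) == alexander_poly(g)

    def test_grid_and_pd_routes_agree_on_gn6_sample(self):
        sample = [g for k, g in enumerate(enumerate_grids(6)) if k % 83 == 0]
        for g in sample:
            assert alexander_poly_from_pd(to_planar_diagram(g)) == alexander_poly(g)

    def test_determinant_odd_exhaustive_gn5(self, gn5_diagrams):
        assert all(determinant(g) % 2 == 1 for g in gn5_diagrams)

    def test_multicomponent_rejected(self):
        from gridknot.grid import MultiComponentError

        link = GridDiagram(4, (1, 0, 3, 2), (0, 1, 2, 3))
        with pytest.raises(MultiComponentError):
            alexander_poly(link)


class TestJones:
    def test_crossingless_diagram_gives_one(self):
        pd = to_planar_diagram(UNKNOT_GN3)
        assert kauffman_bracket(pd) == LaurentPolynomial.one()
        assert jones_normalized(pd) == LaurentPolynomial.one()

    def test_trefoil_known_value_and_mirror_collision(self):
        v = jones_normalized(to_planar_diagram(TORUS_TREFOIL))
        assert v == LaurentPolynomial((-1, 1, 0, 1), -4)
        assert jones_normalized(to_planar_diagram(mirror(TORUS_TREFOIL))) == v

    def test_distinguishes_8_19_from_trefoil(self):
        # same determinant (3); Jones separates them
        v_tre = jones_normalized(to_planar_diagram(TORUS_TREFOIL))
        v_819 = jones_normalized(to_planar_diagram(TORUS_8_19))
        assert v_tre != v_819

    def test_crossing_bound_enforced(self):
        from gridknot.invariants import TooManyCrossings

        with pytest.raises(TooManyCrossings):
            jones_normalized(to_planar_diagram(TORUS_8_19), max_crossings=2)


class TestFingerprint:
    def test_unknot_fingerprint_is_all_ones(self):
        assert fingerprint(UNKNOT_GN3) == (1, 1, 1, 1)

    def test_matches_polynomial_fingerprint(self):
        for g in (TORUS_TREFOIL, TORUS_5_1, TORUS_8_19, GRANNY):
            assert fingerprint(g) == fingerprint_of_poly(alexander_poly(g))

    def test_table_fingerprints_unique_except_composite_collision(self, table):
        collisions = {fp: names for fp, names in table.by_fingerprint.items()
                      if len(names) > 1}
        assert list(collisions.values()) == [["8_20", "3_1#3_1"]]

    def test_table_entries_are_normalized(self, table):
        for entry in table.entries.values():
            p = entry.alexander
            assert p(1) == 1
            assert p.is_palindromic()
            assert abs(p(-1)) % 2 == 1


class TestIdentify:
    def test_all_gn3_gn4_grids_are_unknots(self):
        for n in (3, 4):
            assert all(identify(g) == "0_1" for g in enumerate_grids(n))

    def test_gn5_census_has_exactly_ten_trefoils(self, gn5_diagrams):
        labels = [identify(g) for g in gn5_diagrams]
        assert labels.count("3_1") == 10
        assert labels.count("0_1") == 1430

    def test_torus_knot_labels(self):
        assert identify(TORUS_TREFOIL) == "3_1"
        assert identify(TORUS_5_1) == "5_1"
        assert identify(TORUS_8_19) == "8_19"
        assert identify(validate(tuple(range(9)), tuple((c + 2) % 9 for c in range(9)))) == "7_1"

    def test_composite_trefoils_resolved_by_jones(self):
        # Both chirality combinations (granny and square) fall in the
        # 8_20 Alexander-collision class and must resolve via Jones.
        assert identify(GRANNY) == "3_1#3_1"
        assert identify(SQUARE) == "3_1#3_1"

    def test_out_of_table_knot_labelled_other(self):
        t29 = validate(tuple(range(11)), tuple((c + 2) % 11 for c in range(11)))
        assert identify(t29) == OTHER  # (2,9) torus knot has 9 crossings

    @given(random_grids(min_n=5, max_n=10))
    def test_invariant_under_symmetries_and_moves(self, g):
        label = identify(g)
        assert identify(GridDiagram(g.n, g.os, g.xs)) == label  # X/O swap
        assert identify(mirror(g)) == label
        assert identify(transpose(g)) == label
        assert identify(simplify(g)) == label
        rng = random.Random(0)
        for _ in range(3):
            axis = rng.choice(("col", "row"))
            i = rng.randrange(g.n - 1)
            if not interleaved(g, axis, i):
                assert identify(commute(g, axis, i)) == label

    def test_identify_invariant_under_moves_exhaustive_gn5(self, gn5_diagrams):
        for g in gn5_diagrams[::7]:
            label = identify(g)
            for axis in ("col", "row"):
                for i in range(4):
                    if not interleaved(g, axis, i):
                        assert identify(commute(g, axis, i)) == label
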