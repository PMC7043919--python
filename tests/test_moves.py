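"""Strand passages, juxtaposition geometry, destabilization, simplification."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gridknot.grid import validate
from gridknot.invariants import fingerprint, identify
from gridknot.moves import (
    classify_juxtaposition,
    commute,
    destabilize_once,
    interleaved,
    passage_sites,
    simplify,
)
from gridknot.census import enumerate_grids
from _strategies import random_grids

UNKNOT_FP = (1, 1, 1, 1)
TREFOIL_FP = fingerprint(validate(tuple(range(5)), tuple((c + 2) % 5 for c in range(5))))


class TestInterleaving:
    def test_interleaved_pair(self):
        # columns 0, 1 span rows [0,2] and [1,3]
        g = validate((0, 1, 2, 3), (2, 3, 0, 1))
        assert interleaved(g, "col", 0)

    def test_nested_pair_not_interleaved(self):
        # columns 0, 1 span rows [0,3] and [1,2]
        g = validate((0, 1, 3, 2), (3, 2, 0, 1))
        assert not interleaved(g, "col", 0)

    def test_shared_endpoint_not_interleaved(self):
        # columns 0, 1 span rows [0,2] and [2,3]: interiors meet trivially
        g = validate((0, 2, 1, 3), (2, 3, 0, 1))
        assert not interleaved(g, "col", 0)

    def test_index_out_of_range(self):
        g = validate((1, 2, 0), (0, 1, 2))
        with pytest.raises(IndexError):
            interleaved(g, "col", 2)


class TestCommute:
    @given(random_grids())
    def test_involution_all_sites(self, g):
        for axis in ("col", "row"):
            for i in range(g.n - 1):
                assert commute(commute(g, axis, i), axis, i) == g

    def test_non_interleaved_commutation_preserves_knot_exhaustive_gn5(self, gn5_diagrams):
        for g in gn5_diagrams:
            fp = fingerprint(g)
            for axis in ("col", "row"):
                for i in range(4):
                    if not interleaved(g, axis, i):
                        assert fingerprint(commute(g, axis, i)) == fp

    def test_some_gn6_trefoil_unknots_by_interleaved_commutation(self):
        for g in enumerate_grids(6):
            if fingerprint(g) != TREFOIL_FP:
                continue
            for axis, i in passage_sites(g, "unbiased"):
                if fingerprint(commute(g, axis, i)) == UNKNOT_FP:
                    return
        pytest.fail("no trefoil-to-unknot interleaved commutation found at GN 6")


class TestJuxtapositions:
    def test_torus_trefoil_hooked_site(self):
        tre = validate(tuple(range(5)), tuple((c + 2) % 5 for c in range(5)))
        j = classify_juxtaposition(tre, "col", 1)
        assert j.geometry == "hooked" and j.area == 1 and j.strongly_hooked

    def test_hooked_becomes_free_after_passage(self, gn5_diagrams):
        seen = 0
        for g in gn5_diagrams:
            for axis in ("col", "row"):
                for i in range(4):
                    j = classify_juxtaposition(g, axis, i)
                    if j.geometry == "hooked":
                        after = classify_juxtaposition(commute(g, axis, i), axis, i)
                        assert after.geometry == "free"
                        seen += 1
        assert seen > 0

    def test_all_gn5_trefoils_have_strongly_hooked_sites(self, gn5_diagrams):
        trefoils = [g for g in gn5_diagrams if fingerprint(g) == TREFOIL_FP]
        assert len(trefoils) == 10
        hooked_sites = [passage_sites(g, "hooked", 1) for g in trefoils]
        assert all(hooked_sites)  # every diagram has at least one
        assert sum(len(s) for s in hooked_sites) >= 10

    def test_invariant_structure(self, gn5_diagrams):
        for g in gn5_diagrams[:200]:
            for axis in ("col", "row"):
                for i in range(4):
                    j = classify_juxtaposition(g, axis, i)
                    assert j.interleaved == (j.geometry != "not-interleaved")
                    assert (j.area is not None) == (j.geometry == "hooked")
                    if j.strongly_hooked:
                        assert j.geometry == "hooked" and j.area == 1


class TestPassageSites:
    def test_gn3_unknot_has_no_interleaved_pairs(self):
        assert passage_sites(validate((1, 2, 0), (0, 1, 2)), "unbiased") == []

    @given(random_grids())
    def test_hooked_sites_subset_of_unbiased(self, g):
        unb = set(passage_sites(g, "unbiased"))
        for a in (1, 2, 3):
            assert set(passage_sites(g, "hooked", a)) <= unb

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            passage_sites(validate((1, 2, 0), (0, 1, 2)), "bogus")


class TestDestabilize:
    def test_no_gn5_trefoil_destabilizes(self, gn5_diagrams):
        # The trefoil's arc index is 5: no smaller grid carries it.
        for g in gn5_diagrams:
            if fingerprint(g) == TREFOIL_FP:
                assert destabilize_once(g) is None

    def test_destabilize_preserves_knot_on_gn6_sample(self):
        rng = random.Random(7)
        checked = 0
        pool = [g for k, g in enumerate(enumerate_grids(6)) if k % 17 == 0]
        rng.shuffle(pool)
        for g in pool:
            d = destabilize_once(g)
            if d is not None:
                assert d.n == 5
                assert fingerprint(d) == fingerprint(g)
                checked += 1
            if checked >= 300:
                break
        assert checked >= 100

    def test_gn2_unknot_is_terminal(self):
        assert destabilize_once(validate((0, 1), (1, 0))) is None


class TestSimplify:
    @pytest.mark.parametrize("n", [3, 4])
    def test_small_grids_reduce_to_trivial_unknot(self, n):
        for g in enumerate_grids(n):
            s = simplify(g)
            assert s.n <= 3
            assert fingerprint(s) == UNKNOT_FP if s.n >= 3 else True

    @given(random_grids(min_n=6, max_n=10))
    def test_preserves_alexander_fingerprint(self, g):
        assert fingerprint(simplify(g)) == fingerprint(g)

    @given(random_grids(min_n=5, max_n=10))
    def test_idempotent_in_grid_number(self, g):
        s = simplify(g)
        assert simplify(s).n == s.n

    @given(random_grids())
    def test_never_grows(self, g):
        assert simplify(g).n <= g.n
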