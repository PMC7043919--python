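# gridknot

Grid-diagram modelling of knot spaces and type II topoisomerase-mediated
simplification of DNA topology.

Type II topoisomerases pass one double-stranded DNA segment through a
transient cut in another, changing one crossing of the molecule's knot at a
time — and, experimentally, they unknot DNA far below topological
equilibrium. `gridknot` implements a purely combinatorial framework for
studying this process: closed DNA molecules are modelled as **grid
diagrams** (arc presentations), an *n* × *n* board with one X and one O
marking in every row and column, vertical strands always overpassing
horizontal ones. A diagram is just a pair of permutations
(`xs[c]`, `os[c]` = rows of the X and O in column *c*), so three things that
are expensive in lattice or bead-chain polymer models are exact and cheap
here:

* **exhaustive enumeration** of all diagrams up to a given grid number
  (GN ≤ 7: 1,859,118 diagrams; a grid of size *n* ≈ a polymer of 2*n*
  statistical segments),
* **uniform random sampling** at any grid number (no Markov chain, no
  equilibration — uniformity is built into the representation),
* **strand passages** as *interleaving commutations*: exchanging two
  adjacent rows or columns whose segment intervals partially overlap
  realizes exactly one intersegmental passage.

Knot types are identified with exact integer invariants: the Alexander
polynomial Δ(t) computed from the winding-number matrix of the grid
(det W = ± tᵃ (1−t)ⁿ⁻¹ Δ(t)), the knot determinant |Δ(−1)|, and — for the
one Alexander collision in the lookup table of knots with ≤ 8 crossings —
the mirror-normalized Jones polynomial from a Kauffman-bracket state sum.

On top of this the package computes **knot-interconversion fluxes**: fire a
passage at every admissible site of every diagram, identify the result, and
tabulate directed counts between knot types. Unbiased passages give an
exactly symmetric table (detailed balance — the diagram ensemble *is* the
topological equilibrium). Restricting passages to **hooked juxtapositions**
— interleaved pairs whose strands bound a rectangle, with "strongly hooked"
meaning an elementary 1 × 1 square — breaks the symmetry strongly toward
unknotting; the ratio

    knotting reduction factor = flux(3_1 → 0_1) / flux(0_1 → 3_1)

measures how far below equilibrium the knotting level would settle, which
is the hooked-juxtaposition mechanism proposed for topoisomerase II.

## A worked example

```python
from gridknot import census, flux_table, reduction_factor

cen = census(5, 6)                    # all 44,640 diagrams with GN 5-6
unb = flux_table(cen, policy="unbiased", gn_min=6, gn_max=6)
hk  = flux_table(cen, policy="hooked", max_area=1, gn_min=6, gn_max=6)
print(unb.count("3_1", "0_1"), unb.count("0_1", "3_1"))
print(hk.count("3_1", "0_1"),  hk.count("0_1", "3_1"))
print(reduction_factor(unb, hk).factor)
```

prints

```
6240 6240
1380 80
17.25
```

Reading: among all 43,200 GN-6 diagrams, unbiased strand passages convert
trefoil diagrams into unknot diagrams exactly 6,240 times and unknots into
trefoils exactly 6,240 times — perfectly balanced fluxes. Restricted to
strongly hooked juxtapositions, 1,380 passages unknot a trefoil but only 80
knot an unknot: preferential unknotting with a reduction factor of ≈ 17.
At GN 5 the effect is absolute (`examples/hooked_unknotting.py`): all 24
hooked passages on the ten trefoil diagrams unknot them and none of the
hooked passages on unknots ties a knot — an infinite reduction factor.

The `examples/` directory holds one short narrative script per capability
(identification, censuses, hooked unknotting, sampling); each prints the
numbers it computes and what they mean. A thin CLI mirrors the library:

```
gridknot census --gn-min 3 --gn-max 7 --out census.csv
gridknot fluxes --gn-min 5 --gn-max 7 --policy hooked --max-area 1 \
                --out flux.csv --report reduction_report.json
gridknot identify --grid "x=1,2,0;o=0,1,2"
gridknot sample --gn 12 --n 10000 --seed 1 --out sampled.csv
```

## Scope and limitations

Multi-component diagrams (links/catenanes) are detected and excluded, not
analysed. Knot types are mirror-lumped (no chirality bookkeeping); knots
beyond 8 crossings (other than the trefoil connected sums) are labelled
`other`, and any knot sharing all computed invariants with a table entry is
binned as that entry — the unavoidable misbinning of a finite invariant
set. Exhaustive enumeration is capped at GN 8 (≈ 10⁸ diagrams, expert
mode); larger grids are studied by sampling. See `docs/methods.md` for the
model's assumptions, conventions and numerical choices.
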