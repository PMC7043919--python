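# Methods

## The model

A grid diagram of size *n* (grid number, GN) is an *n* × *n* board with one
X and one O marking in each row and each column, no two markings in the
same square. Columns are joined X–O by vertical segments, rows by
horizontal segments, and vertical segments always overpass horizontal
ones; the resulting closed curve is a knot or link projection. The diagram
is stored as the permutation pair `xs`, `os` with `xs[c]`/`os[c]` the row
of the X/O in column `c`. Conventions fixed throughout: 0-based indices,
row 0 at the bottom; the curve is oriented X→O along columns and O→X along
rows wherever an orientation is needed internally (winding numbers,
crossing signs), but knot types are unoriented and mirror-lumped, so no
orientation or chirality is ever reported.

The number of components is the number of cycles of `xs ∘ os⁻¹`; only
single-component diagrams (knots) are analysed, links are detected and
skipped. Diagrams are counted modulo exchanging the X and O marking sets —
the swap leaves the projected curve unchanged — with the canonical
representative the lexicographically smaller of `(xs, os)` and `(os, xs)`.
No further quotient (translation, rotation, transposition) is taken: under
this convention the number of canonical knot diagrams of size *n* is
exactly *n*!(*n*−1)!/2, and the GN 3–7 space totals 1,859,118 diagrams.
Grids of size 2 are accepted by the validator but excluded from censuses;
a grid of size *n* corresponds to a ring polymer of roughly 2*n*
statistical segments (a GN-5 grid ≈ 3 kb of DNA).

## Strand passages and juxtaposition geometry

A single type II topoisomerase action — one intersegmental passage, i.e.
one crossing change — is an *interleaving commutation*: adjacent lines
*i*, *i*+1 (rows or columns) are exchanged when their segment intervals
strictly interleave, each containing exactly one endpoint of the other in
its open interior. Adjacency is non-cyclic (the board is planar; there is
no wrap-around pair), and pairs sharing an endpoint line are classified
not-interleaved: commuting them, like commuting nested or disjoint pairs,
is a topology-preserving deformation. Every commutation is an involution;
this single fact forces the exact symmetry (detailed balance) of unbiased
flux tables over enumeration-closed diagram sets.

An interleaved adjacent pair is classified by where the perpendicular
segments attached at the two *inner* endpoints go: **hooked** if both
extend across the neighbouring line (producing two crossings whose
bounding rectangle has width 1 and integer height = the distance between
the inner endpoints, taken as the *area* parameter), **free** if both
extend away, **mixed** otherwise. *Strongly hooked* = hooked with area 1
(the elementary square). A passage fired at a hooked site always turns
that site free, realizing the inside-to-outside directionality of the
enzyme's proposed mechanism implicitly — no extra direction parameter
exists, because commutation is symmetric. Passage policies: `unbiased`
fires once at every interleaved pair of both axes; `hooked(max_area)`
fires only at hooked pairs with area ≤ `max_area` (1 by default). Each
(diagram, site) pair is one event; self-fluxes are included. Note that a
strongly hooked rectangle is geometrically detectable both as a column
pair and as its twin row pair; both commutations are distinct events and
both are counted, consistent with "one event per admissible site".

Row-pair operations are implemented as column-pair operations on the
transposed diagram (markings reflected across the main diagonal); the
transposition also mirrors the knot, which is harmless under mirror
lumping.

## Knot identification

The Alexander polynomial is computed from the grid's winding-number
matrix: W(i, j) = t^w(i,j) with w the winding number of the oriented curve
about lattice point (i, j); then det W = ± tᵃ (1−t)^(n−1) Δ(t). The
determinant is evaluated by a fraction-free Bareiss elimination — exactly,
over ℤ[t, 1/t] for the full polynomial, or over ℤ after substituting an
integer t for fast evaluations — and normalized by exact division by
(1−t)^(n−1), sign-fixing Δ(1) = 1, and centering (Δ is palindromic). An
independent route, the Fox-calculus Alexander matrix of the Wirtinger
presentation read off the planar-diagram (PD) code, is implemented solely
as a cross-check; the test suite verifies both routes agree on every GN-5
diagram and on a GN-6 sample.

Identification uses a four-value *fingerprint* of exact evaluations at
t = −1, 2, −2, 3, each reduced to its well-defined unit-free part
(|Δ(−1)| is the knot determinant; at |t| > 1 all factors of |t| are
stripped to cancel the ± tᵃ ambiguity). The fingerprint is matched against
a packaged table of all knots with minimal crossing number ≤ 8 plus the
connected sums of two trefoils; the table was checked to be
fingerprint-collision-free except for the genuine Alexander coincidence
{8_20, 3_1#3_1}. Fingerprint collisions fall back to the full Alexander
polynomial; the 8_20/3_1#3_1 class is broken by the mirror-normalized
Jones polynomial (Kauffman-bracket state sum over ≤ 2^16 states after
heuristic simplification; both the granny and square forms are stored for
the composite, and an unmatched Jones within the class resolves to 8_20).
Everything else is labelled `other`. Two deliberate limitations: the knot
signature is not implemented (its main role is chirality, which is lumped
away; Jones serves as the collision-breaker instead), and any non-table
knot sharing all computed invariants with a table entry is misbinned as
that entry — e.g. Alexander-trivial nontrivial knots (≥ 11 crossings) bin
as unknots. This affects only sampled high-GN statistics, not the exact
GN ≤ 7 censuses, where the only realizable types (unknot, 3_1, 4_1, 5_1,
5_2, 8_19) are separated by the determinant alone or one extra evaluation.

The table's Alexander coefficients are the standard published vectors
(sanity-checked by Δ(1) = 1, palindromicity and odd determinant); its
Jones entries are computed by the package's own bracket from reference
grids (torus grids for 3_1, 5_1, 7_1, 8_19; census searches for 4_1, 5_2;
connected-sum products for 3_1#3_1) and anchored against the published
V(3_1) and V(4_1).

## Enumeration, census and flux scans

Enumeration is constructive and duplicate-free: `xs` runs over all *n*!
permutations and the component cycle over all (*n*−1)! *n*-cycles, with
`os = c⁻¹ ∘ xs` (single component and no coincident markings are automatic
because an *n*-cycle is fixed-point-free); the swap quotient keeps pairs
with `(xs, os) < (os, xs)`. The census pipeline is vectorized (numpy):
diagrams are processed as permutation-array batches, winding exponent
matrices built by cumulative sums, and the determinant fingerprint
evaluated by batched |det| of ±1 matrices (exact: the Hadamard bound at
n ≤ 8 is far below 2⁵³). Only diagrams whose determinant is shared by
several table knots (≈ 5 % at GN ≤ 7) fall back to the per-diagram exact
pipeline. Each census retains a packed-key index (3 bits per digit, both
permutations in one uint64) mapping every canonical diagram to its label;
flux scans label passage results by binary search in this index, since
commutation preserves grid number. The object API (pure Python, one
diagram at a time) is the reference implementation; the tests cross-check
the vectorized engine against it exhaustively at GN 5. Exhaustive mode is
capped at GN 8 (≈ 10⁸ diagrams — accepted but untested by default; all
shipped analyses use GN ≤ 7).

Reported interconversion counts are the GN-6 exhaustive values with per-GN
breakdowns (5, 6, 7) always computed alongside: the unbiased
trefoil↔unknot flux is exactly 6,240 at GN 6, which fixes the scope of the
headline numbers unambiguously. One discrepancy is reported rather than
absorbed: with the strongly hooked definition above, the GN-6 hooked
trefoil→unknot count is 1,380 (giving a reduction factor 1380/80 = 17.25,
and 8.8 at GN 7), not the previously reported 1,220 (= 15.25); the
unknot→trefoil count (80) and every qualitative property (all GN-5 hooked
trefoil passages unknot; no GN-5 hooked unknot passage knots — an infinite
GN-5 reduction factor; hooked sites become free; the factor grows
monotonically as the area threshold tightens) agree exactly. No principled
variant of the hooked criterion we could formulate reproduces 1,220 while
keeping the other exact counts.

## Sampling

Uniform sampling at fixed GN mirrors the enumerator: draw `xs` uniformly
from permutations and the cycle uniformly from *n*-cycles, set
`os = c⁻¹ ∘ xs`, canonicalize. Each canonical diagram arises from exactly
two ordered constructions, so the draw is exactly uniform on the quotient
— verified against the exhaustive GN-5 census by chi-square in the tests.
Per-GN random streams derive deterministically from (seed, gn); all
sampled statistics are bit-reproducible from the seed. Default sample
size is 10⁴ per GN for flux studies; the knotting-fraction curve and the
GN-17 majority-nontrivial check use 2,000–2,500 draws per GN, where the
binomial standard error (≈ 1 %) is already far smaller than the effects
measured. "Nontrivial" in the fast knotting-fraction detector means a
non-unknot Alexander evaluation fingerprint, inheriting the misbinning
caveat above (a conservative undercount of knotting at high GN).

What the sampled studies emulate is the model's own idealization —
an ensemble of ring polymers at topological equilibrium in a 2D projection
ensemble — not real DNA: there is no excluded volume, no bending energy,
no temperature (every diagram has equal weight), and knotting in this
essentially 2D ensemble is stimulated relative to 3D polymers. Passing
tests therefore validate the combinatorial model exactly, and real-DNA
claims only qualitatively.

## Numerical and design notes

* All invariant arithmetic is exact (Python integers/fractions, integer
  Laurent polynomials); no floating point enters any identification,
  except batched ±1-matrix determinants whose integrality is guaranteed
  and checked by exact divisibility.
* `simplify` is a heuristic reducer: greedy destabilization (any 2×2 block
  holding three markings merges two lines) interleaved with a bounded,
  seeded random walk over topology-preserving commutations (budget 50·n
  steps between destabilization scans). It certifies nothing about
  minimal grid number — it only shrinks diagrams before exponential-cost
  bracket computations — and is deterministic for a fixed seed (default 0).
* `identify` computes the fingerprint first and simplifies only when the
  Jones stage is actually needed; this is output-equivalent to
  simplify-first and much faster in bulk scans.
* Degenerate inputs: evaluation points where Δ vanishes are stored as 0 in
  fingerprints (Δ(6_1)(2) = 0 is the reason t = −2 and 3 are included);
  zero-crossing diagrams short-circuit to the unknot bracket; flux rows
  with no events give NaN transition probabilities (flagged, not 0); a
  reduction factor with zero denominator reports ∞, and 1 with a
  `degenerate` flag when both fluxes vanish.
* Ties in mirror-normalization (V vs V(1/q)) are broken by lexicographic
  order on (minimum exponent, coefficient tuple); palindromic V is its own
  mirror.
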