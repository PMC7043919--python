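"""Exhaustive knot census of all grid diagrams with GN 3-6.

Enumerates every canonical single-component diagram (6 + 72 + 1440 +
43,200 of them), identifies each, and prints occurrence probabilities:
the fraction of diagrams of each knot type per grid number.  Nontrivial
knots first appear at GN 5 (ten trefoil diagrams), and the unknot
fraction decreases as the grid -- i.e. the modelled polymer -- grows.
"""

from gridknot import census, occurrence_probabilities

cen = census(3, 6)
print(cen.to_frame().to_string(index=False))
print()
print(occurrence_probabilities(cen).to_string(index=False))
print()
print(f"total diagrams: {cen.grand_total()}")
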