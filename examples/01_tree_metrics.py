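"""Compare two small lineage trees under all four tree metrics.

Builds a pair of toy sublineages that differ in one cycle time and one
missing cell, then prints the tree edit distance (topology only), the
intersection branch distance (shared-cell timing only), the union branch
distance (timing + topology), and the generalized branch distance (the
minimum over all structure-respecting alignments, ignoring labels).
"""

import lineagedist as ld

X = {"Q": 10.0, "Qa": 20.0, "Qp": 30.0, "Qaa": 15.0, "Qap": 18.0}
Y = {"Q": 10.0, "Qa": 22.0, "Qp": 30.0}

print("tree edit distance      :", ld.tree_edit_distance(X, Y))
print("intersection branch dist:", round(ld.intersection_branch_distance(X, Y).value, 4), "min")
print("union branch dist       :", round(ld.union_branch_distance(X, Y).value, 4), "min")
gbd, alignment = ld.generalized_branch_distance(X, Y)
print("generalized branch dist :", round(gbd.value, 4), "min")
print("alignment mismatch frac :", ld.alignment_mismatch_fraction(alignment))

# The tree edit distance counts the two cells missing from Y; the
# intersection distance sees only the 2-minute difference at Qa; the union
# distance adds the full weight of the two unpaired cells; the generalized
# distance here can do no better than the canonical alignment, so it equals
# the union value and uses the name-based pairing (mismatch fraction 0).
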