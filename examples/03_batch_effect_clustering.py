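"""Detect a global-clock batch effect in a cohort of wild-type-like embryos.

Simulates 21 embryos at clock 1.0 and 9 at clock 0.8 (a ~20% rate-of-
development batch effect) with 5% per-cell noise, clusters them on the union
branch distance with single linkage and a largest-gap dendrogram cut, and
estimates the clock ratio between the groups with the PCA slope.
"""

import numpy as np

import lineagedist as ld

spec = ld.CohortSpec(groups=[(21, 1.0, 0.05), (9, 0.8, 0.05)], seed=42)
cohort = ld.generate_cohort(spec)

dm = ld.pairwise_distance_matrix(cohort, metric="ubd")
assignment = ld.cut_largest_gap(ld.single_linkage(dm))

print(f"clusters found: k={assignment.k} (cut height {assignment.cut_height:.1f} min)")
for c in range(1, assignment.k + 1):
    members = [e for e in cohort if assignment.assignment[e.embryo_id] == c]
    clocks = {e.meta["clock_factor"] for e in members}
    print(f"  cluster {c}: {len(members)} embryos, simulated clock factors {sorted(clocks)}")

slopes = [
    ld.pca_slope(a, b).m
    for a in cohort
    for b in cohort
    if a.meta["group"] == 0 and b.meta["group"] == 1
]
print(f"mean cross-group PCA slope: {np.mean(slopes):.3f}  (simulated ratio 0.8)")

# Correlation alone cannot see this structure: the two groups remain highly
# correlated cell-for-cell.  The branch distance separates them because it is
# sensitive to the systematic rescaling of every cycle time.
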