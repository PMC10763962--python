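# Methods

This note records the model, the numerical and design choices, what the
synthetic data does and does not emulate, and the problem sizes used by the
test suite and the acceptance script.

## Data model

A lineage is a flat mapping from Sulston cell names to strictly positive,
finite cycle times (minutes). The tree is implicit in the names: a
non-founder cell's mother is its name minus the last orientation letter;
founder cells are related by the fixed early-embryo table P0→{AB,P1},
P1→{EMS,P2}, EMS→{MS,E}, P2→{C,P3}, P3→{D,P4}, P4→{Z2,Z3} (anterior daughter
first, which also fixes the anterior/posterior letter when founder-table
steps appear inside a root-normalized path). Names are case-sensitive and
matched exactly after whitespace stripping. A lineage may be a forest; any
founder whose table parent is absent acts as a root, and whole-embryo
metrics operate on the union of trees. Structural validation (parent
closure, the 0-or-2-daughters rule, positive finite times) returns
violations as data rather than raising, because partially curated screen
embryos are expected input.

Sublineages extracted for cross-lineage comparison are re-keyed into a
root-normalized namespace: the root becomes `Q` and each subsequent letter is
collapsed onto the anterior/posterior axis ({a,l,d}→a, {p,r,v}→p). The
root's own cycle time is **included** by default (`include_root_time=False`
excludes it); including it keeps the compared vectors maximal, and the
choice is exposed because either convention is defensible.

## Metrics

Definitions are in the README. Implementation notes:

- Distances are reported in minutes as floating point; nothing is rounded
  inside the library.
- The intersection branch distance raises on an empty shared-cell set by
  default (a silent 0 would assert similarity of unrelated trees); an
  opt-in flag returns 0 with a warning. It is a pseudo-metric — two trees
  agreeing on shared cells but differing in topology are at distance 0 —
  and the tests document this.
- The union branch distance satisfies the exact identity
  union² = intersection² + Σ unmatched t², which the tests verify to 1e-9
  relative on randomized trees as a cross-implementation check.
- The generalized branch distance handles unmatched subtrees union-style
  (their full squared weight enters). The label-free alignment search on
  equal-topology trees never needs this, but union semantics keeps the
  quantity a metric on unequal topologies. The recursion memoizes on node
  pairs and minimizes (squared cost, mismatch count) lexicographically, so
  among minimizing alignments the one closest to the canonical name-based
  alignment is returned deterministically — this makes the
  alignment-mismatch diagnostic stable. Exhaustive enumeration doubles per
  internal aligned pair and is guarded at depth 6; it exists purely as an
  independent oracle for the recursion.
- Metric axioms (symmetry, non-negativity, identity of indiscernibles for
  positive weights, triangle inequality) are checked empirically on
  randomized tree triples rather than re-proved.

## Timing statistics

R² is the squared Pearson correlation over shared cells; for a simple
linear fit with intercept this equals the regression R², so one quantity
serves both framings. Birth times are sums of recorded ancestors' cycle
times (a forest root is born at 0).

The clock slope is estimated by PCA / total least squares: the shared
cycle-time pairs are mean-centered and the principal eigenvector of their
2×2 covariance gives the slope, oriented so the run is positive. Ordinary
regression is deliberately avoided — both embryos in a comparison are
subject to random variation, and the choice of independent variable would
be arbitrary. The estimator satisfies slope(X,Y)·slope(Y,X) = 1 exactly and
equals the OLS slope for colinear data. With multiplicative noise on both
sides its residual bias at 5% CV is below ~1% provided the cycle-time
spread is realistic (tens of minutes); this is why the default synthetic
template uses a geometric per-generation baseline (below).

The within-embryo shuffle is a uniform random permutation of cycle times
over cells (a cell may receive its own value); a derangement mode is
available behind a flag since "assigned to a different cell" can be read
either way. The fraction-faster statistic counts strict inequalities only,
so ties favor neither side and f(A,B) + f(B,A) ≤ 1 with equality iff no
ties; a strict majority over the compared cells is the "faster lineage"
call.

## Cohort analysis

Single-linkage clustering runs on the pairwise distance matrix
(scipy's agglomeration; merge heights equal sorted MST edge weights, which
the tests verify against a Prim-based oracle). The dendrogram is cut at the
largest gap between successive merge heights, searched over cuts yielding
2 ≤ k ≤ n/2 — the operational version of "a large gap between merge
generations"; the trivial k=1 side is excluded and an explicit k override
is always available. Ties go to the smaller k.

The permutation test pools both samples, resamples groups of the original
sizes without replacement, and reports p = (# resamples with
|Δmean*| ≥ |Δmean|) / iterations (default 10⁶, vectorized in chunks). The
raw-count estimate can be 0; an add-one-smoothed variant is provided.
Enrichment uses one-sided Boschloo exact tests (overrepresentation of a
class inside a cluster) with Bonferroni correction by the number of tests
actually performed.

## Fate-transformation heuristic

Each candidate fate is represented by the wild-type examples of its
sublineage under the intersection branch distance; the cloud's diameter D
is the maximum pairwise distance, and the neighborhood boundary is
**strict** (distance < D, so at D = 0 only exact matches qualify). A
consequence worth knowing: an exact copy of a diameter-realizing reference
sits exactly at D from its partner and scores (n−1)/n rather than 1.0,
while still being classified unperturbed via its zero-distance source.

The intersection metric is the default (the union variant is available via
a flag). In all-pairs mode the nearest destination fate is the one with
minimal mean distance to its references. Because the intersection distance
only sees shared cells, comparing sublineages of unequal size lets the
smaller one hide inside the larger one's diameter; scans should therefore
use equal-depth roots or a depth limit that equalizes subtree sizes (the
analyses here use 31-cell sublineages throughout). The heuristic is
deliberately not scale invariant: a transformed lineage riding on a shifted
global clock is missed, and that limitation is accepted.

The significance null shuffles cycle times among all same-named cells
across the perturbed cohort and re-runs the scan. This preserves every
per-name marginal distribution; it destroys proximity only because real
(and realistically simulated) perturbed cohorts are heterogeneous, so the
shuffled lineages become chimeras of different global clocks and
perturbation states. On a homogeneous cohort the shuffle is a near-no-op —
the tests pin this boundary case down. The library default is 10,000
repetitions; the test suite and acceptance script use 200 to keep runtimes
in seconds-to-a-minute, which is ample to demonstrate a null that produces
zero full-neighborhood lineages.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analyses key
on:

- **Template**: complete binary subtrees under each founder (default: AB to
  depth 7, MS/E/C to depth 4, D to depth 2, plus the P-line chain; 363
  cells, comparable to a curated early lineage). The per-generation
  baseline is geometric, 12·1.28^g minutes (12 min for the zygote to ~90
  min for generation-8 cells) — matching the wide dynamic range of real
  cycle times, which matters because slope estimation degrades when cycle
  times are artificially compressed. ABa/ABp divide left/right so the
  granddaughters carry their conventional names (ABal … ABpr).
- **Signatures**: multiplicative factors per sublineage (defaults: ABa
  0.85, ABp 1.15, ABal 0.90, ABpr 1.08, MS 0.92, E 1.18, C 1.06; nested
  factors compose). These give each fate a distinctive timing pattern, the
  synthetic analog of lineage-specific developmental programs, with
  separations (≥ 5–10%) comfortably above well-curated wild-type noise.
- **Clock factors**: embryo-level multiplicative rate differences (the
  batch-effect analyses use 1.0 vs 0.8, a ~20% difference).
- **Noise**: independent per-cell unit-mean lognormal factors at a given
  CV (cycle times are positive, and embryo-to-embryo variation is
  multiplicative in this framework; 3% for well-curated wild-type cohorts,
  5% for the clustering/slope analyses). The sample CV converges to the
  nominal CV (tested at ±20% relative, n=200).
- **Perturbations**: subtree pruning (leaves a lone sibling on purpose —
  real truncation artifacts look like this) and origin→destination homeotic
  swaps, which overwrite the origin subtree position-wise with the
  template's destination pattern rescaled by the embryo's clock and
  re-noised at the embryo's CV.

What the generator does **not** emulate: heritable (lineage-correlated)
noise, cell positions or contacts, marker expression, division failures
mid-cohort, or imaging/curation artifacts beyond truncation. Passing tests
therefore demonstrate the correctness and sensitivity of the machinery
under exchangeable per-cell variation, not performance on every failure
mode of real screen data.

## Problem sizes and tolerances

The test suite runs in ~25 s and the acceptance script in ~20 s on one CPU.
Randomized checks use 500 tree triples (axioms), 100 pairs at depth ≤ 4
(recursion vs enumeration), and 500 pairs (union identity, 1e-9 relative).
Simulation analyses use 363-cell embryos: shuffled-pair correlations (|r| <
0.1 vs birth-time R² > 0.3), the 21+9 batch cohort (exact recovery, mean
cross-group slope 0.80 ± 0.02), slope recovery for clocks 0.5/0.8/1.25
(±0.02, averaged over 5 pairs), permutation calibration against exact
enumeration of C(8,4) splits, and the two-fate transformation scan with a
200-repetition null. Numerical comparisons that should be exact (identity,
determinism, reciprocal slope) are asserted at 1e-9–1e-12; Monte-Carlo
estimates at 3 standard errors.
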