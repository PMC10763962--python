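"""Cohort-level analyses: distance matrices, clustering, and significance tests.

An embryo cohort is compared pairwise under one of the tree metrics, single-
linkage clustered, and the dendrogram cut at the largest gap between
successive merge heights — the operational version of "a large distance
between generations" of merges.  Distribution-level differences are tested
with a pooled permutation test on |Δmean|, and cluster composition with
one-sided Boschloo exact tests under Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .metrics import (
    generalized_branch_distance,
    intersection_branch_distance,
    tree_edit_distance,
    union_branch_distance,
)

METRICS = {
    "ted": lambda x, y: float(tree_edit_distance(x, y)),
    "ibd": lambda x, y: intersection_branch_distance(x, y).value,
    "ubd": lambda x, y: union_branch_distance(x, y).value,
    "gbd": lambda x, y: generalized_branch_distance(x, y)[0].value,
}


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal, minutes

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v


@dataclass
class Dendrogram:
    """Single-linkage merge list in scipy linkage format (heights in minutes)."""

    labels: list[str]
    merges: np.ndarray  # (n-1, 4) scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]  # label -> cluster index, contiguous from 1
    k: int
    cut_height: float


@dataclass
class PermutationTestResult:
    observed_diff: float
    p_value: float
    iterations: int
    seed: int
    smoothed: bool = False


@dataclass
class EnrichmentResult:
    cluster: int
    label_class: str
    in_cluster_in_class: int
    in_cluster_total: int
    class_total: int
    cohort_total: int
    p_value: float
    significant: bool


def _label_of(item, i: int) -> str:
    for attr in ("embryo_id", "origin_embryo"):
        v = getattr(item, attr, None)
        if v:
            return str(v)
    return f"item{i}"


def pairwise_distance_matrix(cohort, metric: str = "ubd", labels=None) -> DistanceMatrix:
    """All-pairs distance matrix over a cohort under one of the tree metrics."""
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("need at least 2 items")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}, got {metric!r}")
    fn = METRICS[metric]
    if labels is None:
        labels = [_label_of(item, i) for i, item in enumerate(cohort)]
    n = len(cohort)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = fn(cohort[i], cohort[j])
            except Exception as e:
                raise ValueError(
                    f"metric {metric!r} failed on pair ({labels[i]}, {labels[j]}): {e}"
                ) from e
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(labels), values=values)


def single_linkage(matrix: DistanceMatrix) -> Dendrogram:
    """Single-linkage agglomeration of a distance matrix.

    Merge heights are the minimum inter-cluster distances and are therefore
    non-decreasing; ties resolve deterministically to the lowest pair index.
    """
    condensed = squareform(matrix.values, checks=True)
    merges = hierarchy.linkage(condensed, method="single")
    return Dendrogram(labels=list(matrix.labels), merges=merges)


def cut_largest_gap(dendrogram: Dendrogram, k: int | None = None) -> ClusterAssignment:
    """Cut a dendrogram into clusters.

    With *k* given, cut to exactly k clusters.  Otherwise choose the cut in
    the largest gap between successive merge heights, searched over cuts
    yielding 2 <= k <= n/2 (the trivial everything-in-one-cluster side is
    excluded); ties go to the smaller k.
    """
    n = len(dendrogram.labels)
    if k is not None:
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}], got {k}")
        chosen_k = k
    else:
        h = dendrogram.heights
        k_max = max(2, n // 2)
        best = (-np.inf, 2)
        for kk in range(2, k_max + 1):
            # cutting away the top kk-1 merges leaves kk clusters
            gap = h[n - kk] - h[n - kk - 1]
            if gap > best[0]:
                best = (gap, kk)
        chosen_k = best[1]
    flat = hierarchy.fcluster(dendrogram.merges, t=chosen_k, criterion="maxclust")
    # relabel contiguously in order of first appearance
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for label, c in zip(dendrogram.labels, flat):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        assignment[label] = relabel[c]
    actual_k = len(relabel)
    if actual_k == n and chosen_k < n:
        pass  # degenerate all-singleton case; report what scipy produced
    h = dendrogram.heights
    if chosen_k >= n:
        cut_height = 0.0
    elif chosen_k <= 1:
        cut_height = float(h[-1]) if len(h) else 0.0
    else:
        cut_height = float((h[n - chosen_k] + h[n - chosen_k - 1]) / 2)
    return ClusterAssignment(assignment=assignment, k=actual_k, cut_height=cut_height)


def permutation_mean_diff_test(
    a,
    b,
    iterations: int = 1_000_000,
    seed: int = 0,
    smoothed: bool = False,
) -> PermutationTestResult:
    """Pooled permutation test on the absolute difference of group means.

    The two samples are pooled and repeatedly re-split into groups of the
    original sizes by sampling without replacement; the p-value is the
    fraction of resamples whose |mean_a* - mean_b*| is at least the observed
    |Δmean|.  The raw count/iterations estimate can be 0; ``smoothed=True``
    reports the add-one estimate (count+1)/(iterations+1) instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    observed = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    na, n = a.size, pool.size
    total = pool.sum()
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(iterations, 200_000 // max(n, 1)))
    done = 0
    tol = 1e-12 * max(1.0, observed)
    while done < iterations:
        m = min(chunk, iterations - done)
        mat = rng.permuted(np.broadcast_to(pool, (m, n)).copy(), axis=1)
        sa = mat[:, :na].sum(axis=1)
        diffs = np.abs(sa / na - (total - sa) / (n - na))
        count += int(np.sum(diffs >= observed - tol))
        done += m
    p = (count + 1) / (iterations + 1) if smoothed else count / iterations
    return PermutationTestResult(
        observed_diff=float(observed),
        p_value=float(p),
        iterations=iterations,
        seed=seed,
        smoothed=smoothed,
    )


def cluster_enrichment(
    assignment: ClusterAssignment,
    labels: dict[str, str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-(cluster, class) overrepresentation tests.

    Each test is a one-sided Boschloo exact test on the 2x2 table of class
    membership inside vs outside the cluster; the significance threshold is
    Bonferroni-corrected by the number of tests actually performed.
    """
    missing = [e for e in assignment.assignment if e not in labels]
    if missing:
        raise ValueError(f"unlabeled embryos: {missing[:5]}")
    embryos = list(assignment.assignment)
    n_total = len(embryos)
    classes = sorted({labels[e] for e in embryos})
    clusters = sorted(set(assignment.assignment.values()))
    tests: list[tuple[int, str, int, int, int]] = []
    for cl in clusters:
        in_cluster = [e for e in embryos if assignment.assignment[e] == cl]
        for cls in classes:
            class_total = sum(1 for e in embryos if labels[e] == cls)
            if class_total == 0:
                warnings.warn(f"class {cls!r} has no members; skipped", stacklevel=2)
                continue
            a_count = sum(1 for e in in_cluster if labels[e] == cls)
            tests.append((cl, cls, a_count, len(in_cluster), class_total))
    n_tests = len(tests)
    threshold = alpha / n_tests if n_tests else alpha
    results = []
    for cl, cls, a_count, cluster_total, class_total in tests:
        table = np.array(
            [
                [a_count, cluster_total - a_count],
                [class_total - a_count, n_total - cluster_total - class_total + a_count],
            ]
        )
        res = stats.boschloo_exact(table, alternative="greater")
        p = float(res.pvalue)
        results.append(
            EnrichmentResult(
                cluster=cl,
                label_class=cls,
                in_cluster_in_class=a_count,
                in_cluster_total=cluster_total,
                class_total=class_total,
                cohort_total=n_total,
                p_value=p,
                significant=bool(p < threshold),
            )
        )
    return results
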