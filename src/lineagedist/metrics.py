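"""Tree comparison metrics for name-labeled binary lineage trees.

Four distances are provided, all exploiting the fact that stereotyped
lineages carry a canonical name-based alignment:

* **tree edit distance** — the size of the symmetric difference between the
  two trees' cell-name sets: the number of node insertions/deletions turning
  one topology into the other.
* **intersection branch distance** — the L2 norm of cycle-time differences
  over cells present in both trees; blind to topology changes.  This is a
  pseudo-metric: two trees that agree on their shared cells but differ in
  topology are at distance 0.
* **union branch distance** — the L2 norm over the union of cells with
  missing cells' cycle times imputed as 0; sensitive to both timing and
  topology, and a true metric for strictly positive cycle times.
* **generalized branch distance** — the minimum union-style branch distance
  over all alignments of the two trees that respect depth (nodes pair only
  with nodes at the same depth below their root) and structure (the children
  of an aligned pair may pair only with each other).  It drops the reliance
  on labels entirely and is the natural extension to non-stereotyped
  lineages.  For binary trees the alignment search reduces to a choice, at
  every aligned internal pair, between the straight and the swapped pairing
  of the two children — solved exactly either by exhaustive enumeration or
  by a memoized recursion; both are implemented and agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np

from .core import (
    KeySpaceError,
    Lineage,
    Sublineage,
    cells_of,
    is_normalized_name,
)


@dataclass
class AlignedPairVector:
    """The canonical name-based pairing of two trees' cycle times."""

    entries: list[tuple[str, float, float]]
    unmatched_x: list[tuple[str, float]]
    unmatched_y: list[tuple[str, float]]

    @property
    def n_shared(self) -> int:
        return len(self.entries)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.entries:
            return np.empty(0), np.empty(0)
        a = np.array([(tx, ty) for _, tx, ty in self.entries], dtype=float)
        return a[:, 0], a[:, 1]


@dataclass
class BranchDistanceValue:
    """A branch distance in minutes, tagged with its variant."""

    value: float
    variant: str
    n_shared: int

    def __float__(self) -> float:
        return self.value


@dataclass
class TreeAlignment:
    """A one-to-one, depth- and structure-respecting pairing of two trees."""

    pairs: list[tuple[str, str]]
    unmatched_x: list[str] = field(default_factory=list)
    unmatched_y: list[str] = field(default_factory=list)


def _keyspace(cells) -> str:
    if not cells:
        return "any"
    return "normalized" if all(is_normalized_name(n) for n in cells) else "sulston"


def _check_same_keyspace(cx, cy) -> None:
    kx, ky = _keyspace(cx), _keyspace(cy)
    if "any" not in (kx, ky) and kx != ky:
        raise KeySpaceError(
            f"cannot align raw Sulston names with root-normalized names ({kx} vs {ky})"
        )


def align_by_name(X, Y) -> AlignedPairVector:
    """Pair cycle times by cell name; the canonical alignment of two lineages."""
    cx, cy = cells_of(X), cells_of(Y)
    _check_same_keyspace(cx, cy)
    shared = sorted(cx.keys() & cy.keys())
    return AlignedPairVector(
        entries=[(k, cx[k], cy[k]) for k in shared],
        unmatched_x=[(k, cx[k]) for k in sorted(cx.keys() - cy.keys())],
        unmatched_y=[(k, cy[k]) for k in sorted(cy.keys() - cx.keys())],
    )


def tree_edit_distance(X, Y) -> int:
    """Number of node insertions/deletions between the two trees.

    With the canonical name alignment this is exactly the size of the
    symmetric difference (XOR) of the two cell-name sets.
    """
    cx, cy = cells_of(X), cells_of(Y)
    _check_same_keyspace(cx, cy)
    return len(cx.keys() ^ cy.keys())


def intersection_branch_distance(X, Y, allow_empty: bool = False) -> BranchDistanceValue:
    """L2 distance between cycle times over the cells shared by both trees.

    An empty intersection is an error by default (a silent 0 would claim two
    unrelated trees are identical); pass ``allow_empty=True`` to get 0 with a
    warning instead.
    """
    pairs = align_by_name(X, Y)
    tx, ty = pairs.arrays()
    if pairs.n_shared == 0:
        if allow_empty:
            import warnings

            warnings.warn("empty intersection; returning distance 0", stacklevel=2)
            return BranchDistanceValue(0.0, "intersection", 0)
        raise ValueError("trees share no cells; intersection branch distance undefined")
    return BranchDistanceValue(float(np.sqrt(np.sum((tx - ty) ** 2))), "intersection", pairs.n_shared)


def union_branch_distance(X, Y) -> BranchDistanceValue:
    """L2 distance over the union of cells, imputing 0 for missing cells.

    Equivalently: the intersection term plus the squared cycle times of all
    unmatched cells, square-rooted.
    """
    pairs = align_by_name(X, Y)
    tx, ty = pairs.arrays()
    sq = float(np.sum((tx - ty) ** 2))
    sq += sum(t * t for _, t in pairs.unmatched_x)
    sq += sum(t * t for _, t in pairs.unmatched_y)
    return BranchDistanceValue(math.sqrt(sq), "union", pairs.n_shared)


# ---------------------------------------------------------------------------
# generalized branch distance


class _Node:
    __slots__ = ("key", "t", "children", "subtree_sq", "depth")

    def __init__(self, key: str, t: float):
        self.key = key
        self.t = t
        self.children: list[_Node] = []
        self.subtree_sq = 0.0
        self.depth = 0


def _build_tree(obj) -> _Node:
    """Materialize a single rooted tree from a cells mapping."""
    from .core import parent_of

    cells = cells_of(obj)
    if not cells:
        raise ValueError("empty tree")
    nodes = {k: _Node(k, t) for k, t in cells.items()}
    roots = []
    for k, node in nodes.items():
        p = parent_of(k)
        if p is not None and p in nodes:
            nodes[p].children.append(node)
        else:
            roots.append(node)
    if len(roots) != 1:
        raise ValueError(
            f"input is a forest with {len(roots)} roots; extract a single rooted "
            "(sub)tree first"
        )
    root = roots[0]

    def finish(n: _Node, depth: int) -> float:
        n.depth = depth
        n.children.sort(key=lambda c: c.key)
        n.subtree_sq = n.t * n.t + sum(finish(c, depth + 1) for c in n.children)
        return n.subtree_sq

    finish(root, 0)
    return root


def _tree_depth(n: _Node) -> int:
    return 1 + max((_tree_depth(c) for c in n.children), default=-1)


def _collect_keys(n: _Node, out: list[str]) -> None:
    out.append(n.key)
    for c in n.children:
        _collect_keys(c, out)


def _pair_cost(u: _Node | None, v: _Node | None, memo) -> tuple[float, int]:
    """(squared cost, mismatch count) of optimally aligning subtree u with subtree v.

    Unmatched subtrees contribute their full squared weight (union
    semantics).  Mismatches — aligned nodes whose names differ — are
    minimized secondarily, so that among equally good alignments the one
    closest to the canonical name alignment is reported.
    """
    if u is None and v is None:
        return 0.0, 0
    if u is None:
        return v.subtree_sq, 0
    if v is None:
        return u.subtree_sq, 0
    key = (id(u), id(v))
    hit = memo.get(key)
    if hit is not None:
        return hit
    base = (u.t - v.t) ** 2
    mm = 0 if u.key == v.key else 1
    uc = u.children + [None] * (2 - len(u.children))
    vc = v.children + [None] * (2 - len(v.children))
    straight = _add(_pair_cost(uc[0], vc[0], memo), _pair_cost(uc[1], vc[1], memo))
    swapped = _add(_pair_cost(uc[0], vc[1], memo), _pair_cost(uc[1], vc[0], memo))
    best = min(straight, swapped)  # lexicographic: cost first, then mismatches
    out = (base + best[0], mm + best[1])
    memo[key] = out
    return out


def _add(a: tuple[float, int], b: tuple[float, int]) -> tuple[float, int]:
    return a[0] + b[0], a[1] + b[1]


def _emit_alignment(u, v, memo, alignment: TreeAlignment) -> None:
    if u is None and v is None:
        return
    if u is None:
        _collect_keys(v, alignment.unmatched_y)
        return
    if v is None:
        _collect_keys(u, alignment.unmatched_x)
        return
    alignment.pairs.append((u.key, v.key))
    uc = u.children + [None] * (2 - len(u.children))
    vc = v.children + [None] * (2 - len(v.children))
    straight = _add(_pair_cost(uc[0], vc[0], memo), _pair_cost(uc[1], vc[1], memo))
    swapped = _add(_pair_cost(uc[0], vc[1], memo), _pair_cost(uc[1], vc[0], memo))
    if straight <= swapped:
        _emit_alignment(uc[0], vc[0], memo, alignment)
        _emit_alignment(uc[1], vc[1], memo, alignment)
    else:
        _emit_alignment(uc[0], vc[1], memo, alignment)
        _emit_alignment(uc[1], vc[0], memo, alignment)


def _enumerate_alignments(u: _Node | None, v: _Node | None):
    """Yield (squared cost, pairs) for every feasible alignment; exponential."""
    if u is None and v is None:
        yield 0.0, []
        return
    if u is None:
        yield v.subtree_sq, []
        return
    if v is None:
        yield u.subtree_sq, []
        return
    base = (u.t - v.t) ** 2
    uc = u.children + [None] * (2 - len(u.children))
    vc = v.children + [None] * (2 - len(v.children))
    pairings = [((uc[0], vc[0]), (uc[1], vc[1])), ((uc[0], vc[1]), (uc[1], vc[0]))]
    if uc == [None, None] or vc == [None, None]:
        pairings = pairings[:1]  # no children to permute
    for (l0, r0), (l1, r1) in pairings:
        for sq0, p0 in _enumerate_alignments(l0, r0):
            for sq1, p1 in _enumerate_alignments(l1, r1):
                yield base + sq0 + sq1, [(u.key, v.key)] + p0 + p1


_EXHAUSTIVE_DEPTH_CAP = 6


def generalized_branch_distance(
    X, Y, mode: str = "recursive"
) -> tuple[BranchDistanceValue, TreeAlignment]:
    """Minimum branch distance over all depth/structure-respecting alignments.

    ``recursive`` (default) solves the child-pairing recursion with
    memoization; ``exhaustive`` enumerates every alignment (guarded to trees
    of depth <= 6, since the alignment count doubles at each internal pair).
    Unmatched subtrees contribute their squared weight, mirroring the union
    branch distance, so the result remains a metric on unequal topologies.
    Among minimizing alignments, the one with fewest name mismatches against
    the canonical alignment is returned.
    """
    rx, ry = _build_tree(X), _build_tree(Y)
    memo: dict = {}
    best_sq, _ = _pair_cost(rx, ry, memo)
    if mode == "exhaustive":
        if _tree_depth(rx) > _EXHAUSTIVE_DEPTH_CAP or _tree_depth(ry) > _EXHAUSTIVE_DEPTH_CAP:
            raise ValueError(
                f"exhaustive mode is capped at depth {_EXHAUSTIVE_DEPTH_CAP}; use mode='recursive'"
            )
        best_sq = min(sq for sq, _ in _enumerate_alignments(rx, ry))
    elif mode != "recursive":
        raise ValueError(f"mode must be 'recursive' or 'exhaustive', got {mode!r}")
    alignment = TreeAlignment(pairs=[])
    _emit_alignment(rx, ry, memo, alignment)
    value = math.sqrt(max(best_sq, 0.0))
    return (
        BranchDistanceValue(value, "generalized", len(alignment.pairs)),
        alignment,
    )


def alignment_mismatch_fraction(alignment: TreeAlignment, X=None, Y=None) -> float:
    """Fraction of aligned cells whose partner sits at a different canonical position.

    This is the per-pair diagnostic of how far a minimizing alignment strays
    from the name-based alignment.
    """
    if not alignment.pairs:
        return 0.0
    return sum(1 for a, b in alignment.pairs if a != b) / len(alignment.pairs)
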