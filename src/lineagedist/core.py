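"""Core data model for stereotyped cell lineages.

A lineage is represented the way lineage-tracing data is delivered: a flat
mapping from Sulston cell names to cell cycle times (minutes).  The Sulston
naming convention makes the tree implicit — every non-founder cell's name is
its mother's name plus one letter encoding the division axis (a/p
anterior/posterior, l/r left/right, d/v dorsal/ventral) — so parent, child and
generation queries never need explicit edges.  Founder cells (P0, AB, P1, EMS,
MS, E, C, P2–P4, D, Z2, Z3) are related by a fixed table instead.

Sublineages extracted for cross-lineage comparison are re-keyed into a
root-normalized namespace: the root becomes ``Q`` and each subsequent letter
is collapsed onto the anterior/posterior axis ({a,l,d}→a, {p,r,v}→p), so that
e.g. the subtrees below ``ABal`` and ``ABpr`` become directly alignable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping


class LineageError(Exception):
    """Base class for lineage data errors."""


class NamingError(LineageError, ValueError):
    """A cell name that cannot be parsed under the Sulston convention."""


class MissingCellError(LineageError, KeyError):
    """A referenced cell is absent from the lineage."""


class IntegrityError(LineageError, ValueError):
    """The lineage violates a structural invariant (broken ancestry, single child)."""


class ContainmentError(LineageError, ValueError):
    """A cell is not a descendant of the requested sublineage root."""


class KeySpaceError(LineageError, ValueError):
    """Two inputs mix raw Sulston names with root-normalized names."""


# Founder divisions of the early embryo, anterior daughter first.  All other
# divisions append a single orientation letter to the mother's name.
FOUNDER_CHILDREN: dict[str, tuple[str, str]] = {
    "P0": ("AB", "P1"),
    "P1": ("EMS", "P2"),
    "EMS": ("MS", "E"),
    "P2": ("C", "P3"),
    "P3": ("D", "P4"),
    "P4": ("Z2", "Z3"),
}

FOUNDER_PARENT: dict[str, str] = {
    child: parent for parent, kids in FOUNDER_CHILDREN.items() for child in kids
}

FOUNDERS: frozenset[str] = frozenset(FOUNDER_CHILDREN) | frozenset(FOUNDER_PARENT)

SUFFIX_LETTERS = frozenset("aplrdv")
ANTERIOR_LETTERS = frozenset("ald")
POSTERIOR_LETTERS = frozenset("prv")

NORMALIZED_ROOT = "Q"


def _founder_generation(founder: str) -> int:
    g = 0
    cur = founder
    while cur in FOUNDER_PARENT:
        cur = FOUNDER_PARENT[cur]
        g += 1
    return g


_FOUNDER_GENERATION = {f: _founder_generation(f) for f in FOUNDERS}


def is_normalized_name(name: str) -> bool:
    """True for names in the root-normalized namespace (``Q`` plus a/p letters)."""
    return (
        len(name) >= 1
        and name[0] == NORMALIZED_ROOT
        and all(c in "ap" for c in name[1:])
    )


def parse_cell_name(name: str) -> tuple[str, str]:
    """Split a Sulston name into (founder, suffix).

    The founder prefix must resolve against the founder table and the suffix
    may only contain orientation letters.  Longest founder match wins, which
    disambiguates e.g. ``E`` vs ``EMS``.
    """
    name = name.strip()
    if not name:
        raise NamingError("empty cell name")
    best: tuple[str, str] | None = None
    for founder in FOUNDERS:
        if name.startswith(founder):
            suffix = name[len(founder):]
            if all(c in SUFFIX_LETTERS for c in suffix):
                if best is None or len(founder) > len(best[0]):
                    best = (founder, suffix)
    if best is None:
        raise NamingError(f"unparseable cell name: {name!r}")
    return best


def parent_of(name: str) -> str | None:
    """Mother cell of *name*: suffix truncation, or the founder table; P0 → None."""
    if is_normalized_name(name):
        return name[:-1] if len(name) > 1 else None
    founder, suffix = parse_cell_name(name)
    if suffix:
        return name[:-1]
    return FOUNDER_PARENT.get(founder)  # None for the zygote P0


def generation_of(name: str) -> int:
    """Number of divisions separating the cell from the zygote (P0 = 0).

    Normalized names are counted relative to their ``Q`` root.
    """
    if is_normalized_name(name):
        return len(name) - 1
    founder, suffix = parse_cell_name(name)
    return _FOUNDER_GENERATION[founder] + len(suffix)


def child_names(name: str) -> tuple[str, ...]:
    """All names a daughter of *name* may take under the naming rules."""
    if is_normalized_name(name):
        return (name + "a", name + "p")
    founder, suffix = parse_cell_name(name)
    if not suffix and founder in FOUNDER_CHILDREN:
        return FOUNDER_CHILDREN[founder]
    return tuple(name + c for c in "alpdrv")


@dataclass
class Lineage:
    """One embryo's recorded lineage: Sulston cell names → cycle times (min).

    May be a forest: any founder whose table parent is absent acts as a root.
    """

    embryo_id: str
    cells: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    def __contains__(self, name: str) -> bool:
        return name in self.cells

    def roots(self) -> list[str]:
        out = []
        for name in self.cells:
            p = parent_of(name)
            if p is None or p not in self.cells:
                out.append(name)
        return sorted(out, key=lambda n: (generation_of(n), n))


@dataclass
class Sublineage:
    """A root-normalized subtree extracted from a lineage for comparison.

    Keys are ``Q``-rooted names; values are cycle times in minutes.
    """

    origin_embryo: str
    original_root: str
    cells: dict[str, float]
    depth_limit: int | None = None

    def __len__(self) -> int:
        return len(self.cells)

    def __contains__(self, name: str) -> bool:
        return name in self.cells


def cells_of(obj) -> Mapping[str, float]:
    """The name → cycle-time mapping of a Lineage, Sublineage or plain dict."""
    if isinstance(obj, (Lineage, Sublineage)):
        return obj.cells
    if isinstance(obj, Mapping):
        return obj
    raise TypeError(f"expected Lineage, Sublineage or mapping, got {type(obj)!r}")


def children_of(obj, name: str) -> set[str]:
    """The daughters of *name* present in the lineage (0, 1 or 2 of them).

    A count of exactly 1 is an invariant violation; it is surfaced by
    :func:`validate_lineage` rather than raised here so that truncation
    artifacts can be inspected.
    """
    cells = cells_of(obj)
    if name not in cells:
        raise MissingCellError(name)
    return {c for c in child_names(name) if c in cells}


def birth_time(obj, name: str) -> float:
    """Time of *name*'s birth: the sum of its recorded ancestors' cycle times.

    A root of the recorded forest is born at 0.  If the ancestor chain is
    broken (an absent parent below a present grandparent) the data is
    corrupt and an IntegrityError is raised.
    """
    cells = cells_of(obj)
    if name not in cells:
        raise MissingCellError(name)
    total = 0.0
    cur = parent_of(name)
    while cur is not None and cur in cells:
        total += cells[cur]
        cur = parent_of(cur)
    # every remaining ancestor must be absent too, else the chain is broken
    while cur is not None:
        if cur in cells:
            raise IntegrityError(
                f"broken ancestor chain for {name!r}: {cur!r} present above a gap"
            )
        cur = parent_of(cur)
    return total


def _path_letters(name: str, root: str) -> list[str] | None:
    """Normalized a/p letters along the path root → name, or None if not under root."""
    letters: list[str] = []
    cur = name
    while cur != root:
        p = parent_of(cur)
        if p is None:
            return None
        if is_normalized_name(cur) or cur[: len(p)] == p and len(cur) == len(p) + 1:
            c = cur[-1]
            letters.append("a" if c in ANTERIOR_LETTERS or c == "a" else "p")
        else:  # founder-table step: anterior-first table order fixes the letter
            kids = FOUNDER_CHILDREN[p]
            letters.append("a" if cur == kids[0] else "p")
        cur = p
    letters.reverse()
    return letters


def normalize_name(name: str, root: str) -> str:
    """Re-key *name* relative to *root*: root → ``Q``, then {a,l,d}→a, {p,r,v}→p."""
    letters = _path_letters(name, root)
    if letters is None:
        raise ContainmentError(f"{name!r} is not {root!r} or one of its descendants")
    return NORMALIZED_ROOT + "".join(letters)


def extract_sublineage(
    obj,
    root: str,
    depth_limit: int | None = None,
    include_root_time: bool = True,
) -> Sublineage:
    """Extract the subtree below *root*, re-keyed into the normalized namespace.

    depth_limit counts generations below the root; None keeps everything.
    By default the root's own cycle time is included as ``Q``; pass
    ``include_root_time=False`` to compare strictly the descendants.
    """
    cells = cells_of(obj)
    if root not in cells:
        raise MissingCellError(root)
    out: dict[str, float] = {}
    stack: list[tuple[str, str, int]] = [(root, NORMALIZED_ROOT, 0)]
    while stack:
        name, norm, depth = stack.pop()
        out[norm] = cells[name]
        if depth_limit is not None and depth >= depth_limit:
            continue
        for child in child_names(name):
            if child in cells:
                letter = "a" if (
                    child[-1] in ANTERIOR_LETTERS
                    if child[: len(name)] == name and len(child) == len(name) + 1
                    else child == FOUNDER_CHILDREN[name][0]
                ) else "p"
                stack.append((child, norm + letter, depth + 1))
    if not include_root_time:
        del out[NORMALIZED_ROOT]
    embryo = obj.embryo_id if isinstance(obj, Lineage) else getattr(obj, "origin_embryo", "")
    return Sublineage(
        origin_embryo=embryo,
        original_root=root,
        cells=out,
        depth_limit=depth_limit,
    )


def validate_lineage(obj) -> list[str]:
    """Check all Lineage invariants; returns human-readable violations (empty = valid).

    Rules: parseable names, strictly positive finite cycle times, parent
    closure (a suffix-bearing cell's mother must be recorded), and the binary
    division rule (0 or 2 recorded daughters per cell).
    """
    cells = cells_of(obj)
    violations: list[str] = []
    normalized_space = any(is_normalized_name(n) for n in cells)
    for name, t in cells.items():
        try:
            if normalized_space:
                if not is_normalized_name(name):
                    raise NamingError(name)
            else:
                parse_cell_name(name)
        except NamingError:
            violations.append(f"{name}: unparseable cell name")
            continue
        if not (isinstance(t, (int, float)) and math.isfinite(t) and t > 0):
            violations.append(f"{name}: cycle time must be finite and > 0, got {t!r}")
        p = parent_of(name)
        if p is not None and p not in cells:
            # founder roots may start a tree mid-forest; suffix-bearing cells may not
            suffixed = is_normalized_name(name) or bool(parse_cell_name(name)[1])
            if suffixed:
                violations.append(f"{name}: parent {p} absent (parent-closure)")
        present_children = {c for c in child_names(name) if c in cells}
        if len(present_children) == 1:
            violations.append(
                f"{name}: exactly one recorded daughter "
                f"({next(iter(present_children))}) violates the binary division rule"
            )
        elif len(present_children) > 2:
            violations.append(f"{name}: more than two recorded daughters")
    return violations
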