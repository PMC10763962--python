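"""Seeded synthetic embryo cohorts with the statistical structure of real screens.

The generator emulates the features the analyses in this package key on:

* a stereotyped template lineage — complete binary sublineages under the
  founder cells, with cycle times growing with generation and multiplicative
  *signature* factors giving each sublineage its own timing pattern (the
  synthetic analog of lineage-specific developmental programs);
* embryo-level multiplicative *clock* factors (global rate-of-development
  differences on the order of 20%, the batch effect seen between wild-type
  imaging groups);
* independent per-cell lognormal noise at a configurable coefficient of
  variation (a few percent in well-curated wild-type data);
* perturbations: subtree pruning (topology defects) and origin→destination
  timing swaps (homeotic transformations of the timing pattern).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import (
    Lineage,
    NamingError,
    child_names,
    generation_of,
    is_normalized_name,
    normalize_name,
    parse_cell_name,
)


def _default_base_cycle(generation: int) -> float:
    # early cleavage cycles are short (~15 min); somatic cycles lengthen
    # roughly geometrically, reaching tens of minutes by the ~350-cell stage
    return 12.0 * 1.28**generation


@dataclass
class TemplateSpec:
    """Declarative description of the deterministic template lineage.

    roots maps each subtree root to the number of generations built below it
    (0 = just the root).  base_cycle gives the per-generation baseline in
    minutes: a constant, a {generation: minutes} table, or a callable.
    signature_overrides multiplies the baseline for a root and all its
    descendants; nested overrides compose.
    """

    roots: Mapping[str, int]
    base_cycle: float | Mapping[int, float] | Callable[[int], float] = _default_base_cycle
    signature_overrides: Mapping[str, float] = field(default_factory=dict)

    def baseline(self, generation: int) -> float:
        if callable(self.base_cycle):
            return float(self.base_cycle(generation))
        if isinstance(self.base_cycle, Mapping):
            return float(self.base_cycle[generation])
        return float(self.base_cycle)


@dataclass
class CohortSpec:
    """Declarative description of a simulated cohort.

    groups: (n_embryos, clock_factor, noise_cv) per batch.  perturbations:
    (embryo_index, op) where op is {"op": "prune", "root": ...} or
    {"op": "swap", "origin": ..., "destination": ...}.
    """

    groups: Sequence[tuple[int, float, float]]
    perturbations: Sequence[tuple[int, dict]] = ()
    template: TemplateSpec | None = None
    seed: int = 0


#: Template mirroring a curated early C. elegans lineage: a deep AB subtree,
#: shallower P1-derived founders, ~360 cells, and sublineage-specific timing
#: signatures strong enough to make each fate's pattern distinctive.
DEFAULT_TEMPLATE = TemplateSpec(
    roots={
        "P0": 0, "P1": 0, "EMS": 0, "P2": 0, "P3": 0, "P4": 0, "Z2": 0, "Z3": 0,
        "AB": 7, "MS": 4, "E": 4, "C": 4, "D": 2,
    },
    signature_overrides={
        "ABa": 0.85, "ABp": 1.15,
        "ABal": 0.90, "ABpr": 1.08,
        "MS": 0.92, "E": 1.18, "C": 1.06,
    },
)


def _is_prefix_descendant(name: str, root: str) -> bool:
    """ancestor-or-self test that works in both key spaces."""
    if is_normalized_name(root):
        return name.startswith(root)
    if name == root:
        return True
    from .core import parent_of

    cur = name
    while cur is not None:
        if cur == root:
            return True
        cur = parent_of(cur)
    return False


def make_template(spec: TemplateSpec) -> Lineage:
    """Deterministic template lineage: complete binary subtrees per root."""
    cells: dict[str, float] = {}
    for root, depth in spec.roots.items():
        if not is_normalized_name(root):
            parse_cell_name(root)  # NamingError on invalid roots
        stack = [(root, 0)]
        while stack:
            name, d = stack.pop()
            factor = 1.0
            for ov_root, ov in spec.signature_overrides.items():
                if _is_prefix_descendant(name, ov_root):
                    factor *= ov
            cells[name] = spec.baseline(generation_of(name)) * factor
            if d < depth:
                for child in child_names(name)[:2] if is_normalized_name(name) else _template_children(name):
                    stack.append((child, d + 1))
    return Lineage(embryo_id="template", cells=cells, meta={"template": True})


def _template_children(name: str) -> tuple[str, str]:
    from .core import FOUNDER_CHILDREN

    founder, suffix = parse_cell_name(name)
    if not suffix and founder in FOUNDER_CHILDREN:
        return FOUNDER_CHILDREN[founder]
    # ABa and ABp divide left/right (yielding ABal..ABpr); other divisions
    # are built anterior/posterior, matching the usual early-lineage names
    if founder == "AB" and len(suffix) == 1:
        return (name + "l", name + "r")
    return (name + "a", name + "p")


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise at the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=n)


def generate_embryo(
    template: Lineage,
    clock_factor: float = 1.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    embryo_id: str | None = None,
) -> Lineage:
    """One embryo: template x clock x independent per-cell lognormal noise."""
    if clock_factor <= 0:
        raise ValueError("clock_factor must be > 0")
    names = sorted(template.cells)
    rng = np.random.default_rng(seed)
    noise = _lognormal_factors(rng, len(names), noise_cv)
    cells = {
        n: template.cells[n] * clock_factor * float(noise[i]) for i, n in enumerate(names)
    }
    return Lineage(
        embryo_id=embryo_id or f"sim_seed{seed}",
        cells=cells,
        meta={"clock_factor": clock_factor, "noise_cv": noise_cv, "seed": seed},
    )


def apply_homeotic_swap(
    embryo: Lineage,
    origin_root: str,
    destination_root: str,
    template: Lineage,
    seed: int | None = None,
) -> Lineage:
    """Overwrite the origin subtree's timing with the destination's template pattern.

    Values are replaced position-wise (via root-normalized names) by the
    template's destination pattern, rescaled by the embryo's clock factor and
    re-noised at the embryo's noise level (fresh draws, seeded).  Topology is
    untouched — this is a pure timing transformation.
    """
    for root in (origin_root, destination_root):
        if root not in embryo.cells or root not in template.cells:
            raise KeyError(f"{root!r} missing from embryo or template")

    def subtree(obj, root):
        out = {}
        stack = [root]
        cells = obj.cells
        while stack:
            cur = stack.pop()
            out[normalize_name(cur, root)] = cur
            stack.extend(c for c in child_names(cur) if c in cells)
        return out

    origin_map = subtree(embryo, origin_root)  # normalized pos -> embryo cell name
    dest_map = subtree(template, destination_root)  # normalized pos -> template cell name
    if set(origin_map) != set(dest_map):
        raise ValueError(
            f"origin {origin_root!r} and destination {destination_root!r} subtrees "
            "have different shapes; positions cannot be paired"
        )
    clock = float(embryo.meta.get("clock_factor", 1.0))
    cv = float(embryo.meta.get("noise_cv", 0.0))
    rng = np.random.default_rng(embryo.meta.get("seed", 0) + 1 if seed is None else seed)
    positions = sorted(origin_map)
    noise = _lognormal_factors(rng, len(positions), cv)
    cells = dict(embryo.cells)
    for i, pos in enumerate(positions):
        cells[origin_map[pos]] = template.cells[dest_map[pos]] * clock * float(noise[i])
    meta = dict(embryo.meta)
    meta.setdefault("perturbations", []).append(
        {"op": "swap", "origin": origin_root, "destination": destination_root}
    )
    return Lineage(embryo_id=embryo.embryo_id, cells=cells, meta=meta)


def prune_subtree(embryo: Lineage, root: str) -> Lineage:
    """Remove a subtree root and all its descendants (an RNAi topology defect).

    Intentionally leaves the sibling as a lone daughter — real truncation
    artifacts look like this, and the union/tree-edit metrics must see them.
    """
    if root not in embryo.cells:
        raise KeyError(root)
    cells = dict(embryo.cells)
    stack = [root]
    while stack:
        cur = stack.pop()
        cells.pop(cur, None)
        stack.extend(c for c in child_names(cur) if c in cells)
    if not cells:
        raise ValueError("pruning would leave an empty lineage")
    meta = dict(embryo.meta)
    meta.setdefault("perturbations", []).append({"op": "prune", "root": root})
    return Lineage(embryo_id=embryo.embryo_id, cells=cells, meta=meta)


def generate_cohort(spec: CohortSpec) -> list[Lineage]:
    """Deterministic cohort: groups of embryos plus per-embryo perturbations."""
    template = make_template(spec.template) if spec.template else make_template(DEFAULT_TEMPLATE)
    seeds = np.random.SeedSequence(spec.seed).generate_state(
        sum(n for n, _, _ in spec.groups) * 2 + len(spec.perturbations)
    )
    embryos: list[Lineage] = []
    idx = 0
    for g, (n, clock, cv) in enumerate(spec.groups):
        for _ in range(n):
            emb = generate_embryo(
                template,
                clock_factor=clock,
                noise_cv=cv,
                seed=int(seeds[idx] % (2**31)),
                embryo_id=f"g{g}_e{idx}",
            )
            emb.meta["group"] = g
            embryos.append(emb)
            idx += 1
    for j, (target, op) in enumerate(spec.perturbations):
        emb = embryos[target]
        if op["op"] == "prune":
            embryos[target] = prune_subtree(emb, op["root"])
        elif op["op"] == "swap":
            embryos[target] = apply_homeotic_swap(
                emb,
                op["origin"],
                op["destination"],
                template,
                seed=int(seeds[idx + j] % (2**31)),
            )
        else:
            raise ValueError(f"unknown perturbation op {op!r}")
    return embryos


def random_sublineage(
    rng: np.random.Generator,
    max_depth: int = 4,
    split_prob: float = 0.7,
    t_range: tuple[float, float] = (1.0, 10.0),
) -> dict[str, float]:
    """A random root-normalized binary tree with uniform random cycle times.

    Utility for randomized metric testing: grows from ``Q``, each node
    splitting into two children with probability split_prob until max_depth.
    """
    lo, hi = t_range
    cells = {"Q": float(rng.uniform(lo, hi))}
    frontier = ["Q"]
    for _ in range(max_depth):
        nxt = []
        for name in frontier:
            if rng.random() < split_prob:
                for child in (name + "a", name + "p"):
                    cells[child] = float(rng.uniform(lo, hi))
                    nxt.append(child)
        frontier = nxt
    return cells
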