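"""Detection of homeotic timing transformations via reference neighborhoods.

Each candidate fate (a sublineage root such as ABa or ABp) is represented by
the wild-type examples of that sublineage, viewed as a point cloud under the
intersection branch distance.  The cloud's *diameter* D — its maximum
pairwise distance — defines the fate's neighborhood: a perturbed sublineage
is "in the neighborhood" of a reference when its distance to that reference
is strictly less than D.  A perturbed *origin* sublineage is then

* **unperturbed** if it neighbors at least one wild-type example of its own
  fate,
* **transformed** if it neighbors at least one example of a different fate
  (both can hold at once — mixed neighborhoods are reported as such),
* **perturbed** if it neighbors no reference at all.

The transformation score is the neighbor count normalized by the number of
references.  Significance of observed neighbor counts is assessed against a
same-name shuffle null: cycle times are permuted among all same-named cells
across the perturbed cohort and the scan repeated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import Lineage, Sublineage, extract_sublineage
from .metrics import intersection_branch_distance, union_branch_distance


@dataclass
class DestinationProfile:
    """Wild-type reference cloud for one destination fate."""

    destination_root: str
    references: list[Sublineage]
    diameter_D: float

    @property
    def n_refs(self) -> int:
        return len(self.references)


@dataclass
class Classification:
    unperturbed: bool
    transformed: bool

    @property
    def perturbed(self) -> bool:
        return not (self.unperturbed or self.transformed)

    def label(self) -> str:
        if self.unperturbed and self.transformed:
            return "unperturbed+transformed"
        if self.unperturbed:
            return "unperturbed"
        if self.transformed:
            return "transformed"
        return "perturbed"


@dataclass
class TransformationRecord:
    gene: str
    embryo_id: str
    origin_root: str
    destination_root: str
    n_neighbors: int
    n_refs: int
    score: float
    classification: str


@dataclass
class NullConfig:
    repetitions: int = 10_000
    seed: int = 0


_METRIC = {
    "ibd": intersection_branch_distance,
    "ubd": union_branch_distance,
}


def _distance(origin: Sublineage, ref: Sublineage, metric: str) -> float | None:
    if metric == "ibd":
        try:
            return intersection_branch_distance(origin, ref).value
        except ValueError:
            warnings.warn(
                f"origin shares no cells with a {ref.original_root} reference; "
                "reference contributes no neighborhood",
                stacklevel=2,
            )
            return None
    return union_branch_distance(origin, ref).value


def destination_diameter(references: Sequence[Sublineage], metric: str = "ibd") -> float:
    """Maximum pairwise distance among the wild-type references of one fate."""
    references = list(references)
    if not references:
        raise ValueError("empty reference set")
    if len(references) == 1:
        warnings.warn("single reference: diameter is 0, neighborhood is empty", stacklevel=2)
        return 0.0
    dist = _METRIC[metric]
    best = 0.0
    for i in range(len(references)):
        for j in range(i + 1, len(references)):
            best = max(best, dist(references[i], references[j]).value)
    return best


def build_profile(
    wt_cohort: Iterable[Lineage],
    root: str,
    depth_limit: int | None = None,
    metric: str = "ibd",
) -> DestinationProfile:
    """Extract one fate's wild-type reference sublineages and their diameter."""
    refs = [extract_sublineage(lin, root, depth_limit) for lin in wt_cohort]
    return DestinationProfile(
        destination_root=root,
        references=refs,
        diameter_D=destination_diameter(refs, metric),
    )


def count_neighbors(origin: Sublineage, profile: DestinationProfile, metric: str = "ibd") -> int:
    """References strictly within the fate's diameter of the origin sublineage.

    The boundary is strict (< D): at D = 0 only exact matches qualify.
    """
    count = 0
    for ref in profile.references:
        d = _distance(origin, ref, metric)
        if d is not None and d < profile.diameter_D:
            count += 1
    return count


def transformation_score(origin: Sublineage, profile: DestinationProfile, metric: str = "ibd") -> float:
    """Neighbor count normalized by the number of wild-type references."""
    return count_neighbors(origin, profile, metric) / profile.n_refs


def classify_origin(
    origin: Sublineage,
    origin_profile: DestinationProfile,
    all_profiles: Sequence[DestinationProfile],
    metric: str = "ibd",
) -> Classification:
    """Unperturbed / transformed / perturbed call for one origin sublineage."""
    if origin_profile is None:
        raise ValueError("the origin root's own profile is required")
    own = count_neighbors(origin, origin_profile, metric)
    other = 0
    for profile in all_profiles:
        if profile.destination_root == origin_profile.destination_root:
            continue
        other += count_neighbors(origin, profile, metric)
        if other:
            break
    return Classification(unperturbed=own >= 1, transformed=other >= 1)


def _nearest_destination(
    origin: Sublineage,
    profiles: Sequence[DestinationProfile],
    metric: str,
) -> DestinationProfile:
    """Nearest candidate fate: minimal mean distance to that fate's references."""
    best = None
    best_mean = np.inf
    for profile in profiles:
        ds = [_distance(origin, ref, metric) for ref in profile.references]
        ds = [d for d in ds if d is not None]
        mean = np.mean(ds) if ds else np.inf
        if mean < best_mean:
            best_mean = mean
            best = profile
    return best


def transformation_scan(
    rnai_cohort: Iterable[Lineage],
    wt_cohort: Sequence[Lineage],
    roots: Sequence[str],
    annotations=None,
    metric: str = "ibd",
    depth_limit: int | None = None,
    profiles: Sequence[DestinationProfile] | None = None,
) -> list[TransformationRecord]:
    """Score candidate transformations across a perturbed cohort.

    With *annotations* (gene, embryo, origin, destination records), each
    annotated origin is scored against its annotated destination's profile.
    Without annotations every (embryo, origin root) is scored against its
    nearest destination fate.  Precomputed *profiles* may be passed to avoid
    re-extracting the wild-type references (e.g., inside a shuffle null).
    """
    if len(list(wt_cohort)) < 2:
        raise ValueError("need >= 2 wild-type embryos")
    if profiles is None:
        profiles = [build_profile(wt_cohort, r, depth_limit, metric) for r in roots]
    by_root = {p.destination_root: p for p in profiles}
    records: list[TransformationRecord] = []

    def one(embryo: Lineage, gene: str, origin_root: str, dest_profile: DestinationProfile):
        if origin_root not in embryo.cells:
            warnings.warn(
                f"embryo {embryo.embryo_id}: sublineage {origin_root} missing; skipped",
                stacklevel=2,
            )
            return
        origin = extract_sublineage(embryo, origin_root, depth_limit)
        n = count_neighbors(origin, dest_profile, metric)
        cls = classify_origin(origin, by_root[origin_root], profiles, metric)
        records.append(
            TransformationRecord(
                gene=gene,
                embryo_id=embryo.embryo_id,
                origin_root=origin_root,
                destination_root=dest_profile.destination_root,
                n_neighbors=n,
                n_refs=dest_profile.n_refs,
                score=n / dest_profile.n_refs,
                classification=cls.label(),
            )
        )

    if annotations is not None:
        by_embryo = {lin.embryo_id: lin for lin in rnai_cohort}
        for ann in annotations:
            embryo = by_embryo.get(ann.embryo_id)
            if embryo is None:
                warnings.warn(f"annotated embryo {ann.embryo_id!r} not in cohort; skipped", stacklevel=2)
                continue
            if ann.destination_root not in by_root:
                warnings.warn(f"no profile for destination {ann.destination_root!r}; skipped", stacklevel=2)
                continue
            one(embryo, ann.gene, ann.origin_root, by_root[ann.destination_root])
    else:
        for embryo in rnai_cohort:
            gene = str(embryo.meta.get("gene", ""))
            for root in roots:
                if root not in embryo.cells:
                    warnings.warn(
                        f"embryo {embryo.embryo_id}: sublineage {root} missing; skipped",
                        stacklevel=2,
                    )
                    continue
                origin = extract_sublineage(embryo, root, depth_limit)
                dest = _nearest_destination(origin, profiles, metric)
                one(embryo, gene, root, dest)
    return records


def shuffle_same_name(cohort: Sequence[Lineage], seed: int) -> list[Lineage]:
    """Permute cycle times among all same-named cells across the cohort.

    Cells whose name appears in only one embryo keep their value (a
    permutation of one element); the per-name multisets of cycle times are
    preserved exactly.
    """
    rng = np.random.default_rng(seed)
    locations: dict[str, list[int]] = {}
    for i, lin in enumerate(cohort):
        for name in lin.cells:
            locations.setdefault(name, []).append(i)
    new_cells: list[dict[str, float]] = [dict(lin.cells) for lin in cohort]
    for name in sorted(locations):
        idx = locations[name]
        if len(idx) < 2:
            continue
        values = np.array([cohort[i].cells[name] for i in idx])
        perm = rng.permutation(len(idx))
        for slot, i in enumerate(idx):
            new_cells[i][name] = float(values[perm[slot]])
    return [
        Lineage(embryo_id=lin.embryo_id, cells=cells, meta=dict(lin.meta))
        for lin, cells in zip(cohort, new_cells)
    ]


def shuffle_null_scan(
    cohort: Sequence[Lineage],
    wt_cohort: Sequence[Lineage],
    roots: Sequence[str],
    null_config: NullConfig | None = None,
    metric: str = "ibd",
    depth_limit: int | None = None,
) -> dict:
    """Neighbor-count null distribution under same-name shuffling.

    Per repetition: permute cycle times among same-named cells across the
    perturbed cohort, rerun the all-pairs transformation scan, and
    accumulate the histogram of neighbor counts plus how many scanned
    lineages reach all references / at least one reference.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    cfg = null_config or NullConfig()
    profiles = [build_profile(wt_cohort, r, depth_limit, metric) for r in roots]
    n_refs = profiles[0].n_refs if profiles else 0
    histogram = np.zeros(n_refs + 1, dtype=int)
    n_all = 0
    n_ge1 = 0
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.repetitions)
    for rep in range(cfg.repetitions):
        shuffled = shuffle_same_name(cohort, int(seeds[rep] % (2**31)))
        records = transformation_scan(
            shuffled, wt_cohort, roots, metric=metric, depth_limit=depth_limit, profiles=profiles
        )
        for rec in records:
            histogram[rec.n_neighbors] += 1
            if rec.n_neighbors == rec.n_refs:
                n_all += 1
            if rec.n_neighbors >= 1:
                n_ge1 += 1
    return {
        "histogram": histogram,
        "n_all_reference": n_all,
        "n_at_least_one": n_ge1,
        "repetitions": cfg.repetitions,
        "seed": cfg.seed,
        "n_refs": n_refs,
        "roots": list(roots),
    }
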