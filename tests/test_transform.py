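"""The diameter/neighborhood heuristic for homeotic timing transformations."""

import numpy as np
import pytest

import lineagedist as ld

ROOTS = ["ABal", "ABar", "ABpl", "ABpr"]
DEPTH = 4  # 31-cell sublineages, equal size across all scanned roots


@pytest.fixture(scope="module")
def wt_cohort(template):
    return [
        ld.generate_embryo(template, 1.0, 0.03, seed=1000 + i, embryo_id=f"wt{i}")
        for i in range(21)
    ]


@pytest.fixture(scope="module")
def profiles(wt_cohort):
    return {r: ld.build_profile(wt_cohort, r, depth_limit=DEPTH) for r in ROOTS}


class TestDiameter:
    def test_identical_references_zero(self, template):
        sub = ld.extract_sublineage(template, "ABal", DEPTH)
        assert ld.destination_diameter([sub, sub, sub]) == 0.0

    def test_is_max_of_pairwise_oracle(self, profiles):
        for r, profile in profiles.items():
            refs = profile.references
            brute = max(
                ld.intersection_branch_distance(refs[i], refs[j]).value
                for i in range(len(refs))
                for j in range(i + 1, len(refs))
            )
            assert profile.diameter_D == pytest.approx(brute)

    def test_empty_and_singleton(self, profiles):
        with pytest.raises(ValueError):
            ld.destination_diameter([])
        ref = profiles["ABal"].references[0]
        with pytest.warns(UserWarning):
            assert ld.destination_diameter([ref]) == 0.0


class TestNeighborhood:
    def test_exact_copy_is_neighbor(self, profiles):
        profile = profiles["ABal"]
        assert profile.diameter_D > 0
        copy = profile.references[3]
        assert ld.count_neighbors(copy, profile) >= 1

    def test_strict_boundary_counting(self):
        refs = [
            ld.Sublineage(f"w{i}", "ABal", {"Q": t, "Qa": 5.0, "Qp": 5.0})
            for i, t in enumerate([10.0, 12.0, 15.0])
        ]
        profile = ld.DestinationProfile("ABal", refs, ld.destination_diameter(refs))
        assert profile.diameter_D == 5.0
        origin = ld.Sublineage("o", "ABal", {"Q": 16.0, "Qa": 5.0, "Qp": 5.0})
        # distances to refs: 6, 4, 1 -> two strictly inside D=5
        assert ld.count_neighbors(origin, profile) == 2
        assert ld.transformation_score(origin, profile) == pytest.approx(2 / 3)

    def test_far_origin_has_no_neighbors(self, template, profiles):
        emb = ld.generate_embryo(template, 1.0, 0.03, seed=9)
        scaled = ld.Lineage("x", {k: 10 * v for k, v in emb.cells.items()})
        origin = ld.extract_sublineage(scaled, "ABal", DEPTH)
        assert ld.count_neighbors(origin, profiles["ABal"]) == 0


class TestClassification:
    def test_untouched_is_unperturbed(self, template, profiles):
        emb = ld.generate_embryo(template, 1.0, 0.03, seed=500)
        origin = ld.extract_sublineage(emb, "ABal", DEPTH)
        cls = ld.classify_origin(origin, profiles["ABal"], list(profiles.values()))
        assert cls.unperturbed and not cls.perturbed

    def test_swapped_is_transformed(self, template, profiles):
        emb = ld.generate_embryo(template, 1.0, 0.03, seed=501)
        swapped = ld.apply_homeotic_swap(emb, "ABal", "ABpr", template, seed=77)
        origin = ld.extract_sublineage(swapped, "ABal", DEPTH)
        cls = ld.classify_origin(origin, profiles["ABal"], list(profiles.values()))
        assert cls.transformed
        assert ld.transformation_score(origin, profiles["ABpr"]) == 1.0

    def test_scaled_out_is_perturbed(self, template, profiles):
        emb = ld.generate_embryo(template, 1.0, 0.03, seed=502)
        scaled = ld.Lineage("x", {k: 10 * v for k, v in emb.cells.items()}, dict(emb.meta))
        origin = ld.extract_sublineage(scaled, "ABal", DEPTH)
        cls = ld.classify_origin(origin, profiles["ABal"], list(profiles.values()))
        assert cls.perturbed


class TestScan:
    def test_wt_copies_all_unperturbed(self, template, wt_cohort):
        # literal copies of wild-type embryos: distance 0 to their source
        # reference guarantees unperturbed; every other reference is within D
        # except a copy of a diameter-realizing embryo, which sits exactly AT
        # D from its partner (strict boundary), so scores are >= 20/21
        rnai = [
            ld.Lineage(f"r{i}", dict(wt_cohort[i * 5].cells)) for i in range(3)
        ]
        records = ld.transformation_scan(rnai, wt_cohort, ROOTS, depth_limit=DEPTH)
        assert len(records) == 3 * len(ROOTS)
        for rec in records:
            assert rec.classification == "unperturbed"
            assert rec.destination_root == rec.origin_root
            assert rec.n_neighbors >= rec.n_refs - 1

    def test_single_swap_flagged_exactly_once(self, template, wt_cohort):
        rnai = [
            ld.generate_embryo(template, 1.0, 0.03, seed=3100 + i, embryo_id=f"r{i}")
            for i in range(4)
        ]
        rnai[2] = ld.apply_homeotic_swap(rnai[2], "ABal", "ABpr", template, seed=5)
        records = ld.transformation_scan(rnai, wt_cohort, ROOTS, depth_limit=DEPTH)
        flagged = [r for r in records if r.classification == "transformed"]
        assert len(flagged) == 1
        rec = flagged[0]
        assert (rec.embryo_id, rec.origin_root, rec.destination_root) == ("r2", "ABal", "ABpr")
        assert rec.score == 1.0

    def test_annotated_mode_scores_annotated_destination(self, template, wt_cohort):
        rnai = [ld.generate_embryo(template, 1.0, 0.03, seed=3200, embryo_id="r0")]
        rnai[0] = ld.apply_homeotic_swap(rnai[0], "ABal", "ABpr", template, seed=6)
        ann = [ld.io.TransformationAnnotation("glp-1", "r0", "ABal", "ABpr")]
        records = ld.transformation_scan(rnai, wt_cohort, ROOTS, annotations=ann, depth_limit=DEPTH)
        assert len(records) == 1
        assert records[0].gene == "glp-1" and records[0].score == 1.0

    def test_deterministic_under_fixed_inputs(self, template, wt_cohort):
        rnai = [ld.generate_embryo(template, 1.1, 0.03, seed=3300, embryo_id="r0")]
        r1 = ld.transformation_scan(rnai, wt_cohort, ROOTS, depth_limit=DEPTH)
        r2 = ld.transformation_scan(rnai, wt_cohort, ROOTS, depth_limit=DEPTH)
        assert r1 == r2


class TestShuffleNull:
    def test_same_name_shuffle_preserves_per_name_multisets(self, template):
        cohort = [ld.generate_embryo(template, c, 0.05, seed=i, embryo_id=f"e{i}") for i, c in enumerate([1.0, 0.8, 1.2])]
        shuffled = ld.shuffle_same_name(cohort, seed=4)
        for name in cohort[0].cells:
            before = sorted(lin.cells[name] for lin in cohort)
            after = sorted(lin.cells[name] for lin in shuffled)
            assert before == pytest.approx(after)

    def test_identical_cohort_shuffle_is_noop(self, template):
        emb = ld.generate_embryo(template, 1.0, 0.0, seed=0)
        cohort = [ld.Lineage(f"e{i}", dict(emb.cells)) for i in range(4)]
        shuffled = ld.shuffle_same_name(cohort, seed=9)
        for a, b in zip(cohort, shuffled):
            assert a.cells == b.cells

    def test_null_scan_metadata_and_counts(self, template, wt_cohort):
        clocks = [1.0, 0.8, 1.25]
        rnai = [ld.generate_embryo(template, c, 0.03, seed=4000 + i, embryo_id=f"r{i}") for i, c in enumerate(clocks)]
        rnai[0] = ld.apply_homeotic_swap(rnai[0], "ABal", "ABpr", template, seed=8)
        out = ld.shuffle_null_scan(
            rnai, wt_cohort, ROOTS, ld.NullConfig(repetitions=5, seed=77), depth_limit=DEPTH
        )
        assert out["repetitions"] == 5 and out["seed"] == 77
        assert out["histogram"].sum() == 5 * len(clocks) * len(ROOTS)
        # heterogeneous-clock chimeras land outside every wild-type neighborhood
        assert out["n_all_reference"] == 0


class TestMonotonicity:
    def test_diameter_shrinks_when_references_removed(self, profiles):
        profile = profiles["ABal"]
        full_D = profile.diameter_D
        subset = profile.references[:-5]
        assert ld.destination_diameter(subset) <= full_D + 1e-12

    def test_neighbor_count_monotone_in_diameter(self, template, profiles):
        emb = ld.generate_embryo(template, 1.0, 0.03, seed=900)
        origin = ld.extract_sublineage(emb, "ABal", DEPTH)
        profile = profiles["ABal"]
        shrunk = ld.DestinationProfile(
            profile.destination_root, profile.references, profile.diameter_D / 2
        )
        assert ld.count_neighbors(origin, shrunk) <= ld.count_neighbors(origin, profile)
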