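"""Distance matrices, single-linkage clustering, permutation and enrichment tests."""

import itertools

import numpy as np
import pytest

import lineagedist as ld
from lineagedist.cohort import DistanceMatrix


class TestPairwiseMatrix:
    def test_identical_embryos_all_zero(self, template):
        emb = ld.generate_embryo(template, 1.0, 0.0, seed=0)
        cohort = [ld.Lineage(f"e{i}", dict(emb.cells)) for i in range(4)]
        dm = ld.pairwise_distance_matrix(cohort, "ubd")
        assert np.all(dm.values == 0)

    @pytest.mark.parametrize("metric", ["ted", "ibd", "ubd"])
    def test_entries_match_direct_calls(self, metric, template):
        cohort = [ld.generate_embryo(template, 1.0, 0.1, seed=i) for i in range(5)]
        for i, emb in enumerate(cohort):
            if i % 2:
                cohort[i] = ld.prune_subtree(emb, "ABala")
        dm = ld.pairwise_distance_matrix(cohort, metric)
        from lineagedist.cohort import METRICS

        for i, j in itertools.combinations(range(5), 2):
            assert dm.values[i, j] == pytest.approx(METRICS[metric](cohort[i], cohort[j]))
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)


def _mst_single_linkage_heights(d):
    """Oracle: single-linkage merge heights = sorted MST edge weights (Prim)."""
    n = d.shape[0]
    in_tree = [0]
    heights = []
    best = d[0].copy()
    while len(in_tree) < n:
        candidates = [(best[j], j) for j in range(n) if j not in in_tree]
        w, j = min(candidates)
        heights.append(w)
        in_tree.append(j)
        best = np.minimum(best, d[j])
    return sorted(heights)


class TestSingleLinkage:
    def test_two_points(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        dend = ld.single_linkage(dm)
        assert dend.heights.tolist() == [3.0]

    def test_merge_heights_nondecreasing(self, rng):
        for _ in range(10):
            n = 6
            m = rng.uniform(1, 10, (n, n))
            d = np.triu(m, 1) + np.triu(m, 1).T
            dend = ld.single_linkage(DistanceMatrix([f"x{i}" for i in range(n)], d))
            assert np.all(np.diff(dend.heights) >= 0)

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_matches_mst_oracle(self, n, rng):
        for _ in range(20):
            m = rng.uniform(1, 10, (n, n))
            d = np.triu(m, 1) + np.triu(m, 1).T
            dend = ld.single_linkage(DistanceMatrix([f"x{i}" for i in range(n)], d))
            assert dend.heights.tolist() == pytest.approx(_mst_single_linkage_heights(d))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCutLargestGap:
    def _two_blob_matrix(self, rng, n1=4, n2=3):
        n = n1 + n2
        d = rng.uniform(0.1, 1.0, (n, n))
        d[:n1, n1:] = rng.uniform(10, 11, (n1, n2))
        d[n1:, :n1] = d[:n1, n1:].T
        d = np.triu(d, 1) + np.triu(d, 1).T
        return DistanceMatrix([f"x{i}" for i in range(n)], d), n1

    def test_two_blobs_recovered(self, rng):
        dm, n1 = self._two_blob_matrix(rng)
        dend = ld.single_linkage(dm)
        assert dend.heights[-1] >= 10 and np.all(dend.heights[:-1] <= 1)
        assign = ld.cut_largest_gap(dend)
        assert assign.k == 2
        groups = [assign.assignment[l] for l in dm.labels]
        assert len(set(groups[:n1])) == 1 and len(set(groups[n1:])) == 1
        assert groups[0] != groups[-1]

    def test_forced_k(self, rng):
        dm, _ = self._two_blob_matrix(rng)
        assert ld.cut_largest_gap(ld.single_linkage(dm), k=1).k == 1
        assert ld.cut_largest_gap(ld.single_linkage(dm), k=3).k == 3
        with pytest.raises(ValueError):
            ld.cut_largest_gap(ld.single_linkage(dm), k=99)

    def test_batch_effect_cohort_recovered(self):
        """Synthetic clock batch effect: exact recovery of both groups (Fig-3-style)."""
        spec = ld.CohortSpec(groups=[(21, 1.0, 0.05), (9, 0.8, 0.05)], seed=42)
        cohort = ld.generate_cohort(spec)
        dm = ld.pairwise_distance_matrix(cohort, "ubd")
        assign = ld.cut_largest_gap(ld.single_linkage(dm))
        assert assign.k == 2
        clusters = [assign.assignment[e.embryo_id] for e in cohort]
        truth = [e.meta["group"] for e in cohort]
        mapping = {clusters[0]: truth[0], clusters[-1]: truth[-1]}
        assert [mapping[c] for c in clusters] == truth


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        res = ld.permutation_mean_diff_test([1, 2, 3], [1, 2, 3], iterations=1000, seed=0)
        assert res.p_value == 1.0

    def test_matches_exact_enumeration(self):
        """MC estimate agrees with exhaustive split enumeration on tiny groups."""
        a, b = [0.0, 0.0], [10.0, 10.0]
        pool = a + b
        obs = abs(np.mean(a) - np.mean(b))
        count = total = 0
        for idx in itertools.combinations(range(4), 2):
            sa = [pool[i] for i in idx]
            sb = [pool[i] for i in range(4) if i not in idx]
            total += 1
            if abs(np.mean(sa) - np.mean(sb)) >= obs:
                count += 1
        exact = count / total
        assert exact == pytest.approx(2 / 6)
        res = ld.permutation_mean_diff_test(a, b, iterations=30000, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_exact_agreement_on_size_8_groups(self, rng):
        a = list(rng.uniform(0, 1, 4))
        b = list(rng.uniform(0.5, 1.5, 4))
        pool = a + b
        obs = abs(np.mean(a) - np.mean(b))
        hits = total = 0
        for idx in itertools.combinations(range(8), 4):
            sa = [pool[i] for i in idx]
            sb = [pool[i] for i in range(8) if i not in idx]
            total += 1
            if abs(np.mean(sa) - np.mean(sb)) >= obs - 1e-12:
                hits += 1
        exact = hits / total
        res = ld.permutation_mean_diff_test(a, b, iterations=50000, seed=2)
        assert res.p_value == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / 50000) + 1e-6)

    def test_symmetric_in_groups(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 7.0]
        r1 = ld.permutation_mean_diff_test(a, b, iterations=20000, seed=3)
        r2 = ld.permutation_mean_diff_test(b, a, iterations=20000, seed=3)
        assert r1.p_value == pytest.approx(r2.p_value, abs=0.02)

    def test_smoothed_variant_never_zero(self):
        res = ld.permutation_mean_diff_test([0.0] * 5, [100.0] * 5, iterations=100, seed=0, smoothed=True)
        assert 0 < res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ld.permutation_mean_diff_test([], [1.0])


class TestEnrichment:
    def _assignment(self, labels_by_cluster):
        assignment = {}
        for c, members in labels_by_cluster.items():
            for m in members:
                assignment[m] = c
        return ld.ClusterAssignment(assignment=assignment, k=len(labels_by_cluster), cut_height=1.0)

    def test_concentrated_class_is_most_significant(self):
        # cluster 1 holds the entire 8-member class in a 20-embryo cohort
        assign = self._assignment({1: [f"a{i}" for i in range(10)], 2: [f"b{i}" for i in range(10)]})
        labels = {f"a{i}": ("tf" if i < 8 else "other") for i in range(10)}
        labels.update({f"b{i}": "other" for i in range(10)})
        results = ld.cluster_enrichment(assign, labels, alpha=0.05)
        tf_in_1 = next(r for r in results if r.cluster == 1 and r.label_class == "tf")
        assert tf_in_1.p_value < 0.05
        assert tf_in_1.p_value == min(r.p_value for r in results)

    def test_pro_rata_split_not_significant(self):
        assign = self._assignment({1: [f"a{i}" for i in range(6)], 2: [f"b{i}" for i in range(6)]})
        labels = {f"a{i}": ("tf" if i < 3 else "other") for i in range(6)}
        labels.update({f"b{i}": ("tf" if i < 3 else "other") for i in range(6)})
        for r in ld.cluster_enrichment(assign, labels):
            assert not r.significant

    def test_bonferroni_threshold_is_alpha_over_ntests(self):
        assign = self._assignment({1: [f"a{i}" for i in range(10)], 2: [f"b{i}" for i in range(10)]})
        labels = {f"a{i}": ("tf" if i < 9 else "kinase") for i in range(10)}
        labels.update({f"b{i}": ("kinase" if i < 9 else "tf") for i in range(10)})
        results = ld.cluster_enrichment(assign, labels, alpha=0.05)
        n_tests = len(results)
        for r in results:
            assert r.significant == (r.p_value < 0.05 / n_tests)
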