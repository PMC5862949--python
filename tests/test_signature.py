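import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

from mirsig import diffexp, signature, simulate
from mirsig.io import GeneSetCollection
from mirsig.signature import (candidate_targets, divergent_genes,
                              hierarchical_cluster, signature_genes)
from tests.conftest import make_contrast, make_matrix


class TestDivergentGenes:
    def test_constant_gene_never_selected(self):
        m = make_matrix(np.full((1, 6), 7.0), ["a"] * 3 + ["b"] * 3)
        assert divergent_genes(m, ["a", "b"]) == []

    def test_threshold_is_inclusive_at_boundary(self):
        # one experiment deviates by exactly log2(1.5) from the median
        dev = np.log2(1.5)
        row = np.array([dev, dev, dev, 0.0, 0.0, 0.0, 0.0])
        m = make_matrix(row[None, :], ["a"] * 3 + ["b"] * 4)
        assert divergent_genes(m, ["a", "b"], 1.5, 1) == ["g0"]

    def test_matches_exhaustive_rule_evaluation(self, rng):
        values = rng.normal(8, 1, size=(40, 9))
        conds = ["e1"] * 3 + ["e2"] * 3 + ["e3"] * 3
        m = make_matrix(values, conds)
        got = divergent_genes(m, ["e1", "e2", "e3"], 1.5, 2)
        # brute force over every gene and experiment
        cut = np.log2(1.5)
        expected = []
        for i, g in enumerate(m.gene_ids):
            med = np.median(values[i])
            n = sum(abs(values[i, [j for j, c in enumerate(conds) if c == e]]
                        .mean() - med) >= cut for e in ("e1", "e2", "e3"))
            if n >= 2:
                expected.append(g)
        assert got == expected

    def test_invariant_to_gene_and_sample_order(self, rng):
        values = rng.normal(8, 1.5, size=(30, 6))
        conds = ["a"] * 3 + ["b"] * 3
        m = make_matrix(values, conds)
        perm_g = rng.permutation(30)
        perm_s = np.array([3, 0, 4, 1, 5, 2])
        m2 = make_matrix(values[np.ix_(perm_g, perm_s)],
                         [conds[j] for j in perm_s],
                         gene_ids=[m.gene_ids[i] for i in perm_g],
                         sample_ids=[m.sample_ids[j] for j in perm_s])
        assert (set(divergent_genes(m, ["a", "b"], 1.4, 1))
                == set(divergent_genes(m2, ["a", "b"], 1.4, 1)))


class TestSignatureGenes:
    def _contrasts(self, fc_rows):
        fc = np.asarray(fc_rows, dtype=float)
        genes = [f"g{i}" for i in range(fc.shape[0])]
        return [make_contrast(genes, fc=fc[:, j], name=f"e{j}")
                for j in range(fc.shape[1])]

    def test_three_passes_selected(self):
        sig = signature_genes(self._contrasts([[0.5, 0.5, 0.5, 0.0]]),
                              fold_threshold=1.3, min_experiments=3)
        assert sig.genes == ["g0"]
        assert sig.table.loc["g0", "n_pass"] == 3

    def test_sign_inconsistency_rejected(self):
        sig = signature_genes(self._contrasts([[0.5, 0.5, -0.5, 0.0]]),
                              fold_threshold=1.3, min_experiments=3)
        assert sig.genes == []
        relaxed = signature_genes(self._contrasts([[0.5, 0.5, -0.5, 0.0]]),
                                  fold_threshold=1.3, min_experiments=3,
                                  sign_consistent=False)
        assert relaxed.genes == ["g0"]

    def test_orientation_flips_knockdown_contrast(self):
        # gene is down in the kd contrast; orientation -1 makes it coherent
        fc = [[0.5, 0.5, -0.5]]
        contrasts = self._contrasts(fc)
        sig = signature_genes(contrasts, orientations=[1, 1, -1],
                              fold_threshold=1.3, min_experiments=3)
        assert sig.genes == ["g0"]
        assert (sig.table.loc["g0", ["e0", "e1", "e2"]] == 0.5).all()

    def test_planted_recovery(self):
        """Mean recall and precision over seeded runs for genes planted in
        all four experiments (delta=1, noise 0.5, 100 of 250 genes)."""
        genes = simulate.default_gene_ids(250)
        coll = GeneSetCollection("SIG", {"SIG": genes[:100]})
        recalls, precisions = [], []
        for k in range(20):
            contrasts = []
            for e in range(4):
                design = simulate.ExperimentDesign(
                    conditions={"t": "high", "r": "low"}, n_genes=250,
                    collection=coll, planted={"t": [(["SIG"], 1.0)]},
                    noise_sd=0.5, seed=9000 + 10 * k + e)
                m, _ = simulate.generate_experiment(design)
                contrasts.append(diffexp.contrast(m, "t", "r", name=f"e{e}"))
            sig = signature_genes(contrasts, fold_threshold=1.3,
                                  min_experiments=3)
            hit = set(sig.genes) & set(genes[:100])
            recalls.append(len(hit) / 100)
            precisions.append(len(hit) / max(len(sig.genes), 1))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.9

    def test_rerun_is_identical(self, rng):
        contrasts = self._contrasts(rng.normal(scale=0.6, size=(30, 4)))
        a = signature_genes(contrasts)
        b = signature_genes(contrasts)
        assert a.genes == b.genes
        assert a.table.equals(b.table)


def brute_force_average_linkage(dist):
    """Exhaustive UPGMA: merge the closest pair; inter-cluster distance is
    the mean pairwise distance between original members."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a < b:
                    d = np.mean([dist[i, j] for i in clusters[a]
                                 for j in clusters[b]])
                    if best is None or d < best[0]:
                        best = (d, a, b)
        d, a, b = best
        merges.append((d, frozenset(clusters[a] + clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHierarchicalCluster:
    def test_duplicate_samples_merge_first_at_zero_distance(self, rng):
        values = rng.normal(size=(10, 4))
        values[:, 3] = values[:, 0]  # s3 duplicates s0
        m = make_matrix(values, ["a", "a", "b", "b"])
        res = hierarchical_cluster(m, m.gene_ids)
        first = res.sample_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 3}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_exhaustive_agglomeration(self, rng):
        """Merge structure matches an O(n^3) brute-force UPGMA on 8 genes."""
        values = rng.normal(size=(8, 12))
        m = make_matrix(values, ["a"] * 6 + ["b"] * 6)
        res = hierarchical_cluster(m, m.gene_ids)
        centered = values - np.median(values, axis=1, keepdims=True)
        corr = np.corrcoef(centered)
        merges = brute_force_average_linkage(1 - corr)
        got_heights = sorted(res.gene_linkage[:, 2])
        exp_heights = sorted(d for d, _ in merges)
        np.testing.assert_allclose(got_heights, exp_heights, atol=1e-10)
        # membership of every merged cluster agrees
        def scipy_merge_sets(link, n):
            members = {i: frozenset([i]) for i in range(n)}
            out = []
            for k, (a, b, d, _) in enumerate(link):
                members[n + k] = members[int(a)] | members[int(b)]
                out.append((d, members[n + k]))
            return out
        got = {s for _, s in scipy_merge_sets(res.gene_linkage, 8)}
        exp = {s for _, s in merges}
        assert got == exp

    def test_planted_two_group_partition_recovered(self, rng):
        """Two anti-correlated sample groups (3 vs 4) are exactly split by
        the k=2 cut of the sample dendrogram."""
        pattern = rng.normal(size=60)
        cols = [pattern + rng.normal(scale=0.3, size=60) for _ in range(3)]
        cols += [-pattern + rng.normal(scale=0.3, size=60) for _ in range(4)]
        m = make_matrix(np.column_stack(cols), ["low"] * 3 + ["high"] * 4)
        res = hierarchical_cluster(m, m.gene_ids)
        part = res.sample_partition
        groups = {part[s] for s in m.sample_ids[:3]}, \
                 {part[s] for s in m.sample_ids[3:]}
        assert len(groups[0]) == 1 and len(groups[1]) == 1
        assert groups[0] != groups[1]

    def test_zero_variance_gene_dropped(self, rng):
        values = rng.normal(size=(5, 6))
        values[2] = 3.0
        m = make_matrix(values, ["a"] * 3 + ["b"] * 3)
        res = hierarchical_cluster(m, m.gene_ids)
        assert res.dropped_genes == ["g2"]
        assert len(res.gene_order) == 4


class TestCandidateTargets:
    def _contrast(self, genes, fc, p):
        return make_contrast(genes, fc=fc, p=p)

    def test_direction_and_membership_rule(self):
        genes = ["a", "b", "c", "d"]
        kd = self._contrast(genes, [-1, -1, -1, 1], [0.01] * 4)
        ind = self._contrast(genes, [1, -1, 1, 1], [0.01] * 4)
        sets = GeneSetCollection("MIR", {"S": ["a", "d"]})
        # a: down-in-kd, up-induced, member -> kept; b down both; c not member
        assert candidate_targets(kd, ind, sets) == ["a"]

    def test_matches_exhaustive_filter(self, rng):
        genes = [f"g{i}" for i in range(20)]
        fc_kd = rng.normal(size=20)
        fc_in = rng.normal(size=20)
        p_kd = rng.random(20) * 0.1
        p_in = rng.random(20) * 0.1
        members = set(rng.choice(genes, size=8, replace=False))
        kd = self._contrast(genes, fc_kd, p_kd)
        ind = self._contrast(genes, fc_in, p_in)
        sets = GeneSetCollection("MIR", {"S": sorted(members)})
        expected = [g for i, g in enumerate(genes)
                    if p_kd[i] < 0.05 and fc_kd[i] < 0
                    and p_in[i] < 0.05 and fc_in[i] > 0
                    and g.upper() in {x.upper() for x in members}]
        assert candidate_targets(kd, ind, sets) == expected

    def test_empty_mir_selection_is_error(self):
        kd = self._contrast(["a"], [-1], [0.01])
        ind = self._contrast(["a"], [1], [0.01])
        with pytest.raises(ValueError, match="empty"):
            candidate_targets(kd, ind, {})
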