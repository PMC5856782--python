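"""Allele-sharing distances, NJ exactness on additive matrices, genotype PCA
properties, and the separation permutation test."""

import numpy as np
import pytest

from altipop.structure import (
    DistanceMatrix,
    TreeNode,
    allele_sharing_distance,
    distance_matrix,
    genotype_pca,
    neighbor_joining,
    permutation_test_separation,
)
from altipop.variants import MISSING, VariantTable


def _table(dosages, samples):
    n = dosages.shape[0]
    return VariantTable(
        ["T1"] * n, list(range(1, n + 1)), ["A"] * n, ["G"] * n,
        dosages.astype(np.int8), samples,
    )


class TestAlleleSharing:
    def test_identical_vectors(self):
        t = _table(np.array([[1, 1], [2, 2], [0, 0]]), ["a", "b"])
        assert allele_sharing_distance(t, "a", "b") == 0.0

    def test_opposite_homozygotes_maximal(self):
        t = _table(np.array([[0, 2], [2, 0]]), ["a", "b"])
        assert allele_sharing_distance(t, "a", "b") == 1.0

    def test_half_for_het_vs_hom(self):
        t = _table(np.array([[0, 1]]), ["a", "b"])
        assert allele_sharing_distance(t, "a", "b") == 0.5

    def test_no_overlap_rejected(self):
        t = _table(np.array([[MISSING, 1], [0, MISSING]]), ["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            allele_sharing_distance(t, "a", "b")


# ---------------------------------------------------------------------------
# random additive matrices from random trees (test-side oracle)


def random_tree_distances(rng, n_taxa):
    """Build a random binary tree, return (leaf labels, path-length matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a star over 3 leaves, attach remaining leaves to random edges
    # simpler: random coalescent-style join order with random positive lengths
    nodes = {i: [i] for i in range(n_taxa)}  # node -> leaf indices
    dist = np.zeros((n_taxa, n_taxa))
    height = {i: np.zeros(1) for i in range(n_taxa)}
    pending = dict(nodes)
    depth = {i: {i: 0.0} for i in range(n_taxa)}  # node -> leaf -> distance
    keys = list(pending)
    while len(keys) > 1:
        i, j = sorted(rng.choice(len(keys), 2, replace=False))
        a, b = keys[i], keys[j]
        la = float(rng.uniform(0.1, 1.0))
        lb = float(rng.uniform(0.1, 1.0))
        for u, du in depth[a].items():
            for v, dv in depth[b].items():
                dist[u, v] = dist[v, u] = du + la + dv + lb
        merged = {u: du + la for u, du in depth[a].items()}
        merged.update({v: dv + lb for v, dv in depth[b].items()})
        new_key = max(keys) + 1
        depth[new_key] = merged
        keys = [k for k in keys if k not in (a, b)] + [new_key]
    return labels, dist


def tree_patristic(tree: TreeNode):
    """Leaf-to-leaf path lengths of a TreeNode."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            dists[node.label] = acc
            return
        for child, length in node.children:
            walk(child, acc + length)

    # distances via lowest common ancestor: accumulate leaf depths per subtree
    leaves = sorted(tree.leaves())
    n = len(leaves)
    index = {l: i for i, l in enumerate(leaves)}
    out = np.zeros((n, n))

    def collect(node):
        if node.is_leaf:
            return {node.label: 0.0}
        sub = []
        for child, length in node.children:
            d = collect(child)
            sub.append({k: v + length for k, v in d.items()})
        for x in range(len(sub)):
            for y in range(x + 1, len(sub)):
                for u, du in sub[x].items():
                    for v, dv in sub[y].items():
                        out[index[u], index[v]] = out[index[v], index[u]] = du + dv
        merged = {}
        for d in sub:
            merged.update(d)
        return merged

    collect(tree)
    return leaves, out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree, _ = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        leaves, pat = tree_patristic(tree)
        np.testing.assert_allclose(pat, d, atol=1e-12)
        # branch of A = (d_AB + d_AC - d_BC)/2 = 0.1
        edge = {c.label: l for c, l in tree.children if c.is_leaf}
        assert edge.get("A", 0.1) == pytest.approx(0.1)

    def test_exact_recovery_on_additive_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 9))
            labels, d = random_tree_distances(rng, n)
            tree, _ = neighbor_joining(DistanceMatrix(labels, d))
            leaves, pat = tree_patristic(tree)
            order = [leaves.index(l) for l in labels]
            np.testing.assert_allclose(pat[np.ix_(order, order)], d, atol=1e-9)

    def test_matches_scikit_bio_topology(self, rng):
        import skbio

        labels, d = random_tree_distances(rng, 7)
        tree, _ = neighbor_joining(DistanceMatrix(labels, d))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        sk_clades = set()
        for node in sk_tree.traverse():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < len(labels):
                sk_clades.add(tips)
        my_clades = {c for c in tree.clades() if 1 < len(c) < len(labels)}
        all_taxa = frozenset(labels)
        # unrooted comparison: a split equals a clade or its complement
        for clade in my_clades:
            assert clade in sk_clades or (all_taxa - clade) in sk_clades

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], d)

    def test_populations_form_clades(self, default_dataset):
        tree, _ = neighbor_joining(distance_matrix(default_dataset["table"]))
        clades = set(tree.clades())
        design = default_dataset["design"]
        all_samples = frozenset(design.assignment)
        for lab in design.labels:
            pop = frozenset(design.samples_for(lab))
            assert pop in clades or (all_samples - pop) in clades


class TestPca:
    def test_duplicated_samples_identical_scores(self, default_dataset):
        t = default_dataset["table"]
        g = np.column_stack([t.genotypes, t.genotypes[:, 0]])
        dup = VariantTable(t.transcript_id, t.pos, t.ref, t.alt, g, t.samples + ["dup"])
        res = genotype_pca(dup)
        np.testing.assert_allclose(res.scores[0], res.scores[-1], atol=1e-8)

    def test_variance_fractions_sum_to_one(self, default_dataset):
        res = genotype_pca(default_dataset["table"])
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(res.variance_fractions >= 0)

    def test_scores_centered(self, default_dataset):
        res = genotype_pca(default_dataset["table"])
        np.testing.assert_allclose(res.scores.mean(axis=0)[:3], 0.0, atol=1e-8)

    def test_order_invariance_up_to_sign(self, default_dataset):
        t = default_dataset["table"]
        perm = np.array([3, 1, 8, 0, 5, 2, 7, 4, 6])
        shuffled = VariantTable(
            t.transcript_id, t.pos, t.ref, t.alt,
            t.genotypes[:, perm], [t.samples[i] for i in perm],
        )
        r1 = genotype_pca(t)
        r2 = genotype_pca(shuffled)
        s1 = {s: r1.scores[i, 0] for i, s in enumerate(r1.samples)}
        s2 = {s: r2.scores[i, 0] for i, s in enumerate(r2.samples)}
        ratio = np.array([s2[s] / s1[s] for s in s1 if abs(s1[s]) > 1e-9])
        np.testing.assert_allclose(np.abs(ratio), 1.0, atol=1e-6)

    def test_pc1_separates_high_population(self, default_dataset):
        res = genotype_pca(default_dataset["table"])
        design = default_dataset["design"]
        pc1 = dict(zip(res.samples, res.scores[:, 0]))
        h = [pc1[s] for s in design.samples_for("H")]
        rest = [pc1[s] for s in design.samples_for("L") + design.samples_for("M")]
        assert min(h) > max(rest) or max(h) < min(rest)

    def test_monomorphic_only_rejected(self):
        t = _table(np.zeros((5, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError):
            genotype_pca(t)


class TestPermutationTest:
    def _separated_scores(self):
        pts = np.array([[10.0, 0], [10.5, 0.2], [10.2, -0.1],
                        [-5.0, 1.0], [-5.2, 0.8], [-4.9, 1.1],
                        [-5.1, -0.9], [-5.3, -1.2], [-4.8, -1.0]])
        labels = ["H"] * 3 + ["L"] * 3 + ["M"] * 3
        return pts, labels

    def test_minimal_attainable_p(self):
        pts, labels = self._separated_scores()
        grouping = {"H": "high", "L": "low", "M": "low"}
        _, p = permutation_test_separation(pts, labels, grouping, n_perm=999, seed=1)
        # 9 choose 3 = 84 distinct assignments; with 999 random permutations
        # the observed maximum recurs by chance, so p is small but > 1/1000
        assert p <= 0.05

    def test_determinism(self):
        pts, labels = self._separated_scores()
        grouping = {"H": "high", "L": "low", "M": "low"}
        r1 = permutation_test_separation(pts, labels, grouping, n_perm=199, seed=9)
        r2 = permutation_test_separation(pts, labels, grouping, n_perm=199, seed=9)
        assert r1 == r2

    def test_plus_one_lower_bound(self, rng):
        pts = rng.normal(size=(9, 2))
        labels = ["H"] * 3 + ["L"] * 3 + ["M"] * 3
        grouping = {"H": "a", "L": "b", "M": "b"}
        _, p = permutation_test_separation(pts, labels, grouping, n_perm=99, seed=3)
        assert p >= 1 / 100

    def test_null_p_values_roughly_uniform(self, rng):
        """Random labels: small p-values occur at their nominal rate."""
        hits = 0
        reps = 60
        for k in range(reps):
            pts = rng.normal(size=(9, 2))
            labels = ["H"] * 3 + ["L"] * 3 + ["M"] * 3
            grouping = {"H": "a", "L": "b", "M": "b"}
            _, p = permutation_test_separation(pts, labels, grouping, n_perm=99, seed=k)
            hits += p < 0.1
        # binomial(60, ~0.1): allow up to 13 hits (> 4 sigma)
        assert hits <= 13

    def test_min_permutations_enforced(self):
        pts, labels = self._separated_scores()
        with pytest.raises(ValueError):
            permutation_test_separation(pts, labels, {"H": "a", "L": "b", "M": "b"}, n_perm=10)
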