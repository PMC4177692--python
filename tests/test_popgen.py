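import numpy as np
import pandas as pd
import pytest

from landgen.popgen import (
    GenotypeMatrix,
    assign_clusters,
    fst_weir_cockerham,
    genotype_pca,
    nj_tree,
    nj_with_bootstrap,
    p_distance,
    pairwise_fst,
    select_k,
    vanraden_kinship,
)
from conftest import make_genotypes


class TestWeirCockerham:
    def test_hand_computed_fixture(self):
        # pop1 dosages (2,2,2,0), pop2 (0,0,0,0): components enumerated by
        # hand give a=0.25, b=0.125, c=0 -> theta = 0.25/0.375 = 2/3
        c1 = np.array([[2], [2], [2], [0]], dtype=np.int8)
        c2 = np.array([[0], [0], [0], [0]], dtype=np.int8)
        assert fst_weir_cockerham(c1, c2) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_fixed_opposite_alleles(self):
        c1 = np.full((5, 10), 2, dtype=np.int8)
        c2 = np.zeros((5, 10), dtype=np.int8)
        assert fst_weir_cockerham(c1, c2) == pytest.approx(1.0)

    def test_duplicated_samples_no_differentiation(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 3, size=(8, 50)).astype(np.int8)
        theta = fst_weir_cockerham(c, c.copy())
        assert theta <= 0 + 1e-12

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        c1 = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        c2 = rng.integers(0, 3, size=(7, 40)).astype(np.int8)
        t1 = fst_weir_cockerham(c1, c2)
        t2 = fst_weir_cockerham(c1[::-1], c2[::-1])
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        c1 = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        c2 = rng.integers(0, 3, size=(7, 40)).astype(np.int8)
        t1 = fst_weir_cockerham(c1, c2)
        t2 = fst_weir_cockerham(2 - c1, 2 - c2)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_pairwise_matrix(self):
        codes = np.vstack(
            [np.full((4, 5), 2), np.zeros((4, 5)), np.full((4, 5), 2)]
        ).astype(np.int8)
        g = make_genotypes(codes, groups=["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4)
        fst = pairwise_fst(g)
        assert fst.loc["p1", "p2"] == pytest.approx(1.0)
        assert np.isnan(fst.loc["p1", "p3"])  # both monomorphic, undefined

    def test_recovers_generator_fst(self, small_bundle):
        # between-clade theta on neutral loci tracks the configured value
        b = small_bundle
        neutral = ~np.isin(
            np.arange(b.genotypes.n_loci),
            np.concatenate(
                [b.eas_truth["locus"].to_numpy(),
                 b.outlier_truth["locus"].to_numpy()]
            ),
        )
        g = b.genotypes.subset_loci(neutral)
        lab = g.groups.reindex(g.samples).to_numpy()
        clade = np.array([(int(x[1:]) - 1) % 2 for x in lab])
        theta = fst_weir_cockerham(g.codes[clade == 0], g.codes[clade == 1])
        assert abs(theta - b.config.fst_between_clades) < 0.08


class TestVanRaden:
    def test_hand_example(self):
        g = make_genotypes(np.array([[0], [2]]))
        kin = vanraden_kinship(g)
        np.testing.assert_allclose(
            kin.matrix, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12
        )

    def test_duplicated_individuals(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 3, size=60).astype(np.int8)
        codes = np.vstack([row, row, rng.integers(0, 3, size=60)])
        kin = vanraden_kinship(make_genotypes(codes))
        assert kin.matrix[0, 1] == pytest.approx(kin.matrix[0, 0])
        np.testing.assert_allclose(kin.matrix[0], kin.matrix[1])

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(12, 80)).astype(np.int8)
        kin = vanraden_kinship(make_genotypes(codes))
        assert np.linalg.eigvalsh(kin.matrix).min() >= -1e-8

    def test_all_monomorphic_error(self):
        g = make_genotypes(np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_kinship(g)


class TestPDistance:
    def test_identical_samples(self):
        codes = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (2, 1))
        d = p_distance(make_genotypes(codes))
        assert d.iloc[0, 1] == 0.0

    def test_all_differing(self):
        codes = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        d = p_distance(make_genotypes(codes))
        assert d.iloc[0, 1] == 1.0

    def test_missing_excluded(self):
        codes = np.array([[0, 1, 2, 0], [0, 1, 0, -1]], dtype=np.int8)
        d = p_distance(make_genotypes(codes))
        assert d.iloc[0, 1] == pytest.approx(1.0 / 3.0)

    def test_no_shared_loci(self):
        codes = np.array([[0, -1], [-1, 2]], dtype=np.int8)
        d = p_distance(make_genotypes(codes))
        assert np.isnan(d.iloc[0, 1])


def random_additive_matrix(rng, n_taxa):
    """Additive-matrix oracle: build a random tree by sequential leaf
    attachment on an explicit edge list, then read off path distances."""
    next_id = [n_taxa]

    def new_node():
        next_id[0] += 1
        return next_id[0]

    root = new_node()
    tree = {root: []}
    parents = {}
    lengths = {}

    def attach(parent, child, length):
        tree.setdefault(parent, []).append(child)
        tree.setdefault(child, [])
        parents[child] = parent
        lengths[child] = length

    attach(root, 0, rng.uniform(0.1, 2))
    attach(root, 1, rng.uniform(0.1, 2))
    attach(root, 2, rng.uniform(0.1, 2))
    edge_list = [0, 1, 2]
    for leaf in range(3, n_taxa):
        target = edge_list[rng.integers(len(edge_list))]
        # split the edge above `target`
        mid = new_node()
        parent = parents[target]
        tree[parent].remove(target)
        old_len = lengths[target]
        cut = rng.uniform(0.2, 0.8) * old_len
        attach(parent, mid, old_len - cut)
        tree[mid].append(target)
        parents[target] = mid
        lengths[target] = cut
        attach(mid, leaf, rng.uniform(0.1, 2))
        edge_list.extend([leaf, mid])

    # cophenetic distances by walking to root
    def path_to_root(x):
        out = {}
        d = 0.0
        while x in parents:
            d += lengths[x]
            x = parents[x]
            out[x] = d
        return out

    n = n_taxa
    dist = np.zeros((n, n))
    paths = [path_to_root(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            d = min(paths[i][a] + paths[j][a] for a in shared)
            dist[i, j] = dist[j, i] = d
    labels = [f"t{i}" for i in range(n)]
    return pd.DataFrame(dist, index=labels, columns=labels)


class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = nj_tree(d)
        got = tree.cophenetic(list("abc"))
        np.testing.assert_allclose(got, d.to_numpy(), atol=1e-9)
        # closed-form terminal branches v_a = (dab + dac - dbc)/2 = 2
        lengths = {}

        def rec(node):
            for ch in node.children:
                if ch.is_leaf():
                    lengths[ch.name] = ch.length
                rec(ch)

        rec(tree)
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(7.0)

    def test_four_taxon_additive_recovery(self):
        d = random_additive_matrix(np.random.default_rng(0), 4)
        tree = nj_tree(d)
        got = tree.cophenetic(list(d.index))
        np.testing.assert_allclose(got, d.to_numpy(), atol=1e-9)

    def test_additive_property_50_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            d = random_additive_matrix(rng, n)
            tree = nj_tree(d)
            got = tree.cophenetic(list(d.index))
            np.testing.assert_allclose(got, d.to_numpy(), atol=1e-8)

    def test_identical_taxa_zero_sister_pair(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(4, 120)).astype(np.int8)
        codes[1] = codes[0]
        g = make_genotypes(codes)
        d = p_distance(g)
        tree, supports = nj_with_bootstrap(
            d,
            column_matrix=g.codes,
            dist_fn=lambda m: p_distance(make_genotypes(m)),
            n_reps=30,
            seed=0,
        )
        # the duplicated pair forms a zero-length sister split at full
        # support (the split may be recorded from either side)
        found = None
        for s, sup in supports.items():
            if s in (frozenset({"s0", "s1"}), frozenset({"s2", "s3"})):
                found = sup
        assert found is not None and found == pytest.approx(1.0)
        assert d.loc["s0", "s1"] == 0.0

    def test_missing_distance_error(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        d.iloc[0, 1] = d.iloc[1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            nj_tree(d)

    def test_too_few_taxa(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(d)


class TestGenotypePCA:
    def test_two_clades_separate(self, small_bundle):
        from sklearn.metrics import silhouette_score

        g = small_bundle.genotypes
        scores = genotype_pca(g, n_pcs=2)
        lab = g.groups.reindex(g.samples).to_numpy()
        clade = np.array([(int(x[1:]) - 1) % 2 for x in lab])
        pc1 = scores.iloc[:, 0].to_numpy().reshape(-1, 1)
        assert silhouette_score(pc1, clade) > 0.8

    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(8, 100)).astype(np.int8)
        codes[1] = codes[0]
        scores = genotype_pca(make_genotypes(codes), n_pcs=3)
        np.testing.assert_allclose(
            scores.iloc[0].to_numpy(), scores.iloc[1].to_numpy(), atol=1e-8
        )

    def test_matches_eigensolver_oracle(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(10, 60)).astype(np.int8)
        g = make_genotypes(codes)
        scores = genotype_pca(g, n_pcs=3)
        d = codes.astype(float)
        d -= d.mean(axis=0)
        gram = d @ d.T
        evals, evecs = np.linalg.eigh(gram)
        for comp in range(3):
            v = evecs[:, -1 - comp] * np.sqrt(evals[-1 - comp])
            got = scores.iloc[:, comp].to_numpy()
            err = min(np.abs(got - v).max(), np.abs(got + v).max())
            assert err < 1e-8

    def test_n_pcs_bound(self):
        g = make_genotypes(np.zeros((4, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            genotype_pca(g, n_pcs=4)


class TestClusters:
    def test_two_clades_ari(self, small_bundle):
        from sklearn.metrics import adjusted_rand_score

        g = small_bundle.genotypes
        scores = genotype_pca(g, n_pcs=2)
        labels = assign_clusters(scores, k=2, seed=0)
        lab = g.groups.reindex(g.samples).to_numpy()
        clade = np.array([(int(x[1:]) - 1) % 2 for x in lab])
        assert adjusted_rand_score(clade, labels.to_numpy()) == 1.0

    def test_k1(self):
        scores = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        labels = assign_clusters(scores, k=1)
        assert (labels == 0).all()

    def test_k_too_large(self):
        scores = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            assign_clusters(scores, k=5)

    def test_silhouette_selects_k5(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(20):
            centers = rng.normal(scale=12, size=(5, 3))
            pts = np.vstack(
                [c + rng.normal(size=(12, 3)) for c in centers]
            )
            scores = pd.DataFrame(pts)
            best, _ = select_k(scores, range(2, 9), seed=rep)
            hits += best == 5
        assert hits >= 16
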