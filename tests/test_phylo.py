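import numpy as np
import pytest

from mitolineage import DistanceMatrix, bootstrap_supports, hamming_distances, nj_tree
from mitolineage.phylo import TreeNode, split_support

from conftest import haplotypes_of


def random_additive_tree(seed, n_leaves):
    """Random binary tree with positive branch lengths and its leaf distances."""
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(0.5, 3.0))
    pool = nodes[:]
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = TreeNode(children=[pool[i], pool[j]], length=float(rng.uniform(0.5, 3.0)))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    root = TreeNode(children=pool)
    labels = [f"L{i}" for i in range(n_leaves)]
    # leaf-to-leaf path distances
    def paths(node, acc):
        if node.is_leaf():
            return {node.name: acc + node.length}
        out = {}
        for c in node.children:
            out.update(paths(c, acc + (node.length if node is not root else 0.0)))
        return out
    # distance via shared-path subtraction: compute per-leaf distance from root
    def leaf_dists(node):
        if node.is_leaf():
            return {node.name: node.length}
        out = {}
        for c in node.children:
            for k, v in leaf_dists(c).items():
                out[k] = v + (node.length if node is not root else 0.0)
        return out
    # build full matrix by recursive merge
    def collect(node):
        """Return (dists_to_leaves_below, pair_distances)."""
        if node.is_leaf():
            return {node.name: 0.0}, {}
        below = []
        pairs = {}
        for c in node.children:
            d, p = collect(c)
            d = {k: v + c.length for k, v in d.items()}
            below.append(d)
            pairs.update(p)
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for la, va in below[a].items():
                    for lb, vb in below[b].items():
                        pairs[frozenset((la, lb))] = va + vb
        merged = {k: v for d in below for k, v in d.items()}
        return merged, pairs
    _, pairs = collect(root)
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            D[i, j] = D[j, i] = pairs[frozenset((f"L{i}", f"L{j}"))]
    true_splits = PhyloSplits(root, labels)
    return DistanceMatrix(labels, D), true_splits


def PhyloSplits(root, labels):
    from mitolineage.phylo import PhyloTree
    return PhyloTree(root=root, labels=labels).bipartitions()


class TestHammingDistances:
    def test_basic_counts(self):
        h = haplotypes_of(["AAA", "AAT"], [1, 1])
        dm = hamming_distances(h)
        assert dm.d[0, 1] == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(10)]
        h = haplotypes_of(seqs, [1] * len(set(seqs)))
        dm = hamming_distances(h)
        for i in range(h.n_haplotypes):
            for j in range(h.n_haplotypes):
                expect = sum(a != b for a, b in
                             zip(h.haplotype_seqs[i], h.haplotype_seqs[j]))
                assert dm.d[i, j] == expect

    def test_per_site_mode(self):
        h = haplotypes_of(["AAAA", "AATT"], [1, 1])
        assert hamming_distances(h, per_site=True).d[0, 1] == pytest.approx(0.5)


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(dm)
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_four_taxon_additive_recovery(self):
        # tree ((A,B),(C,D)) with internal edge 2
        # A,B at 1 from left node; C,D at 1 from right node
        D = np.array([[0, 2, 4, 4],
                      [2, 0, 4, 4],
                      [4, 4, 0, 2],
                      [4, 4, 2, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), D))
        assert tree.bipartitions() == {frozenset("AB")}
        # recovered branch lengths reproduce the additive matrix
        assert _tree_distance(tree, "A", "C") == pytest.approx(4)
        assert _tree_distance(tree, "A", "B") == pytest.approx(2)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n_leaves):
        for seed in range(5):
            dm, true_splits = random_additive_tree(seed * 31 + n_leaves, n_leaves)
            tree = nj_tree(dm)
            assert tree.bipartitions() == true_splits
            for i, a in enumerate(dm.labels):
                for b in dm.labels[i + 1:]:
                    assert _tree_distance(tree, a, b) == pytest.approx(dm.d[dm.labels.index(a), dm.labels.index(b)])

    def test_agrees_with_skbio_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 7
            pts = rng.random((n, 6))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            labels = [f"x{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(labels, D)).bipartitions()
            sk_tree = sk_nj(SkDM(D, labels))
            theirs = set()
            for node in sk_tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                other = frozenset(labels) - side
                if 1 < len(side) < n - 1:
                    theirs.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            assert mine == theirs

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_outgroup_rooting(self):
        dm, _ = random_additive_tree(1, 6)
        tree = nj_tree(dm, outgroup="L0")
        assert len(tree.root.children) == 2
        names = [c.name for c in tree.root.children if c.is_leaf()]
        assert names == ["L0"]
        nwk = tree.newick()
        assert nwk.count("L0") == 1 and nwk.endswith(";")


def _tree_distance(tree, a, b):
    # path distance between two leaves via root paths
    def path_to(node, name, acc):
        if node.is_leaf():
            return acc + [node] if node.name == name else None
        for c in node.children:
            r = path_to(c, name, acc + [node])
            if r:
                return r
        return None
    pa = path_to(tree.root, a, [])
    pb = path_to(tree.root, b, [])
    shared = 0
    for x, y in zip(pa, pb):
        if x is y:
            shared += 1
        else:
            break
    return sum(n.length for n in pa[shared:]) + sum(n.length for n in pb[shared:])


class TestBootstrap:
    def test_fixed_split_gets_full_support(self):
        # two clades separated by 50 fixed differences
        rng = np.random.default_rng(0)
        L = 120
        base = rng.choice(list("ACGT"), size=L)
        seqs = []
        for i in range(4):  # clade 1: small private changes
            s = base.copy()
            s[i] = "A" if s[i] != "A" else "C"
            seqs.append("".join(s))
        other = base.copy()
        other[60:110] = np.where(other[60:110] == "A", "G", "A")
        for i in range(4):
            s = other.copy()
            s[10 + i] = "A" if s[10 + i] != "A" else "C"
            seqs.append("".join(s))
        h = haplotypes_of(seqs, [1] * 8)
        tree, supports = bootstrap_supports(h, n_reps=100, seed=3)
        groups = {}
        for lbl, members in h.members.items():
            groups.setdefault(int(members[0][1:]) <= 4, set()).add(lbl)
        sup = split_support(supports, groups[True], set(h.labels))
        assert sup == 100.0

    def test_no_variation_zero_supports(self):
        h = haplotypes_of(["AAAA", "AATA", "ATAA"], [1, 1, 1])
        # 3 haplotypes -> star; no internal bipartitions at all
        tree, supports = bootstrap_supports(h, n_reps=10, seed=0)
        assert supports == {}

    def test_same_seed_reproducible(self, yunling):
        from mitolineage import build_site_index, collapse_haplotypes
        aln, _ = yunling
        h = collapse_haplotypes(aln.subset(aln.sample_ids[:30]), build_site_index(aln))
        _, s1 = bootstrap_supports(h, n_reps=25, seed=7)
        _, s2 = bootstrap_supports(h, n_reps=25, seed=7)
        assert s1 == s2
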