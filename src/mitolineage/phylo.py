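"""Neighbor-joining trees over haplotypes, with column-bootstrap supports.

Distances default to raw pairwise differences (p-distance times usable
length, i.e. Hamming counts) with no substitution-model correction.
Bootstrap supports are the percentage of replicates (usable columns
resampled with replacement) whose NJ tree contains each internal
bipartition of the original tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SiteIndex
from .popgen import HaplotypeSet


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    units: str = "differences"

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def newick(self, with_supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_supports and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in self.children)
        label = f"{self.support:g}" if (with_supports and self.support is not None) else ""
        return f"({inner}){label};"


@dataclass
class PhyloTree:
    root: TreeNode
    labels: list[str]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the smaller/lexicographic side."""
        all_leaves = frozenset(self.labels)
        splits: set[frozenset[str]] = set()
        def walk(node: TreeNode):
            for c in node.children:
                if not c.is_leaf():
                    side = frozenset(lf.name for lf in c.leaves())
                    other = all_leaves - side
                    if 1 < len(side) < len(all_leaves) - 1:
                        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
                    walk(c)
        walk(self.root)
        return splits

    def annotate_supports(self, support_of: dict[frozenset[str], float]) -> None:
        all_leaves = frozenset(self.labels)
        def walk(node: TreeNode):
            for c in node.children:
                if not c.is_leaf():
                    side = frozenset(lf.name for lf in c.leaves())
                    key = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
                    if key in support_of:
                        c.support = support_of[key]
                    walk(c)
        walk(self.root)

    def newick(self, with_supports: bool = True) -> str:
        return self.root.newick(with_supports)


def hamming_distances(h: HaplotypeSet, idx: SiteIndex | None = None,
                      per_site: bool = False) -> DistanceMatrix:
    """Pairwise differing-site counts between haplotypes (optionally / L)."""
    mat = h.haplotype_seqs
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 haplotypes")
    d = np.zeros((mat.shape[0], mat.shape[0]))
    for i in range(mat.shape[0]):
        d[i] = (mat != mat[i]).sum(axis=1)
    units = "differences"
    if per_site:
        d = d / mat.shape[1]
        units = "per-site"
    return DistanceMatrix(labels=list(h.labels), d=d, units=units)


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None) -> PhyloTree:
    """Saitou & Nei neighbor joining with the Q-criterion.

    Ties in Q are broken toward the smallest (i, j) index pair in the
    current node ordering (initially label order), making the topology
    deterministic. If ``outgroup`` is given the tree is rooted on the
    midpoint of its pendant edge.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if outgroup is not None and outgroup not in dm.labels:
        raise ValueError(f"outgroup {outgroup!r} not among labels")
    nodes = [TreeNode(name=l) for l in dm.labels]
    D = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = divmod(int(np.argmin(Q)), m)  # first minimum in row-major order
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2 * (m - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    # final three-point resolution
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    nodes[a].length = 0.5 * (dab + dac - dbc)
    nodes[b].length = 0.5 * (dab + dbc - dac)
    nodes[c].length = 0.5 * (dac + dbc - dab)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    tree = PhyloTree(root=root, labels=list(dm.labels))
    if outgroup is not None:
        tree = _root_on(tree, outgroup)
    return tree


def _root_on(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Re-root on the midpoint of the outgroup's pendant edge."""
    # build parent map
    parent: dict[int, TreeNode] = {}
    target = None
    def walk(node: TreeNode):
        nonlocal target
        for c in node.children:
            parent[id(c)] = node
            if c.is_leaf() and c.name == outgroup:
                target = c
            walk(c)
    walk(tree.root)
    if target is None:
        raise ValueError(f"outgroup {outgroup!r} not found in tree")
    og_parent = parent[id(target)]
    half = target.length / 2.0
    # walk from og_parent back to the old root, reversing edges
    path = [og_parent]
    while id(path[-1]) in parent:
        path.append(parent[id(path[-1])])
    for child, par in zip(path[:-1], path[1:]):
        par.children.remove(child)
        child.children.append(par)
        par.length = child.length
        par.support = child.support
    og_parent.children.remove(target)
    target.length = half
    og_parent.length = half
    new_root = TreeNode(children=[target, og_parent])
    return PhyloTree(root=new_root, labels=tree.labels)


def bootstrap_supports(h: HaplotypeSet, n_reps: int = 1000, seed: int = 0,
                       outgroup: str | None = None) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """NJ tree with bootstrap supports from resampling usable columns.

    Returns the original tree annotated with supports (percent of
    replicates containing each bipartition). With zero variable columns all
    supports are 0 and a warning is embedded in the result.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mat = h.haplotype_seqs
    n_hap, L = mat.shape
    dm = hamming_distances(h)
    tree = nj_tree(dm, outgroup=outgroup)
    original = tree.bipartitions()
    counts = {split: 0 for split in original}
    # only variable columns can change distances; precompute their mismatch stacks
    variable = np.flatnonzero([(len(np.unique(mat[:, c])) > 1) for c in range(L)])
    mism = np.array([(mat[:, c][:, None] != mat[:, c][None, :]) for c in variable],
                    dtype=np.float64)  # (V, H, H)
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        w = np.bincount(cols, minlength=L)[variable].astype(float)
        d = np.tensordot(w, mism, axes=1) if len(variable) else np.zeros((n_hap, n_hap))
        rep = nj_tree(DistanceMatrix(list(h.labels), d), outgroup=None)
        for split in rep.bipartitions():
            if split in counts:
                counts[split] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    tree.annotate_supports(supports)
    return tree, supports


def split_support(supports: dict[frozenset[str], float], group: set[str],
                  all_labels: set[str]) -> float | None:
    """Support for the bipartition separating ``group`` from the rest."""
    key = min(frozenset(group), frozenset(all_labels - group),
              key=lambda s: (len(s), sorted(s)))
    return supports.get(key)
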