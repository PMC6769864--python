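"""Median-joining haplotype networks (Bandelt, Forster & Roehl style).

The network starts from the epsilon-relaxed minimum spanning network
(MSN) over observed haplotypes: an edge (u, v) is included iff
d(u, v) <= minimax(u, v) + epsilon, where minimax is the bottleneck
(minimax-path) distance — at epsilon = 0 this is the union of all minimum
spanning trees. The algorithm then repeatedly proposes Steiner "median
vectors" (column-wise majority consensus of connected triplets), keeping
per pass only candidates whose connection cost is within epsilon of the
best, until no new medians arise; median vectors that end with degree < 3
are pruned. Edges are labelled with the mutated np positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .io import SiteIndex
from .popgen import HaplotypeSet


@dataclass
class HaploNetwork:
    graph: nx.Graph  # nodes carry: seq index, frequency, is_median; edges: weight, positions
    seqs: np.ndarray  # (n_nodes, L) uint8, observed haplotypes then medians
    usable_np: np.ndarray
    epsilon: int = 0

    @property
    def haplotype_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def total_frequency(self) -> int:
        return sum(d["frequency"] for _, d in self.graph.nodes(data=True))

    def edge_weight_sum(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def write_tsv(self, edges_path, nodes_path) -> None:
        with open(nodes_path, "w") as fh:
            fh.write("label\tfrequency\tis_median\n")
            for n, d in self.graph.nodes(data=True):
                fh.write(f"{n}\t{d['frequency']}\t{int(d['is_median'])}\n")
        with open(edges_path, "w") as fh:
            fh.write("u\tv\tn_mutations\tpositions\n")
            for u, v, d in self.graph.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['weight']}\t{','.join(map(str, d['positions']))}\n")


def _pairwise_hamming(seqs: np.ndarray) -> np.ndarray:
    d = np.zeros((seqs.shape[0], seqs.shape[0]), dtype=np.int64)
    for i in range(seqs.shape[0]):
        d[i] = (seqs != seqs[i]).sum(axis=1)
    return d


def _minimax(d: np.ndarray) -> np.ndarray:
    """Bottleneck distances: max edge on the minimax path, via the MST."""
    n = d.shape[0]
    mst = minimum_spanning_tree(d).toarray()
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if mst[i, j] > 0:
                adj[i].append((j, mst[i, j]))
                adj[j].append((i, mst[i, j]))
    out = np.zeros_like(d, dtype=float)
    for src in range(n):
        seen = {src}
        stack = [(src, 0.0)]
        while stack:
            node, best = stack.pop()
            for nb, w in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    m = max(best, w)
                    out[src, nb] = m
                    stack.append((nb, m))
    return out


def minimum_spanning_network(d: np.ndarray, epsilon: int = 0) -> list[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network."""
    mm = _minimax(d)
    edges = []
    n = d.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= mm[i, j] + epsilon:
                edges.append((i, j))
    return edges


def _majority_median(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Column-wise majority; ties (all three distinct) resolved toward ``a``."""
    med = a.copy()
    bc = b == c
    med[bc] = b[bc]  # b==c outvotes a where they agree; elsewhere a wins (a==b, a==c, or tie)
    return med


def median_joining(h: HaplotypeSet, idx: SiteIndex | None = None,
                   epsilon: int = 0, max_passes: int = 50) -> HaploNetwork:
    """Median-joining network over the haplotypes of ``h``.

    Only variable columns are carried internally (constant columns cannot
    contribute to distances or medians); reported positions are np
    coordinates of mutated sites.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if h.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    full = h.haplotype_seqs
    variable = np.flatnonzero([len(np.unique(full[:, c])) > 1 for c in range(full.shape[1])])
    seqs = full[:, variable].copy()
    var_np = h.usable_np[variable]
    n_obs = seqs.shape[0]
    labels = list(h.labels)
    freqs = {lbl: int(c) for lbl, c in zip(labels, h.counts)}

    all_seqs = [seqs[i] for i in range(n_obs)]
    keys = {s.tobytes(): i for i, s in enumerate(all_seqs)}

    def build_edges():
        d = _pairwise_hamming(np.vstack(all_seqs))
        return d, minimum_spanning_network(d, epsilon)

    for _ in range(max_passes):
        d, edges = build_edges()
        neighbors: dict[int, set[int]] = {i: set() for i in range(len(all_seqs))}
        for u, v in edges:
            neighbors[u].add(v)
            neighbors[v].add(u)
        candidates: dict[bytes, tuple[np.ndarray, int]] = {}
        for u in neighbors:
            nbrs = sorted(neighbors[u])
            for ai in range(len(nbrs)):
                for bi in range(ai + 1, len(nbrs)):
                    v, w = nbrs[ai], nbrs[bi]
                    trip = sorted((u, v, w))
                    med = _majority_median(*(all_seqs[t] for t in trip))
                    key = med.tobytes()
                    if key in keys or key in candidates:
                        continue
                    cost = int(sum((med != all_seqs[t]).sum() for t in trip))
                    candidates[key] = (med, cost)
        if not candidates:
            break
        lam = min(cost for _, cost in candidates.values())
        added = False
        for key, (med, cost) in sorted(candidates.items()):
            if cost <= lam + epsilon:
                keys[key] = len(all_seqs)
                all_seqs.append(med)
                added = True
        if not added:  # pragma: no cover
            break

    # prune median vectors of degree < 3 (not needed as intermediates)
    while True:
        d, edges = build_edges()
        deg = {i: 0 for i in range(len(all_seqs))}
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        drop = [i for i in range(n_obs, len(all_seqs)) if deg[i] < 3]
        if not drop:
            break
        keep = [i for i in range(len(all_seqs)) if i not in set(drop)]
        all_seqs = [all_seqs[i] for i in keep]
        keys = {s.tobytes(): i for i, s in enumerate(all_seqs)}

    d, edges = build_edges()
    g = nx.Graph()
    names = []
    for i in range(len(all_seqs)):
        if i < n_obs:
            name = labels[i]
            g.add_node(name, frequency=freqs[name], is_median=False)
        else:
            name = f"mv{i - n_obs + 1}"
            g.add_node(name, frequency=0, is_median=True)
        names.append(name)
    stacked = np.vstack(all_seqs)
    for u, v in edges:
        pos = var_np[stacked[u] != stacked[v]]
        g.add_edge(names[u], names[v], weight=int(d[u, v]),
                   positions=[int(p) for p in pos])
    net = HaploNetwork(graph=g, seqs=stacked, usable_np=var_np, epsilon=epsilon)
    return net


def cluster_separation(net: HaploNetwork, group_a: set[str], group_b: set[str]) -> int:
    """Mutational separation of two haplotype clusters in the network.

    Defined as the largest single-edge mutation count on the
    minimum-weight path between the closest pair of haplotype nodes drawn
    from the two groups — the long boundary branch between the clusters.
    """
    g = net.graph
    best_path = None
    best_len = np.inf
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for a in group_a:
        for b in group_b:
            if lengths[a].get(b, np.inf) < best_len:
                best_len = lengths[a][b]
                best_path = (a, b)
    if best_path is None:
        raise ValueError("groups are not connected in the network")
    path = nx.dijkstra_path(g, *best_path, weight="weight")
    return max(g.edges[u, v]["weight"] for u, v in zip(path[:-1], path[1:]))
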