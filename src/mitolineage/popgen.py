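"""Haplotype collapsing and Nei diversity statistics.

Implements the classic within-population summary bundle for a set of
aligned mitogenomes restricted to the usable sites of a
:class:`~mitolineage.io.SiteIndex`:

* S — number of variable (segregating) sites, split into singletons and
  parsimony-informative sites (column-level classification: a variable
  column is informative iff at least two bases each occur in >= 2
  sequences, a singleton otherwise);
* H — number of distinct haplotypes, with Nei's haplotype (gene) diversity
  Hd = n (1 - sum p_i^2) / (n - 1) and its sampling SD (Nei 1987, eq. 8.12);
* k — mean number of pairwise nucleotide differences, and nucleotide
  diversity Pi = k / L with Nei's total variance (eq. 10.7) as SD;
* a sliding-window Pi profile over np coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MitoAlignment, SiteIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class HaplotypeSet:
    """Distinct sequences over usable sites, with counts and memberships.

    Labels "H1", "H2", ... are assigned by descending count, ties broken by
    first occurrence in the alignment.
    """

    haplotype_seqs: np.ndarray  # (H, n_usable) uint8
    counts: np.ndarray  # (H,) int
    members: dict[str, list[str]]
    labels: list[str]
    n: int
    usable_np: np.ndarray  # 1-based np coordinate of each usable column

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n


@dataclass
class DiversityStats:
    S: int
    singletons: int
    parsimony_informative: int
    H: int
    Hd: float
    Hd_sd: float
    Pi: float
    Pi_sd: float
    k: float
    L_used: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class DiversityProfile:
    windows: pd.DataFrame  # columns: start_np, end_np, n_usable, Pi
    window_size: int
    step: int

    def peak(self) -> pd.Series:
        valid = self.windows.dropna(subset=["Pi"])
        return valid.loc[valid["Pi"].idxmax()]

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def collapse_haplotypes(aln: MitoAlignment, idx: SiteIndex) -> HaplotypeSet:
    """Group samples sharing identical bases at every usable site."""
    sub = aln.seq_matrix[:, idx.usable_sites]
    seen: dict[bytes, int] = {}
    members_by_h: list[list[str]] = []
    rows: list[np.ndarray] = []
    for i, sid in enumerate(aln.sample_ids):
        key = sub[i].tobytes()
        if key not in seen:
            seen[key] = len(rows)
            rows.append(sub[i])
            members_by_h.append([])
        members_by_h[seen[key]].append(sid)
    counts = np.array([len(m) for m in members_by_h])
    order = sorted(range(len(rows)), key=lambda h: (-counts[h], h))
    labels = [f"H{r + 1}" for r in range(len(rows))]
    usable_np = aln.np_of_column()[idx.usable_sites]
    return HaplotypeSet(
        haplotype_seqs=np.vstack([rows[h] for h in order]),
        counts=counts[order],
        members={f"H{r + 1}": members_by_h[h] for r, h in enumerate(order)},
        labels=labels,
        n=aln.n_samples,
        usable_np=usable_np,
    )


def _base_counts(mat: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Per-column counts of A, C, G, T -> (4, n_cols)."""
    if weights is None:
        weights = np.ones(mat.shape[0])
    return np.stack([weights @ (mat == b) for b in _BASES])


def classify_variable_sites(aln: MitoAlignment, idx: SiteIndex) -> tuple[int, int, int]:
    """Return (S, singletons, parsimony_informative) over usable sites."""
    if aln.n_samples < 2:
        raise ValueError("need >= 2 sequences")
    counts = _base_counts(aln.seq_matrix[:, idx.usable_sites])
    n_alleles = (counts >= 1).sum(axis=0)
    n_common = (counts >= 2).sum(axis=0)
    variable = n_alleles >= 2
    informative = variable & (n_common >= 2)
    S = int(variable.sum())
    pi_count = int(informative.sum())
    return S, S - pi_count, pi_count


def haplotype_diversity(h: HaplotypeSet) -> tuple[float, float]:
    """Nei's haplotype diversity and its sampling SD.

    Hd = n (1 - sum p_i^2) / (n - 1);
    V(Hd) = 2/(n(n-1)) * [2(n-2)(sum p_i^3 - (sum p_i^2)^2) + sum p_i^2 - (sum p_i^2)^2].
    """
    n = h.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = h.frequencies
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hd = n * (1.0 - s2) / (n - 1)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return hd, math.sqrt(max(var, 0.0))


def site_pair_differences(mat: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Per-column count of sequence pairs differing at that column.

    For column base counts c_b over n sequences this is
    C(n,2) - sum_b C(c_b,2); equal to a brute-force pairwise comparison.
    """
    counts = _base_counts(mat, weights)
    n = counts.sum(axis=0)
    return (n * (n - 1) - (counts * (counts - 1)).sum(axis=0)) / 2.0


def pairwise_differences(h: HaplotypeSet) -> tuple[float, float, float]:
    """Mean pairwise differences k, nucleotide diversity Pi = k/L, and Pi SD.

    Pi SD is the square root of Nei's (1987, eq. 10.7) total variance
    (stochastic + sampling):
    V(Pi) = (n+1)/(3(n-1)L) * Pi + 2(n^2+n+3)/(9n(n-1)) * Pi^2.
    """
    n = h.n
    if n < 2:
        raise ValueError("pairwise differences require n >= 2")
    L = h.haplotype_seqs.shape[1]
    if L < 1:
        raise ValueError("no usable sites")
    diffs = site_pair_differences(h.haplotype_seqs, h.counts.astype(float))
    n_pairs = n * (n - 1) / 2.0
    k = float(diffs.sum()) / n_pairs
    pi = k / L
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) * pi**2
    return k, pi, math.sqrt(var)


def diversity_stats(aln: MitoAlignment, idx: SiteIndex) -> DiversityStats:
    """The full per-population statistic bundle."""
    h = collapse_haplotypes(aln, idx)
    S, singles, informative = classify_variable_sites(aln, idx)
    hd, hd_sd = haplotype_diversity(h)
    k, pi, pi_sd = pairwise_differences(h)
    return DiversityStats(S=S, singletons=singles, parsimony_informative=informative,
                          H=h.n_haplotypes, Hd=hd, Hd_sd=hd_sd,
                          Pi=pi, Pi_sd=pi_sd, k=k, L_used=idx.n_usable)


def diversity_scan(aln: MitoAlignment, idx: SiteIndex,
                   window_size: int = 200, step: int = 25) -> DiversityProfile:
    """Sliding-window nucleotide diversity over np coordinates.

    Windows with zero usable sites get Pi = NaN (undefined), not zero.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    npos = aln.np_of_column()
    max_np = int(npos.max())
    usable_np = npos[idx.usable_sites]
    per_site = site_pair_differences(aln.seq_matrix[:, idx.usable_sites])
    n_pairs = aln.n_samples * (aln.n_samples - 1) / 2.0
    # accumulate per-np pair-difference mass and usable-site indicators
    diff_by_np = np.zeros(max_np + 1)
    usable_by_np = np.zeros(max_np + 1)
    diff_by_np[usable_np] = per_site
    usable_by_np[usable_np] = 1.0
    cum_d = np.concatenate([[0.0], np.cumsum(diff_by_np[1:])])
    cum_u = np.concatenate([[0.0], np.cumsum(usable_by_np[1:])])
    rows = []
    for start in range(1, max_np - window_size + 2, step):
        end = start + window_size - 1
        n_use = cum_u[end] - cum_u[start - 1]
        if n_use > 0:
            pi = (cum_d[end] - cum_d[start - 1]) / n_pairs / n_use
        else:
            pi = np.nan
        rows.append((start, end, int(n_use), pi))
    windows = pd.DataFrame(rows, columns=["start_np", "end_np", "n_usable", "Pi"])
    return DiversityProfile(windows=windows, window_size=window_size, step=step)


@dataclass
class Table1Report:
    """Per-breed diversity and haplogroup-composition table."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def summarize(aln: MitoAlignment, idx_builder, haplogroup_of: dict[str, str],
              haplogroup_order: list[str] | None = None) -> Table1Report:
    """Build a breed-by-breed summary with a pooled Total row.

    ``idx_builder`` maps a (sub)alignment to a SiteIndex, so each subset is
    filtered under the same site policy; the Total row is computed on the
    pooled alignment, not by summing per-breed statistics. Breeds with n < 2
    get NaN statistics (flagged unavailable).
    """
    breeds = sorted(set(aln.breed_map.values()))
    if haplogroup_order is None:
        haplogroup_order = sorted(set(haplogroup_of.values()))
    rows = []
    groups = [(b, [s for s in aln.sample_ids if aln.breed_map.get(s) == b]) for b in breeds]
    groups.append(("Total", list(aln.sample_ids)))
    for name, ids in groups:
        row: dict = {"breed": name, "n": len(ids)}
        for hg in haplogroup_order:
            row[hg] = sum(1 for s in ids if haplogroup_of.get(s) == hg)
        if len(ids) >= 2:
            sub = aln.subset(ids)
            stats = diversity_stats(sub, idx_builder(sub))
            row.update({k: v for k, v in stats.as_dict().items()
                        if k in {"S", "H", "k", "Hd", "Hd_sd", "Pi", "Pi_sd"}})
        else:
            row.update({k: np.nan for k in ["S", "H", "k", "Hd", "Hd_sd", "Pi", "Pi_sd"]})
        rows.append(row)
    return Table1Report(pd.DataFrame(rows))
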