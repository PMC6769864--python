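"""Motif-based haplogroup classification.

Assignment proceeds top-down through the motif hierarchy:

1. **Clade** — at the clade-diagnostic sites (fixed differences between the
   taurine and indicine matrilines), score each clade by the fraction of
   sites carrying its expected state (derived/alt for the clade the motif
   names, ancestral/ref for the other); the higher score wins.
2. **Haplogroup** — within the winning clade, score each haplogroup by the
   fraction of its own diagnostic alt alleles present. A backbone
   haplogroup (empty motif; T3 for the bovine frame) is scored by the
   fraction of *reference* alleles at its siblings' diagnostic sites. The
   best-scoring haplogroup is accepted when its score reaches the
   acceptance threshold (default 0.8); otherwise the call is
   ``"<clade>-novel"``.
3. **Sub-haplogroup** — a child motif (e.g. I1a) is assigned only when all
   of its assessable diagnostic alleles are present.

Sites where the query carries N or a gap are dropped from both matched and
total counts and recorded as unassessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import MitoAlignment
from .motifs import Motif, MotifTable

_MISSING = frozenset(b"N-")


@dataclass
class HaplogroupCall:
    sample_id: str
    clade: str
    haplogroup_label: str
    subhaplogroup_label: str | None
    matched: int
    total: int
    score: float
    mismatched_positions: list[int] = field(default_factory=list)
    unassessed_positions: list[int] = field(default_factory=list)
    tied_with: list[str] = field(default_factory=list)

    @property
    def is_novel(self) -> bool:
        return self.haplogroup_label.endswith("-novel")


def _allele_states(seq: np.ndarray, motif: Motif, np_to_col: dict[int, int] | None):
    """Yield (position, state) with state in {"ref","alt","other","missing"}."""
    for v in motif.variants:
        col = (np_to_col.get(v.position) if np_to_col is not None else v.position - 1)
        if col is None or col >= len(seq):
            yield v.position, "missing"
            continue
        b = seq[col]
        if b in _MISSING:
            yield v.position, "missing"
        elif b == ord(v.alt_allele):
            yield v.position, "alt"
        elif b == ord(v.ref_allele):
            yield v.position, "ref"
        else:
            yield v.position, "other"


def _score(seq, motif, want: str, np_to_col):
    matched, total = 0, 0
    mismatches, unassessed = [], []
    for pos, state in _allele_states(seq, motif, np_to_col):
        if state == "missing":
            unassessed.append(pos)
            continue
        total += 1
        if state == want:
            matched += 1
        else:
            mismatches.append(pos)
    score = matched / total if total else 0.0
    return score, matched, total, mismatches, unassessed


def _sibling_union_motif(table: MotifTable, clade: str, backbone: str) -> Motif:
    variants = [v for lbl in table.haplogroups_of(clade) if lbl != backbone
                for v in table.haplogroups[lbl].variants]
    return Motif(label=backbone, level="haplogroup", parent=clade, variants=variants)


def call_haplogroup(seq: np.ndarray, ref_seq: np.ndarray, table: MotifTable,
                    sample_id: str = "query", threshold: float = 0.8,
                    np_to_col: dict[int, int] | None = None) -> HaplogroupCall:
    """Classify one sequence (same coordinate frame as ``ref_seq``)."""
    if np_to_col is None and len(seq) < table.max_position:
        raise ValueError(
            f"sequence length {len(seq)} shorter than max motif position {table.max_position}")
    # 1. clade
    clade_scores: dict[str, tuple] = {}
    for clade in table.clade_labels():
        if clade in table.clades:
            clade_scores[clade] = _score(seq, table.clades[clade], "alt", np_to_col)
        else:  # the clade the reference frame belongs to: ref states at rival motifs
            rivals = [m for c, m in table.clades.items() if c != clade]
            variants = [v for m in rivals for v in m.variants]
            m = Motif(label=clade, level="clade", parent=None, variants=variants)
            clade_scores[clade] = _score(seq, m, "ref", np_to_col)
    clade = max(sorted(clade_scores), key=lambda c: clade_scores[c][0])
    # 2. haplogroup within clade
    hg_results: dict[str, tuple] = {}
    for label in table.haplogroups_of(clade):
        m = table.haplogroups[label]
        if len(m) == 0:
            m = _sibling_union_motif(table, clade, label)
            hg_results[label] = _score(seq, m, "ref", np_to_col)
        else:
            hg_results[label] = _score(seq, m, "alt", np_to_col)
    best, ties = None, []
    if hg_results:
        # score desc, assessable sites desc, label asc
        ranked = sorted(hg_results, key=lambda l: (-hg_results[l][0], -hg_results[l][2], l))
        best = ranked[0]
        ties = [l for l in ranked[1:]
                if hg_results[l][0] == hg_results[best][0]
                and hg_results[l][2] == hg_results[best][2]]
    if best is not None and hg_results[best][0] >= threshold:
        score, matched, total, mism, unass = hg_results[best]
        label = best
    else:
        label = f"{clade}-novel"
        score, matched, total, mism, unass = clade_scores[clade]
        ties = []
    # 3. sub-haplogroup: full motif required
    sub = None
    if not label.endswith("-novel"):
        for child in table.children_of(label):
            s, m_, t_, mm, ua = _score(seq, table.subhaplogroups[child], "alt", np_to_col)
            if t_ > 0 and m_ == t_:
                sub = child
                break
    return HaplogroupCall(sample_id=sample_id, clade=clade, haplogroup_label=label,
                          subhaplogroup_label=sub, matched=matched, total=total,
                          score=score, mismatched_positions=mism,
                          unassessed_positions=unass, tied_with=ties)


def classify_alignment(aln: MitoAlignment, ref_seq: np.ndarray, table: MotifTable,
                       threshold: float = 0.8) -> list[HaplogroupCall]:
    np_to_col = aln.column_of_np() if aln.ref_row is not None else None
    return [call_haplogroup(aln.seq_matrix[i], ref_seq, table,
                            sample_id=sid, threshold=threshold, np_to_col=np_to_col)
            for i, sid in enumerate(aln.sample_ids)]


def _pct(count: int, n: int) -> float:
    """Percentage with half-up rounding to 2 decimals, as printed in breed tables."""
    if n == 0:
        return 0.0
    frac = Decimal(100) * Decimal(count) / Decimal(n)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class HaplogroupFrequencies:
    table: pd.DataFrame  # columns: breed, level, label, count, n, percent

    def percent(self, label: str, breed: str = "Total") -> float:
        t = self.table
        row = t[(t["label"] == label) & (t["breed"] == breed)]
        if row.empty:
            return 0.0
        return float(row["percent"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.2f")


def frequency_table(calls: list[HaplogroupCall],
                    breed_map: dict[str, str] | None = None) -> HaplogroupFrequencies:
    """Counts and half-up percentages per haplogroup and clade, by breed and overall."""
    if not calls:
        raise ValueError("no calls")
    breed_map = breed_map or {}
    breeds = sorted(set(breed_map.get(c.sample_id, "Total") for c in calls) | {"Total"})
    rows = []
    for breed in breeds:
        sel = [c for c in calls
               if breed == "Total" or breed_map.get(c.sample_id, "Total") == breed]
        n = len(sel)
        labels = sorted({c.haplogroup_label for c in sel})
        for label in labels:
            cnt = sum(1 for c in sel if c.haplogroup_label == label)
            rows.append((breed, "haplogroup", label, cnt, n, _pct(cnt, n)))
        for clade in sorted({c.clade for c in sel}):
            cnt = sum(1 for c in sel if c.clade == clade)
            rows.append((breed, "clade", clade, cnt, n, _pct(cnt, n)))
        for sub in sorted({c.subhaplogroup_label for c in sel if c.subhaplogroup_label}):
            cnt = sum(1 for c in sel if c.subhaplogroup_label == sub)
            rows.append((breed, "subhaplogroup", sub, cnt, n, _pct(cnt, n)))
    return HaplogroupFrequencies(
        pd.DataFrame(rows, columns=["breed", "level", "label", "count", "n", "percent"]))


def haplotype_frequency_percents(counts: np.ndarray, n: int) -> list[float]:
    """Half-up percentages for haplotype counts (most common first)."""
    return [_pct(int(c), n) for c in sorted(counts, reverse=True)]


@dataclass
class NovelReport:
    entries: pd.DataFrame  # sample_id, clade, label, n_private, private_positions

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries["sample_id"])


def detect_novel(calls: list[HaplogroupCall], aln: MitoAlignment, ref_seq: np.ndarray,
                 table: MotifTable, min_private: int = 10) -> NovelReport:
    """List candidate novel lineages with their private-variant positions.

    A sample is reported when its haplogroup call is ``<clade>-novel``, or
    when it carries at least ``min_private`` substitutions relative to the
    reference that are not part of any motif it was assigned — the
    situation in which a divergent sub-haplogroup hides behind a backbone
    match (a T6-like lineage scores a perfect T3 before its motif is known).
    """
    npos = aln.np_of_column()
    rows = []
    by_id = {s: i for i, s in enumerate(aln.sample_ids)}
    for call in calls:
        seq = aln.seq_matrix[by_id[call.sample_id]]
        assigned_positions: set[int] = set()
        if not call.is_novel:
            hg = table.haplogroups[call.haplogroup_label]
            assigned_positions |= set(hg.positions)
            if hg.parent in table.clades:
                assigned_positions |= set(table.clades[hg.parent].positions)
            if call.subhaplogroup_label:
                assigned_positions |= set(table.subhaplogroups[call.subhaplogroup_label].positions)
        cols = np.flatnonzero(npos > 0)
        ref_at_cols = ref_seq[npos[cols] - 1]
        sub = seq[cols]
        mask = (sub != ref_at_cols) & (sub != ord("N")) & (sub != ord("-"))
        private = [int(p) for p in npos[cols[mask]] if int(p) not in assigned_positions]
        if call.is_novel or len(private) >= min_private:
            rows.append((call.sample_id, call.clade, call.haplogroup_label,
                         len(private), ",".join(map(str, private))))
    return NovelReport(pd.DataFrame(
        rows, columns=["sample_id", "clade", "label", "n_private", "private_positions"]))


def calls_to_frame(calls: list[HaplogroupCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample_id, c.clade, c.haplogroup_label, c.subhaplogroup_label or ".",
          f"{c.score:.4f}", ",".join(map(str, c.mismatched_positions)) or ".")
         for c in calls],
        columns=["sample_id", "clade", "haplogroup", "subhaplogroup", "score", "mismatches"])
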