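"""Diagnostic-variant motif tables for cattle mtDNA haplogroups.

A haplogroup is defined relative to the reference frame by a motif: the set
of substitutions (1-based np position, ref allele, alt allele) that jointly
diagnose membership. The packaged default table covers the taurine
haplogroups T1–T6 (T3 as the reference backbone), the indicine clade motif
and haplogroups I1/I2, and the sub-haplogroups T1a and I1a. T6 (12 sites)
and I1a (5 sites) use published positions; the remaining positions and all
alleles are synthetic stand-ins for the synthetic reference frame and are
flagged in the table's ``source`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

LEVELS = ("clade", "haplogroup", "subhaplogroup")
_BASES = set(b"ACGT")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticVariant:
    position: int  # 1-based np in the reference frame
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.position < 1:
            raise MotifError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise MotifError(f"ref == alt at np {self.position}")
        for a in (self.ref_allele, self.alt_allele):
            if len(a) != 1 or ord(a) not in _BASES:
                raise MotifError(f"allele {a!r} at np {self.position} not in ACGT")


@dataclass
class Motif:
    label: str
    level: str
    parent: str | None
    variants: list[DiagnosticVariant]
    source: str = "synthetic"

    @property
    def positions(self) -> list[int]:
        return [v.position for v in self.variants]

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class MotifTable:
    """Clade / haplogroup / sub-haplogroup diagnostic motifs.

    Exactly one haplogroup per clade may be a backbone (empty motif): the
    lineage whose alleles the reference frame itself carries (T3 for the
    bovine reference). Clade-level motifs list sites fixed between clades;
    the derived (alt) state diagnoses the named clade, the ancestral (ref)
    state the other clade.
    """

    clades: dict[str, Motif] = field(default_factory=dict)
    haplogroups: dict[str, Motif] = field(default_factory=dict)
    subhaplogroups: dict[str, Motif] = field(default_factory=dict)
    reference_id: str = "synthetic-ref"

    def validate(self) -> "MotifTable":
        for label, m in self.subhaplogroups.items():
            if m.parent not in self.haplogroups:
                raise MotifError(f"sub-haplogroup {label} references missing parent {m.parent!r}")
        for label, m in self.haplogroups.items():
            if m.parent is None:
                raise MotifError(f"haplogroup {label} has no clade")
        for m in self.all_motifs():
            pos = m.positions
            if len(set(pos)) != len(pos):
                dupes = sorted({p for p in pos if pos.count(p) > 1})
                raise MotifError(f"duplicate position(s) {dupes} within motif {m.label}")
        backbones: dict[str, list[str]] = {}
        for label, m in self.haplogroups.items():
            if len(m) == 0:
                backbones.setdefault(m.parent, []).append(label)
        for clade, labels in backbones.items():
            if len(labels) > 1:
                raise MotifError(f"clade {clade} has multiple backbone haplogroups: {labels}")
        return self

    def all_motifs(self) -> list[Motif]:
        return [*self.clades.values(), *self.haplogroups.values(), *self.subhaplogroups.values()]

    def all_positions(self) -> set[int]:
        return {p for m in self.all_motifs() for p in m.positions}

    @property
    def max_position(self) -> int:
        return max(self.all_positions())

    def clade_labels(self) -> list[str]:
        """All clade labels: those with explicit motifs plus parents of haplogroups."""
        labels = set(self.clades) | {m.parent for m in self.haplogroups.values()}
        return sorted(labels)

    def haplogroups_of(self, clade: str) -> list[str]:
        return sorted(l for l, m in self.haplogroups.items() if m.parent == clade)

    def children_of(self, haplogroup: str) -> list[str]:
        return sorted(l for l, m in self.subhaplogroups.items() if m.parent == haplogroup)

    def motif(self, label: str) -> Motif:
        for group in (self.subhaplogroups, self.haplogroups, self.clades):
            if label in group:
                return group[label]
        raise KeyError(label)


def load_motif_table(source, reference_id: str = "synthetic-ref") -> MotifTable:
    """Load a motif table from TSV.

    Columns: level, label, parent, position, ref, alt[, source]. A row with
    position '.' declares a backbone haplogroup with no variants of its own.
    Lines starting with '#' and a header line are skipped.
    """
    text = Path(source).read_text()
    table = MotifTable(reference_id=reference_id)
    groups = {"clade": table.clades, "haplogroup": table.haplogroups,
              "subhaplogroup": table.subhaplogroups}
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "level":
            continue
        if len(parts) < 6:
            raise MotifError(f"line {ln}: expected >= 6 tab-separated columns")
        level, label, parent, pos, ref, alt = parts[:6]
        src = parts[6] if len(parts) > 6 else "unspecified"
        if level not in LEVELS:
            raise MotifError(f"line {ln}: unknown level {level!r}")
        group = groups[level]
        if label not in group:
            group[label] = Motif(label=label, level=level,
                                 parent=parent or None, variants=[], source=src)
        if pos != ".":
            group[label].variants.append(DiagnosticVariant(int(pos), ref, alt))
    return table.validate()


def default_motif_table() -> MotifTable:
    """The packaged default table (synthetic reference frame)."""
    path = resources.files("mitolineage.data").joinpath("motifs_default.tsv")
    with resources.as_file(path) as p:
        return load_motif_table(p)


def motif_lineage(table: MotifTable, haplogroup: str, subhaplogroup: str | None = None
                  ) -> list[DiagnosticVariant]:
    """All variants carried by a lineage: clade motif + haplogroup + sub motif."""
    hg = table.haplogroups[haplogroup]
    variants = list(hg.variants)
    if hg.parent in table.clades:
        variants = list(table.clades[hg.parent].variants) + variants
    if subhaplogroup is not None:
        sub = table.subhaplogroups[subhaplogroup]
        if sub.parent != haplogroup:
            raise MotifError(f"{subhaplogroup} is not a child of {haplogroup}")
        variants += sub.variants
    return variants


def apply_motif(ref_seq: np.ndarray, variants: list[DiagnosticVariant]) -> np.ndarray:
    """Return a copy of ``ref_seq`` with each variant's alt allele applied."""
    seq = ref_seq.copy()
    for v in variants:
        if v.position > len(seq):
            raise MotifError(f"np {v.position} beyond sequence length {len(seq)}")
        seq[v.position - 1] = ord(v.alt_allele)
    return seq
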