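"""Synthetic mitogenome cohorts with known haplogroup structure.

The generator emulates the structure of a composite-breed cattle cohort in
a ~16.3 kb reference coordinate frame: each animal's mitogenome is the
reference sequence plus the diagnostic motif of its haplogroup (indicine
animals additionally carry the deep taurine/indicine clade motif), plus
private substitutions. Private substitutions are placed with a control-
region ("D-loop") hotspot weighting and a 10:1 transition:transversion
bias, typical of mammalian mtDNA.

Two noise modes exist:

* template mode (default): samples within a haplogroup are partitioned into
  haplotype templates; satellite templates carry 1 + Poisson(rate - 1)
  private mutations around a mutation-free core, producing the star-like
  clusters, singletons and parsimony-informative sites seen in real
  matrilineal data. The realized haplotype partition equals the template
  partition exactly.
* per-sample mode (``template_counts=None``): every sample independently
  draws Poisson(rate) private mutations.

The default composition (:func:`yunling_composition`) encodes a 129-animal
cohort with haplogroup counts {T1:19, T2:5, T3:37, T4:7, T6:2, I1:54, I2:5},
47 haplotype templates (largest 17, second 12, twenty singletons) and a
28-animal I1a star inside I1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import MitoAlignment, write_alignment
from .motifs import MotifTable, apply_motif, default_motif_table, motif_lineage

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_FREQS = np.array([0.33, 0.26, 0.13, 0.28])  # A, C, G, T (bovine mtDNA-like)
_TS = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T


@dataclass
class SyntheticConfig:
    seed: int = 0
    ref_seed: int | None = None  # reference-frame seed; defaults to seed
    ref_length: int = 16338
    breed: str = "Yunling"
    # haplogroup label -> number of samples
    haplogroup_counts: dict[str, int] = field(default_factory=lambda: dict(YUNLING_HAPLOGROUP_COUNTS))
    # haplogroup label -> per-template sample counts (None => per-sample mode)
    template_counts: dict[str, list[int]] | None = field(
        default_factory=lambda: {k: list(v) for k, v in YUNLING_TEMPLATE_COUNTS.items()})
    # sub-haplogroup label -> (parent haplogroup, template indices carrying the sub motif)
    sub_templates: dict[str, tuple[str, list[int]]] = field(
        default_factory=lambda: {k: (v[0], list(v[1])) for k, v in YUNLING_SUB_TEMPLATES.items()})
    private_mutation_rate: float = 3.0
    sample_mutation_rate: float = 0.0  # extra per-sample noise on top of templates
    hotspot_start: int = 15909
    hotspot_end: int = 16315
    hotspot_multiplier: float = 20.0
    avoid_diagnostic_positions: bool = True
    indel_columns: int = 0  # optional: gap columns planted inside the hotspot

    def __post_init__(self):
        if any(c < 0 for c in self.haplogroup_counts.values()):
            raise ValueError("haplogroup counts must be >= 0")
        if not (1 <= self.hotspot_start <= self.hotspot_end <= self.ref_length):
            raise ValueError("hotspot interval must lie within the reference")
        if self.template_counts is not None:
            for hg, counts in self.template_counts.items():
                if sum(counts) != self.haplogroup_counts.get(hg, 0):
                    raise ValueError(f"template counts for {hg} do not sum to its sample count")


# Composition of the default 129-animal cohort. Haplogroup counts follow the
# published breed table; template counts realize 47 haplotypes with the
# published frequency skeleton (top haplotype 17, second 12, 20 singletons;
# the remaining 80 samples split near-equally into five 4s and twenty 3s).
YUNLING_HAPLOGROUP_COUNTS = {"T1": 19, "T2": 5, "T3": 37, "T4": 7, "T6": 2, "I1": 54, "I2": 5}
YUNLING_TEMPLATE_COUNTS = {
    "T1": [4, 3, 3, 3, 3, 3],
    "T2": [3, 1, 1],
    "T3": [12, 3, 3, 3, 3, 3, 3, 3, 1, 1, 1, 1],
    "T4": [4, 3],
    "T6": [1, 1],
    "I1": [17, 4, 4, 3, 3, 3, 3, 3, 3, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "I2": [4, 1],
}
# The I1a star: the I1 core plus its singleton satellites.
YUNLING_SUB_TEMPLATES = {"I1a": ("I1", [0] + list(range(9, 20)))}

# Control cohort in the same frame (31 animals, 20 haplotypes).
BRAHMAN_HAPLOGROUP_COUNTS = {"T1": 11, "T3": 8, "I1": 7, "I2": 5}
BRAHMAN_TEMPLATE_COUNTS = {
    "T1": [4, 3, 2, 1, 1],
    "T3": [3, 2, 1, 1, 1],
    "I1": [2, 2, 1, 1, 1],
    "I2": [1, 1, 1, 1, 1],
}


def yunling_composition(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, **overrides)


def brahman_composition(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        breed="Brahman",
        haplogroup_counts=dict(BRAHMAN_HAPLOGROUP_COUNTS),
        template_counts={k: list(v) for k, v in BRAHMAN_TEMPLATE_COUNTS.items()},
        sub_templates={},
        **overrides,
    )


@dataclass
class SampleTruth:
    sample_id: str
    breed: str
    haplogroup: str
    subhaplogroup: str | None
    template: str  # haplotype class label, e.g. "I1.3"
    private_positions: list[int]


@dataclass
class GroundTruth:
    samples: list[SampleTruth]
    hotspot: tuple[int, int]
    ref_seq: np.ndarray

    def haplotype_partition(self) -> dict[str, list[str]]:
        part: dict[str, list[str]] = {}
        for s in self.samples:
            part.setdefault(s.template, []).append(s.sample_id)
        return part

    def labels(self) -> dict[str, tuple[str, str | None]]:
        return {s.sample_id: (s.haplogroup, s.subhaplogroup) for s in self.samples}


def make_reference(cfg: SyntheticConfig, table: MotifTable | None = None) -> np.ndarray:
    """Deterministic synthetic reference sequence carrying the motif table's
    ref alleles at every diagnostic position."""
    table = table if table is not None else default_motif_table()
    if cfg.ref_length < table.max_position:
        raise ValueError(
            f"ref_length {cfg.ref_length} < max motif position {table.max_position}")
    rng = np.random.default_rng(cfg.seed if cfg.ref_seed is None else cfg.ref_seed)
    seq = rng.choice(_BASES, size=cfg.ref_length, p=_BASE_FREQS).astype(np.uint8)
    for m in table.all_motifs():
        for v in m.variants:
            seq[v.position - 1] = ord(v.ref_allele)
    return seq


def _position_weights(cfg: SyntheticConfig, forbidden: set[int]) -> np.ndarray:
    w = np.ones(cfg.ref_length)
    w[cfg.hotspot_start - 1 : cfg.hotspot_end] = cfg.hotspot_multiplier
    if cfg.avoid_diagnostic_positions:
        for p in forbidden:
            if p <= cfg.ref_length:
                w[p - 1] = 0.0
    return w / w.sum()


def _draw_privates(rng, n: int, probs: np.ndarray) -> list[int]:
    if n <= 0:
        return []
    pos = rng.choice(len(probs), size=n, replace=False, p=probs) + 1
    return sorted(int(p) for p in pos)


def _mutate(rng, seq: np.ndarray, positions: list[int]) -> None:
    for p in positions:
        ref = int(seq[p - 1])
        if rng.random() < 10 / 11:  # 10:1 transition:transversion
            seq[p - 1] = _TS[ref]
        else:
            choices = [b for b in (65, 67, 71, 84) if b not in (ref, _TS[ref])]
            seq[p - 1] = choices[rng.integers(2)]


def generate_cohort(cfg: SyntheticConfig, table: MotifTable | None = None
                    ) -> tuple[MitoAlignment, GroundTruth]:
    """Generate an aligned cohort plus its ground truth."""
    table = table if table is not None else default_motif_table()
    for hg in cfg.haplogroup_counts:
        if hg not in table.haplogroups:
            raise ValueError(f"haplogroup {hg!r} absent from motif table")
    for sub, (parent, _) in cfg.sub_templates.items():
        if sub not in table.subhaplogroups or table.subhaplogroups[sub].parent != parent:
            raise ValueError(f"sub-haplogroup {sub!r} (parent {parent!r}) absent from motif table")
    rng = np.random.default_rng(cfg.seed)
    ref = make_reference(cfg, table)
    probs = _position_weights(cfg, table.all_positions())
    sub_of_template: dict[tuple[str, int], str] = {
        (parent, t): sub for sub, (parent, idxs) in cfg.sub_templates.items() for t in idxs}

    rows: list[np.ndarray] = []
    truths: list[SampleTruth] = []
    prefix = "".join(c for c in cfg.breed if c.isupper())[:2] or cfg.breed[:2].upper()
    counter = 0

    def add_sample(hg, sub, template_label, base_seq, template_privates):
        nonlocal counter
        counter += 1
        sid = f"{prefix}{counter:03d}"
        seq = base_seq.copy()
        extra: list[int] = []
        if cfg.sample_mutation_rate > 0:
            extra = _draw_privates(rng, rng.poisson(cfg.sample_mutation_rate), probs)
            _mutate(rng, seq, extra)
        rows.append(seq)
        truths.append(SampleTruth(sid, cfg.breed, hg, sub, template_label,
                                  sorted(template_privates + extra)))

    for hg, n_hg in cfg.haplogroup_counts.items():
        if n_hg == 0:
            continue
        if cfg.template_counts is not None:
            counts = cfg.template_counts[hg]
            seen: set[bytes] = set()
            for t_idx, t_n in enumerate(counts):
                sub = sub_of_template.get((hg, t_idx))
                lineage = apply_motif(ref, motif_lineage(table, hg, sub))
                # core template (index 0 within its sub-class) is mutation-free;
                # satellites carry >=1 private site; redraw on the rare clash so
                # the template partition is exactly the haplotype partition
                is_core = t_idx == 0 or (sub is not None and
                                         t_idx == cfg.sub_templates[sub][1][0])
                # at rate 0 templates within a motif class deliberately merge
                no_noise = is_core or cfg.private_mutation_rate == 0
                for _ in range(100):
                    if no_noise:
                        priv: list[int] = []
                    else:
                        lam = max(cfg.private_mutation_rate - 1.0, 0.0)
                        priv = _draw_privates(rng, 1 + rng.poisson(lam), probs)
                    seq = lineage.copy()
                    _mutate(rng, seq, priv)
                    key = seq.tobytes()
                    if no_noise or key not in seen:
                        seen.add(key)
                        break
                else:  # pragma: no cover
                    raise RuntimeError("could not draw a distinct template")
                for _ in range(t_n):
                    add_sample(hg, sub, f"{hg}.{t_idx}", seq, priv)
        else:
            for i in range(n_hg):
                sub = None
                lineage = apply_motif(ref, motif_lineage(table, hg, sub))
                priv = _draw_privates(rng, rng.poisson(cfg.private_mutation_rate), probs)
                seq = lineage.copy()
                _mutate(rng, seq, priv)
                rows.append(seq)
                counter += 1
                truths.append(SampleTruth(f"{prefix}{counter:03d}", cfg.breed, hg, sub,
                                          f"{hg}.s{i}", priv))

    mat = np.vstack(rows)
    if cfg.indel_columns > 0:
        cols = rng.choice(np.arange(cfg.hotspot_start - 1, cfg.hotspot_end),
                          size=min(cfg.indel_columns, 2), replace=False)
        victims = rng.choice(mat.shape[0], size=max(1, mat.shape[0] // 2), replace=False)
        for c in cols:
            mat[victims, c] = ord("-")
    ids = [t.sample_id for t in truths]
    aln = MitoAlignment(ids, mat, ref_id=table.reference_id,
                        breed_map={i: cfg.breed for i in ids})
    return aln, GroundTruth(truths, (cfg.hotspot_start, cfg.hotspot_end), ref)


def merge_cohorts(a: tuple[MitoAlignment, GroundTruth],
                  b: tuple[MitoAlignment, GroundTruth]) -> tuple[MitoAlignment, GroundTruth]:
    """Pool two cohorts generated in the same reference frame."""
    aln_a, gt_a = a
    aln_b, gt_b = b
    if aln_a.aligned_length != aln_b.aligned_length:
        raise ValueError("cohorts have different aligned lengths")
    if not np.array_equal(gt_a.ref_seq, gt_b.ref_seq):
        raise ValueError("cohorts were generated against different references")
    ids = aln_a.sample_ids + [f"{s}b" if s in set(aln_a.sample_ids) else s
                              for s in aln_b.sample_ids]
    rename = dict(zip(aln_b.sample_ids, ids[aln_a.n_samples:]))
    mat = np.vstack([aln_a.seq_matrix, aln_b.seq_matrix])
    breeds = dict(aln_a.breed_map)
    breeds.update({rename[s]: b for s, b in aln_b.breed_map.items()})
    truths = list(gt_a.samples) + [replace(t, sample_id=rename[t.sample_id])
                                   for t in gt_b.samples]
    aln = MitoAlignment(ids, mat, ref_id=aln_a.ref_id, breed_map=breeds)
    return aln, GroundTruth(truths, gt_a.hotspot, gt_a.ref_seq)


def write_fixture(aln: MitoAlignment, truth: GroundTruth, out_dir) -> dict[str, Path]:
    """Write FASTA + breed TSV + ground-truth TSV, re-readable by the io module."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "cohort.fasta",
        "breeds": out / "breeds.tsv",
        "truth": out / "truth.tsv",
        "reference": out / "reference.fasta",
    }
    write_alignment(aln, paths["fasta"], paths["breeds"])
    from .io import write_fasta
    write_fasta(paths["reference"], ["reference"], [truth.ref_seq])
    with open(paths["truth"], "w") as fh:
        fh.write("sample_id\tbreed\thaplogroup\tsubhaplogroup\ttemplate\tprivate_positions\n")
        for s in truth.samples:
            fh.write(f"{s.sample_id}\t{s.breed}\t{s.haplogroup}\t"
                     f"{s.subhaplogroup or '.'}\t{s.template}\t"
                     f"{','.join(map(str, s.private_positions)) or '.'}\n")
    return paths
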