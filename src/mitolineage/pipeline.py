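"""End-to-end orchestration: validate inputs, run every stage, write artifacts."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import calls_to_frame, classify_alignment, detect_novel, frequency_table
from .io import MitoAlignment, build_site_index, read_alignment, write_fasta
from .motifs import MotifTable, default_motif_table, load_motif_table
from .network import median_joining
from .phylo import bootstrap_supports
from .popgen import collapse_haplotypes, diversity_scan, diversity_stats, summarize


@dataclass
class RunConfig:
    fasta: str
    breed_map: str | None = None
    reference_fasta: str | None = None  # record id'd "reference"; defaults to first motif-consistent frame
    motif_table: str | None = None  # packaged default if None
    site_policy: str = "complete"
    window_size: int = 200
    step: int = 25
    epsilon: int = 0
    bootstrap_reps: int = 1000
    seed: int = 0
    out_dir: str = "results"
    overwrite: bool = False


@dataclass
class Diagnostics:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _load(cfg: RunConfig) -> tuple[MitoAlignment, MotifTable, np.ndarray]:
    table = load_motif_table(cfg.motif_table) if cfg.motif_table else default_motif_table()
    aln = read_alignment(cfg.fasta, cfg.breed_map)
    if cfg.reference_fasta:
        ref = _read_reference(cfg.reference_fasta)
    else:
        # fall back: reconstruct the frame consensus as the per-column majority base
        ref = np.apply_along_axis(
            lambda col: np.bincount(col, minlength=256).argmax(), 0, aln.seq_matrix
        ).astype(np.uint8)
    return aln, table, ref


def _read_reference(path) -> np.ndarray:
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"))
    return np.frombuffer(str(rec.seq).upper().replace("U", "T").encode(), dtype=np.uint8).copy()


def validate_inputs(cfg: RunConfig) -> Diagnostics:
    """Dry-run checks of formats, coordinate ranges and motif consistency."""
    diag = Diagnostics()
    try:
        aln, table, ref = _load(cfg)
    except FileNotFoundError as e:
        diag.errors.append(f"missing input file: {e.filename or e}")
        return diag
    except Exception as e:  # surfaced as a diagnostic, not a crash
        diag.errors.append(str(e))
        return diag
    if table.max_position > aln.aligned_length:
        diag.errors.append(
            f"motif position {table.max_position} beyond alignment length {aln.aligned_length}")
    missing = [s for s in aln.sample_ids if s not in aln.breed_map]
    if cfg.breed_map is not None and missing:
        diag.warnings.append(f"samples absent from breed map: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
    if len(ref) != aln.aligned_length:
        diag.errors.append("reference length differs from alignment length")
    return diag


def run_full(cfg: RunConfig) -> dict:
    """Run the complete pipeline; returns a manifest dict (also written to disk)."""
    diag = validate_inputs(cfg)
    if not diag.ok:
        raise RuntimeError("input validation failed: " + "; ".join(diag.errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {k: out / v for k, v in {
        "table1": "table1.tsv", "frequencies": "frequencies.tsv", "calls": "calls.tsv",
        "novel": "novel.tsv", "profile": "diversity_profile.tsv", "tree": "tree.nwk",
        "network_edges": "network_edges.tsv", "network_nodes": "network_nodes.tsv",
        "haplotypes": "haplotypes.fasta", "manifest": "manifest.json"}.items()}
    if not cfg.overwrite:
        clashes = [str(p) for p in artifacts.values() if p.exists()]
        if clashes:
            raise RuntimeError(f"refusing to overwrite existing outputs: {clashes}")

    aln, table, ref = _load(cfg)
    idx = build_site_index(aln, cfg.site_policy)
    haps = collapse_haplotypes(aln, idx)
    calls = classify_alignment(aln, ref, table)
    hg_of = {c.sample_id: c.haplogroup_label for c in calls}

    summarize(aln, lambda a: build_site_index(a, cfg.site_policy), hg_of).to_tsv(artifacts["table1"])
    frequency_table(calls, aln.breed_map).to_tsv(artifacts["frequencies"])
    calls_to_frame(calls).to_csv(artifacts["calls"], sep="\t", index=False)
    detect_novel(calls, aln, ref, table).entries.to_csv(artifacts["novel"], sep="\t", index=False)
    diversity_scan(aln, idx, cfg.window_size, cfg.step).to_tsv(artifacts["profile"])
    tree, _ = bootstrap_supports(haps, n_reps=cfg.bootstrap_reps, seed=cfg.seed)
    artifacts["tree"].write_text(tree.newick() + "\n")
    net = median_joining(haps, idx, epsilon=cfg.epsilon)
    net.write_tsv(artifacts["network_edges"], artifacts["network_nodes"])
    write_fasta(artifacts["haplotypes"], haps.labels, haps.haplotype_seqs)

    manifest = {
        "package": "mitolineage",
        "version": __version__,
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "inputs": {name: _sha256(p) for name, p in
                   [("fasta", cfg.fasta), ("breed_map", cfg.breed_map),
                    ("motif_table", cfg.motif_table), ("reference", cfg.reference_fasta)]
                   if p is not None},
        "outputs": {k: str(v) for k, v in artifacts.items()},
        "n_samples": aln.n_samples,
        "n_haplotypes": haps.n_haplotypes,
        "stats": diversity_stats(aln, idx).as_dict(),
    }
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
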