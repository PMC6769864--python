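"""Reading, validating and indexing reference-frame mitogenome alignments.

Coordinate convention used throughout the package: nucleotide positions
("np") are 1-based in the reference frame, the same convention as published
diagnostic-site lists for the bovine reference V00654. For an alignment
without reference insertions, column ``i`` (0-based) corresponds to np
``i + 1``. When a reference row containing gap characters is supplied,
inserted columns carry no np and are excluded from motif matching.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = b"ACGTN-"
_GAP = ord("-")
_N = ord("N")


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments (ragged rows, duplicates)."""


class ValidationError(ValueError):
    """Raised for content-level problems (illegal characters, bad metadata)."""


@dataclass
class MitoAlignment:
    """A reference-frame alignment of complete mitogenome sequences.

    ``seq_matrix`` is an (n_samples, aligned_length) uint8 array of ASCII
    codes over {A, C, G, T, N, -}.
    """

    sample_ids: list[str]
    seq_matrix: np.ndarray
    ref_id: str = "synthetic-ref"
    ref_row: np.ndarray | None = None
    breed_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq_matrix = np.ascontiguousarray(self.seq_matrix, dtype=np.uint8)
        if self.seq_matrix.ndim != 2:
            raise AlignmentError("seq_matrix must be 2-D (samples x columns)")
        if len(self.sample_ids) != self.seq_matrix.shape[0]:
            raise AlignmentError("sample_ids and seq_matrix row count differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        legal = np.zeros(256, dtype=bool)
        legal[list(ALPHABET)] = True
        bad = ~legal[self.seq_matrix]
        if bad.any():
            r, c = np.argwhere(bad)[0]
            ch = chr(int(self.seq_matrix[r, c]))
            raise ValidationError(
                f"illegal character {ch!r} in {self.sample_ids[r]} at column {c + 1}"
            )
        unknown = set(self.breed_map) - set(self.sample_ids)
        if unknown:
            raise ValidationError(f"breed map ids absent from alignment: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.seq_matrix.shape[0]

    @property
    def aligned_length(self) -> int:
        return self.seq_matrix.shape[1]

    def np_of_column(self) -> np.ndarray:
        """Map 0-based columns to 1-based reference positions (0 = inserted)."""
        if self.ref_row is None:
            return np.arange(1, self.aligned_length + 1)
        is_ref = self.ref_row != _GAP
        npos = np.cumsum(is_ref)
        npos[~is_ref] = 0
        return npos

    def column_of_np(self) -> dict[int, int]:
        npos = self.np_of_column()
        return {int(p): int(c) for c, p in enumerate(npos) if p > 0}

    def subset(self, sample_ids: Sequence[str]) -> "MitoAlignment":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MitoAlignment(
            sample_ids=list(sample_ids),
            seq_matrix=self.seq_matrix[idx],
            ref_id=self.ref_id,
            ref_row=self.ref_row,
            breed_map={s: b for s, b in self.breed_map.items() if s in set(sample_ids)},
        )


@dataclass
class SiteIndex:
    """Partition of alignment columns into usable and excluded sites.

    ``coordinate_base`` is fixed at 1 ("np" positions); ``excluded_sites``
    maps 0-based column -> reason code ("gap", "ambiguous", "inserted").
    """

    usable_sites: np.ndarray
    excluded_sites: dict[int, str]
    n_columns: int
    coordinate_base: int = 1

    def __post_init__(self) -> None:
        self.usable_sites = np.asarray(self.usable_sites, dtype=np.int64)
        if len(self.usable_sites) + len(self.excluded_sites) != self.n_columns:
            raise ValidationError("usable and excluded sites must partition all columns")
        if np.any(np.diff(self.usable_sites) <= 0):
            raise ValidationError("usable_sites must be strictly increasing")

    @property
    def n_usable(self) -> int:
        return len(self.usable_sites)


def _normalize(seq: str) -> bytes:
    return seq.upper().replace("U", "T").encode("ascii")


def read_breed_map(source) -> dict[str, str]:
    """Read a two-column TSV (sample_id, breed); a header line is tolerated."""
    path = Path(source)
    out: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}:{ln}: expected 2 tab-separated columns")
        if ln == 1 and parts[0].lower() in {"sample_id", "sample", "id"}:
            continue
        out[parts[0]] = parts[1]
    return out


def read_alignment(
    fasta_source,
    breed_map_source=None,
    ref_id: str = "synthetic-ref",
    ref_record_id: str | None = None,
) -> MitoAlignment:
    """Read a multi-FASTA alignment (and optional breed TSV) into a MitoAlignment.

    If ``ref_record_id`` names one of the records, that record becomes the
    reference row defining the np frame and is removed from the sample rows.
    """
    handle = fasta_source
    if isinstance(fasta_source, (str, Path)):
        handle = open(fasta_source)
    with handle if hasattr(handle, "close") else _io.StringIO(handle) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) < 2:
        raise AlignmentError("need at least 2 FASTA records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        by_len: dict[int, list[str]] = {}
        for r in records:
            by_len.setdefault(len(r.seq), []).append(r.id)
        raise AlignmentError(f"records have unequal aligned lengths: {by_len}")
    ref_row = None
    sample_records = []
    for r in records:
        if ref_record_id is not None and r.id == ref_record_id:
            ref_row = np.frombuffer(_normalize(str(r.seq)), dtype=np.uint8)
        else:
            sample_records.append(r)
    ids = [r.id for r in sample_records]
    mat = np.vstack(
        [np.frombuffer(_normalize(str(r.seq)), dtype=np.uint8) for r in sample_records]
    )
    breed_map = read_breed_map(breed_map_source) if breed_map_source is not None else {}
    return MitoAlignment(ids, mat, ref_id=ref_id, ref_row=ref_row, breed_map=breed_map)


def build_site_index(aln: MitoAlignment, policy: str = "complete") -> SiteIndex:
    """Classify columns as usable or excluded under a deletion policy.

    ``complete`` (default): any column containing '-' or 'N' in any row is
    excluded; ``pairwise`` keeps such columns usable (downstream statistics
    then skip missing data pair by pair). Columns inserted relative to the
    reference row are always excluded (they carry no np coordinate).
    """
    if policy not in {"complete", "pairwise"}:
        raise ValidationError(f"unknown site policy {policy!r}")
    mat = aln.seq_matrix
    has_gap = (mat == _GAP).any(axis=0)
    has_n = (mat == _N).any(axis=0)
    inserted = aln.np_of_column() == 0
    excluded: dict[int, str] = {}
    for col in np.flatnonzero(inserted):
        excluded[int(col)] = "inserted"
    if policy == "complete":
        for col in np.flatnonzero(has_gap & ~inserted):
            excluded[int(col)] = "gap"
        for col in np.flatnonzero(has_n & ~has_gap & ~inserted):
            excluded[int(col)] = "ambiguous"
    usable = np.setdiff1d(np.arange(aln.aligned_length), np.fromiter(excluded, dtype=np.int64, count=len(excluded)))
    if len(usable) == 0:
        raise ValidationError("no usable sites remain under the site policy")
    return SiteIndex(usable_sites=usable, excluded_sites=excluded, n_columns=aln.aligned_length)


def write_fasta(path, ids: Iterable[str], seqs: Iterable[np.ndarray | str]) -> None:
    """Write sequences (uint8 rows or strings) as a normalized multi-FASTA."""
    records = []
    for sid, seq in zip(ids, seqs):
        if isinstance(seq, np.ndarray):
            seq = seq.tobytes().decode("ascii")
        records.append(SeqRecord(Seq(seq), id=str(sid), description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_alignment(aln: MitoAlignment, fasta_path, breed_path=None) -> None:
    write_fasta(fasta_path, aln.sample_ids, aln.seq_matrix)
    if breed_path is not None:
        with open(breed_path, "w") as fh:
            fh.write("sample_id\tbreed\n")
            for sid in aln.sample_ids:
                fh.write(f"{sid}\t{aln.breed_map.get(sid, 'NA')}\n")
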