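"""Readers, writers and coordinate conventions shared by the whole pipeline.

All internal coordinates are 1-based inclusive, the convention of SAM, GFF3
and of the printed Mi-549 locus (chr12_2:64,820,556-64,821,104 spans exactly
549 bp only under 1-based inclusive arithmetic). BED's 0-based half-open
convention is translated at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AlignmentRecord",
    "read_fasta",
    "write_fasta",
    "read_depth_table",
    "write_depth_table",
    "bed_to_internal",
    "internal_to_bed",
    "read_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_outfmt6",
    "write_outfmt6",
    "read_tpm_matrix",
    "write_tpm_matrix",
]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs (0 if on different sequences)."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene feature with its rank along the chromosome (used for synteny)."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    ordinal: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or - (got {self.strand!r})")
        if self.ordinal < 0:
            raise ValueError("ordinal must be non-negative")


@dataclass(frozen=True)
class AlignmentRecord:
    """One row of 12-column tabular alignment output (blastn -outfmt 6).

    The dialect reports gap *opens*; ``gap_bases`` is derived from the
    alignment length, the identity percentage and the mismatch count
    (matches = round(pident * length / 100); the remainder of the aligned
    columns are gap positions).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    gap_bases: int = field(default=-1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0, 100]: {self.pct_identity}")
        for name in ("q_start", "q_end", "s_start", "s_end"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.gap_bases < 0:
            matches = round(self.pct_identity * self.aln_length / 100.0)
            derived = max(0, self.aln_length - matches - self.mismatches)
            object.__setattr__(self, "gap_bases", derived)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{seq_id: SEQUENCE}`` map.

    Sequences are upper-cased. Duplicate IDs and non-FASTA leading content
    are rejected with the offending line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines, start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(f"{path}: line {i}: expected FASTA header, got {line.strip()!r}")
            break
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO("".join(lines)), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate sequence ID {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in seqs.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# samtools-depth-style tables

def read_depth_table(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read a 3-column (seq, 1-based position, depth) whitespace table.

    Rows with zero depth may be absent (``samtools depth`` default); callers
    that need dense profiles materialize zeros over their target interval.
    """
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(f"{path}: line {i}: expected 3 columns, got {len(fields)}")
            seq_id, pos_s, depth_s = fields
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {i}: non-integer position/depth") from exc
            if pos < 1:
                raise ParseError(f"{path}: line {i}: position must be >= 1")
            if depth < 0:
                raise ParseError(f"{path}: line {i}: negative depth")
            out.append((seq_id, pos, depth))
    return out


def write_depth_table(rows: list[tuple[str, int, int]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for seq_id, pos, depth in rows:
            fh.write(f"{seq_id}\t{pos}\t{depth}\n")


# ---------------------------------------------------------------------------
# BED <-> internal coordinates

def bed_to_internal(bed_line: str) -> GenomicInterval:
    """Convert a BED3+ line (0-based half-open) to a 1-based inclusive interval."""
    fields = bed_line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ParseError(f"BED line needs >= 3 columns: {bed_line!r}")
    chrom, start_s, end_s = fields[0], fields[1], fields[2]
    start, end = int(start_s), int(end_s)
    if start < 0:
        raise ParseError(f"BED start must be >= 0: {bed_line!r}")
    if end <= start:
        raise ParseError(f"BED end must exceed start: {bed_line!r}")
    strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
    return GenomicInterval(chrom, start + 1, end, strand)


def internal_to_bed(interval: GenomicInterval, name: str = ".", score: float = 0) -> str:
    """Render a 1-based inclusive interval as a BED6 line."""
    return "\t".join(
        [
            interval.seq_id,
            str(interval.start - 1),
            str(interval.end),
            name,
            str(score),
            interval.strand if interval.strand != "." else ".",
        ]
    )


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                out.append(bed_to_internal(line))
    return out


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene features from GFF3; gene_id comes from the ID attribute.

    Ordinals rank genes by start coordinate within each sequence.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: list[tuple[str, int, int, str, str]] = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        raw.append((feat.seqid, feat.start, feat.end, feat.strand, gene_id))
    genes: list[GeneModel] = []
    by_seq: dict[str, int] = {}
    for seqid, start, end, strand, gene_id in sorted(raw):
        ordinal = by_seq.get(seqid, 0)
        by_seq[seqid] = ordinal + 1
        genes.append(
            GeneModel(gene_id, GenomicInterval(seqid, start, end, strand), strand, ordinal)
        )
    return genes


def write_gff3_genes(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.seq_id}\tmitescan\tgene\t{iv.start}\t{iv.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BLAST outfmt-6 tables

def read_outfmt6(path: str | os.PathLike) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 12:
        raise ParseError(f"{path}: expected 12 columns, got {df.shape[1]}")
    df.columns = OUTFMT6_COLUMNS
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AlignmentRecord(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                pct_identity=float(row.pident),
                aln_length=int(row.length),
                mismatches=int(row.mismatch),
                gap_opens=int(row.gapopen),
                q_start=int(row.qstart),
                q_end=int(row.qend),
                s_start=int(row.sstart),
                s_end=int(row.send),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
            )
        )
    return records


def write_outfmt6(records: list[AlignmentRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.subject_id, f"{r.pct_identity:.3f}",
                        r.aln_length, r.mismatches, r.gap_opens,
                        r.q_start, r.q_end, r.s_start, r.s_end,
                        f"{r.evalue:.2g}", f"{r.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TPM matrices

def read_tpm_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x tissues TPM matrix (TSV, first column = gene ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene IDs: {dupes}")
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative TPM values")
    return df.astype(float)


def write_tpm_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
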