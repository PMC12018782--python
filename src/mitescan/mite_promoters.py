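"""MITE-to-promoter annotation.

Alignment records of a MITE library against a genome are filtered by the
identity/gap rules (identity strictly above 98%, gapped bases strictly below
5), strand-aware 2000-bp upstream promoter windows are derived from gene
models, and filtered hits are assigned to the windows either by any overlap
(default) or by full containment.

A naive ungapped scanner (`locate_mites_naive`) lets the synthetic test loop
run without an external aligner; production runs ingest blastn outfmt-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .io_formats import AlignmentRecord, GeneModel, GenomicInterval

__all__ = [
    "MiteHit",
    "PromoterRegion",
    "PromoterInsertion",
    "filter_alignments",
    "promoter_of",
    "assign_mites_to_promoters",
    "locate_mites_naive",
    "DEFAULT_PROMOTER_LENGTH",
    "IDENTITY_MIN",
    "GAP_MAX",
]

DEFAULT_PROMOTER_LENGTH = 2000
IDENTITY_MIN = 98.0  # strict: kept iff pct_identity > 98
GAP_MAX = 5          # strict: kept iff gaps < 5


@dataclass(frozen=True)
class MiteHit:
    """A filtered MITE alignment, subject coordinates normalized start <= end."""

    mite_id: str
    location: GenomicInterval
    pct_identity: float
    gap_bases: int
    orientation: str  # + or -


@dataclass(frozen=True)
class PromoterRegion:
    """The upstream window of one gene; None window = entirely off-sequence."""

    gene_id: str
    window: GenomicInterval | None
    truncated: bool


@dataclass(frozen=True)
class PromoterInsertion:
    gene_id: str
    mite_id: str
    overlap_bp: int
    contained: bool


def filter_alignments(
    records: list[AlignmentRecord],
    min_identity: float = IDENTITY_MIN,
    max_gap: int = GAP_MAX,
    gap_field: str = "gap_bases",
) -> list[MiteHit]:
    """Keep alignments with identity > min_identity and gaps < max_gap.

    Both comparisons are strict. ``gap_field`` selects whether the gap rule
    reads gapped bases (default) or gap opens. Order-preserving.
    """
    if gap_field not in {"gap_bases", "gap_opens"}:
        raise ValueError(f"gap_field must be gap_bases or gap_opens, got {gap_field!r}")
    hits = []
    for r in records:
        gaps = r.gap_bases if gap_field == "gap_bases" else r.gap_opens
        if r.pct_identity > min_identity and gaps < max_gap:
            orientation = "+" if r.s_start <= r.s_end else "-"
            lo, hi = min(r.s_start, r.s_end), max(r.s_start, r.s_end)
            hits.append(
                MiteHit(
                    mite_id=r.query_id,
                    location=GenomicInterval(r.subject_id, lo, hi, orientation),
                    pct_identity=r.pct_identity,
                    gap_bases=r.gap_bases,
                    orientation=orientation,
                )
            )
    return hits


def promoter_of(
    gene: GeneModel,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    seq_length: int | None = None,
) -> PromoterRegion:
    """Strand-aware upstream window abutting the gene's 5' boundary.

    A + strand gene starting at s gets [s - L, s - 1]; a - strand gene ending
    at e gets [e + 1, e + L]. Windows are clipped at sequence bounds and
    flagged truncated; a window falling entirely off-sequence is None.
    """
    iv = gene.interval
    if gene.strand == "+":
        lo, hi = iv.start - promoter_length, iv.start - 1
    else:
        lo, hi = iv.end + 1, iv.end + promoter_length
    clipped_lo = max(1, lo)
    clipped_hi = min(hi, seq_length) if seq_length is not None else hi
    if clipped_hi < clipped_lo:
        return PromoterRegion(gene.gene_id, None, True)
    truncated = (clipped_lo != lo) or (clipped_hi != hi)
    return PromoterRegion(
        gene.gene_id,
        GenomicInterval(iv.seq_id, clipped_lo, clipped_hi, gene.strand),
        truncated,
    )


def assign_mites_to_promoters(
    hits: list[MiteHit],
    promoters: list[PromoterRegion],
    mode: str = "overlap",
) -> list[PromoterInsertion]:
    """Assign hits to promoter windows.

    ``overlap`` emits a record for any hit sharing >= 1 bp with a window;
    ``containment`` requires the hit wholly inside the window. Multiple hits
    of the same MITE in one promoter collapse to a single record (typing
    downstream is presence/absence); different MITEs stay separate.
    """
    if mode not in {"overlap", "containment"}:
        raise ValueError(f"mode must be overlap or containment, got {mode!r}")
    trees: dict[str, IntervalTree] = {}
    regions: dict[int, PromoterRegion] = {}
    for idx, prom in enumerate(promoters):
        if prom.window is None:
            continue
        w = prom.window
        trees.setdefault(w.seq_id, IntervalTree()).addi(w.start, w.end + 1, idx)
        regions[idx] = prom
    best: dict[tuple[str, str], PromoterInsertion] = {}
    for hit in hits:
        tree = trees.get(hit.location.seq_id)
        if tree is None:
            continue
        for node in sorted(tree.overlap(hit.location.start, hit.location.end + 1)):
            prom = regions[node.data]
            overlap = prom.window.overlap(hit.location)
            contained = prom.window.contains(hit.location)
            if mode == "containment" and not contained:
                continue
            key = (prom.gene_id, hit.mite_id)
            prev = best.get(key)
            if prev is None or overlap > prev.overlap_bp:
                best[key] = PromoterInsertion(prom.gene_id, hit.mite_id, overlap, contained)
    return sorted(best.values(), key=lambda p: (p.gene_id, p.mite_id))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def locate_mites_naive(
    mite_library: dict[str, str],
    genome: dict[str, str],
    max_divergence: float = 0.02,
) -> list[AlignmentRecord]:
    """Ungapped sliding-window scan of a MITE library against a genome.

    Reports every genome window (both strands) whose Hamming divergence from
    a library element is <= max_divergence, as pseudo-alignment records with
    zero gap fields. Windows with > 10% N are skipped. Intended for small
    synthetic genomes; quadratic in genome x element length.
    """
    records: list[AlignmentRecord] = []
    for seq_id, seq in genome.items():
        g = _encode(seq.upper())
        n_mask = (g == ord("N")).astype(np.int32)
        n_cum = np.concatenate([[0], np.cumsum(n_mask)])
        for mite_id, mite_seq in mite_library.items():
            L = len(mite_seq)
            if L == 0 or L > len(seq):
                continue
            n_windows = len(seq) - L + 1
            max_mm = int(np.floor(max_divergence * L))
            for strand, query in (("+", mite_seq.upper()), ("-", revcomp(mite_seq.upper()))):
                m = _encode(query)
                mism = np.zeros(n_windows, dtype=np.int32)
                for j in range(L):
                    mism += g[j:j + n_windows] != m[j]
                n_in_window = n_cum[L:] - n_cum[:-L]
                ok = (mism <= max_mm) & (n_in_window <= 0.10 * L)
                for i in np.flatnonzero(ok):
                    k = int(mism[i])
                    pident = 100.0 * (L - k) / L
                    s_start, s_end = int(i + 1), int(i + L)
                    if strand == "-":
                        s_start, s_end = s_end, s_start
                    records.append(
                        AlignmentRecord(
                            query_id=mite_id,
                            subject_id=seq_id,
                            pct_identity=pident,
                            aln_length=L,
                            mismatches=k,
                            gap_opens=0,
                            q_start=1,
                            q_end=L,
                            s_start=s_start,
                            s_end=s_end,
                            evalue=0.0,
                            bitscore=float(2 * (L - k)),
                            gap_bases=0,
                        )
                    )
    return records
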