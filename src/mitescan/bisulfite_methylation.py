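"""Clone-based bisulfite methylation calling over an amplified fragment.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T
after PCR) while methylated cytosines stay C. Comparing each sequenced
clone to the untreated reference fragment therefore calls methylation at
every reference cytosine: clone C = methylated, clone T = unmethylated.
Contexts are assigned from the reference alone — CG, CHG, CHH with
H in {A, C, T} — and mC% is the fraction of methylated calls per context
(and over all cytosines). Analysis is forward-strand: clone-BS-PCR
interrogates the amplified strand only; a reverse-complement mode covers
bottom-strand amplicons.

Rules needed for reproducible denominators: cytosines with fewer than two
downstream reference bases ("edge") are excluded everywhere; a clone base
other than C/T at a reference C is an anomaly (cloning/sequencing error),
excluded from numerator and denominator and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy import stats

__all__ = [
    "CytosineCall",
    "CloneCallResult",
    "MethylationSummary",
    "TissueComparison",
    "classify_context",
    "call_clone",
    "summarize_replicate",
    "compare_tissues",
    "CONTEXTS",
]

CONTEXTS = ("CG", "CHG", "CHH")
_H = {"A", "C", "T"}


@dataclass(frozen=True)
class CytosineCall:
    position: int  # 1-based offset in the reference fragment
    context: str   # CG | CHG | CHH
    clone_id: str
    methylated: bool


@dataclass(frozen=True)
class CloneCallResult:
    clone_id: str
    calls: tuple[CytosineCall, ...]
    n_anomalies: int


@dataclass(frozen=True)
class MethylationSummary:
    fragment_id: str
    replicate_id: str
    context: str  # CG | CHG | CHH | all
    n_sites: int
    n_methylated: int

    @property
    def mc_percent(self) -> float:
        return 100.0 * self.n_methylated / self.n_sites if self.n_sites else float("nan")


@dataclass(frozen=True)
class TissueComparison:
    context: str
    mean_a: float
    mean_b: float
    difference: float
    t_statistic: float
    p_value: float
    degenerate: bool


def classify_context(reference: str, position: int) -> str:
    """Context of the cytosine at 1-based ``position`` of the reference.

    CG if the next base is G; CHG if C-H-G; CHH if C-H-H (H = A, C or T);
    ``edge`` when fewer than two downstream bases remain or a downstream
    base is not A/C/G/T.
    """
    ref = reference.upper()
    if not 1 <= position <= len(ref):
        raise ValueError(f"position {position} outside fragment of length {len(ref)}")
    if ref[position - 1] != "C":
        raise ValueError(f"reference base at position {position} is {ref[position - 1]}, not C")
    if position + 2 > len(ref):
        return "edge"  # fewer than two downstream bases: context undefined
    nxt = ref[position]
    nxt2 = ref[position + 1]
    if nxt == "G":
        return "CG"
    if nxt in _H and nxt2 == "G":
        return "CHG"
    if nxt in _H and nxt2 in _H:
        return "CHH"
    return "edge"


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _align(clone: str, reference: str) -> tuple[str, str]:
    """Global alignment; returns gapped (clone, reference) strings."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = 0
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(clone, reference)[0]
    return str(aln[0]), str(aln[1])


def call_clone(
    clone_sequence: str,
    reference: str,
    clone_id: str = "clone",
    min_backbone_identity: float = 0.80,
    bottom_strand: bool = False,
) -> CloneCallResult:
    """Call methylation at every non-edge reference cytosine of one clone.

    Equal-length clones are compared position-wise; otherwise a global
    alignment is applied and reference cytosines aligned to a gap are
    skipped. Clones whose identity at non-C reference positions (the
    bisulfite-invariant backbone) falls below ``min_backbone_identity``
    are rejected as mis-cloned.
    """
    ref = reference.upper()
    clone = clone_sequence.upper()
    if bottom_strand:
        clone = _revcomp(clone)
    if len(clone) == len(ref):
        clone_g, ref_g = clone, ref
    else:
        clone_g, ref_g = _align(clone, ref)
    # identity over bisulfite-invariant (non-C) reference positions
    backbone = [(c, r) for c, r in zip(clone_g, ref_g) if r not in ("C", "-")]
    if backbone:
        ident = sum(c == r for c, r in backbone) / len(backbone)
        if ident < min_backbone_identity:
            raise ValueError(
                f"{clone_id}: backbone identity {ident:.2f} below "
                f"{min_backbone_identity:.2f}; clone rejected as mis-cloned"
            )
    calls: list[CytosineCall] = []
    n_anomalies = 0
    ref_pos = 0
    for c_base, r_base in zip(clone_g, ref_g):
        if r_base != "-":
            ref_pos += 1
        if r_base != "C":
            continue
        if classify_context(ref, ref_pos) == "edge":
            continue
        if c_base == "-":
            continue  # gapped C positions carry no call
        if c_base == "C":
            calls.append(CytosineCall(ref_pos, classify_context(ref, ref_pos), clone_id, True))
        elif c_base == "T":
            calls.append(CytosineCall(ref_pos, classify_context(ref, ref_pos), clone_id, False))
        else:
            n_anomalies += 1
    return CloneCallResult(clone_id, tuple(calls), n_anomalies)


def summarize_replicate(
    results: list[CloneCallResult],
    fragment_id: str = "fragment",
    replicate_id: str = "rep1",
) -> list[MethylationSummary]:
    """Per-context and all-cytosine mC% for one replicate's clone set."""
    calls = [c for r in results for c in r.calls]
    if not calls:
        raise ValueError("no cytosine calls to summarize")
    out = []
    for context in CONTEXTS:
        sub = [c for c in calls if c.context == context]
        out.append(
            MethylationSummary(
                fragment_id, replicate_id, context,
                len(sub), sum(c.methylated for c in sub),
            )
        )
    out.append(
        MethylationSummary(
            fragment_id, replicate_id, "all",
            len(calls), sum(c.methylated for c in calls),
        )
    )
    return out


def position_profile(results: list[CloneCallResult]) -> dict[int, tuple[str, float]]:
    """Per-position (context, fraction methylated) across clones."""
    agg: dict[int, list[CytosineCall]] = {}
    for r in results:
        for c in r.calls:
            agg.setdefault(c.position, []).append(c)
    return {
        pos: (calls[0].context, float(np.mean([c.methylated for c in calls])))
        for pos, calls in sorted(agg.items())
    }


def compare_tissues(
    summaries_a: list[list[MethylationSummary]],
    summaries_b: list[list[MethylationSummary]],
) -> list[TissueComparison]:
    """Pooled-variance two-tailed Student's t on replicate-level mC%.

    Each argument is a list of replicate summary lists (>= 2 per side).
    Identical replicate vectors compare at p = 1; a nonzero mean difference
    with zero within-group variance is reported degenerate with p = 0.
    """
    if len(summaries_a) < 2 or len(summaries_b) < 2:
        raise ValueError("need >= 2 replicates on each side")

    def per_context(replicates: list[list[MethylationSummary]], context: str) -> np.ndarray:
        vals = []
        for rep in replicates:
            matching = [s for s in rep if s.context == context]
            if not matching:
                raise ValueError(f"replicate missing context {context}")
            vals.append(matching[0].mc_percent)
        return np.asarray(vals, dtype=float)

    out = []
    for context in (*CONTEXTS, "all"):
        a = per_context(summaries_a, context)
        b = per_context(summaries_b, context)
        diff = float(b.mean() - a.mean())
        pooled_var = float(a.var(ddof=1) + b.var(ddof=1))
        if pooled_var == 0.0:
            if diff == 0.0:
                out.append(TissueComparison(context, float(a.mean()), float(b.mean()),
                                            0.0, 0.0, 1.0, False))
            else:
                out.append(TissueComparison(context, float(a.mean()), float(b.mean()),
                                            diff, float("inf"), 0.0, True))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        out.append(TissueComparison(context, float(a.mean()), float(b.mean()),
                                    diff, float(t), float(p), False))
    return out
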