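"""Homolog-pair insertion typing and the expression-variation statistic.

Each synteny-derived homolog pair is typed by promoter-MITE presence:
``single`` (exactly one gene carries an insertion), ``none`` (neither;
negative control) or ``both`` (both; positive control). Per tissue, the
pair's expression divergence is (max - min) / max of the two TPM values,
a scale-invariant statistic in [0, 1]; pairs where both TPMs are zero are
excluded. Distributions per type are summarized as Tukey boxplots
(1.5 x IQR whiskers) with descriptive Wilcoxon rank-sum comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synteny_homology import HomologPair

__all__ = [
    "VariationRecord",
    "BoxplotSummary",
    "type_pairs",
    "variation",
    "variation_table",
    "summarize_by_type",
]

INSERTION_TYPES = ("single", "none", "both")


@dataclass(frozen=True)
class VariationRecord:
    pair: HomologPair
    tissue: str
    tpm_a: float
    tpm_b: float
    variation: float | None  # None = excluded (both TPMs zero)

    @property
    def excluded(self) -> bool:
        return self.variation is None


@dataclass(frozen=True)
class BoxplotSummary:
    insertion_type: str
    tissue: str
    n: int
    q1: float | None
    median: float | None
    q3: float | None
    whisker_low: float | None
    whisker_high: float | None
    outliers: tuple[float, ...] = ()


def type_pairs(
    pairs: list[HomologPair],
    inserted_genes: set[str],
    universe: set[str],
) -> list[HomologPair]:
    """Attach insertion_type to each pair from promoter-insertion presence.

    ``inserted_genes`` holds genes with >= 1 promoter MITE; ``universe`` is
    the set of genes the annotation covered — a pair gene outside it is an
    error (absence of evidence, not evidence of absence).
    """
    missing = sorted(
        {g for p in pairs for g in (p.gene_a, p.gene_b) if g not in universe}
    )
    if missing:
        raise ValueError(f"genes absent from annotation universe: {missing}")
    typed = []
    for p in pairs:
        a_in = p.gene_a in inserted_genes
        b_in = p.gene_b in inserted_genes
        itype = "both" if (a_in and b_in) else ("single" if (a_in or b_in) else "none")
        typed.append(
            HomologPair(p.gene_a, p.gene_b, p.block_id, itype, p.multi_block)
        )
    return typed


def variation(tpm_a: float, tpm_b: float) -> float | None:
    """(max - min) / max of a homolog pair's TPMs; None when both are zero."""
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError(f"TPM values must be non-negative: {tpm_a}, {tpm_b}")
    hi = max(tpm_a, tpm_b)
    if hi == 0:
        return None
    return (hi - min(tpm_a, tpm_b)) / hi


def variation_table(
    typed_pairs: list[HomologPair],
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
) -> list[VariationRecord]:
    """One VariationRecord per (pair, tissue). Tissue sets must match."""
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValueError(
            f"tissue sets differ: {list(matrix_a.columns)} vs {list(matrix_b.columns)}"
        )
    missing_a = sorted({p.gene_a for p in typed_pairs} - set(matrix_a.index))
    missing_b = sorted({p.gene_b for p in typed_pairs} - set(matrix_b.index))
    if missing_a or missing_b:
        raise ValueError(f"pair genes missing from matrices: {missing_a + missing_b}")
    records = []
    for p in typed_pairs:
        for tissue in matrix_a.columns:
            a = float(matrix_a.at[p.gene_a, tissue])
            b = float(matrix_b.at[p.gene_b, tissue])
            records.append(VariationRecord(p, tissue, a, b, variation(a, b)))
    return records


def _tukey(values: np.ndarray) -> tuple[float, float, float, float, float, tuple[float, ...]]:
    # linear-interpolation ("type 7") quartiles; whiskers at the most
    # extreme data points within 1.5 x IQR of the quartiles
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = tuple(sorted(values[(values < lo_fence) | (values > hi_fence)]))
    return float(q1), float(med), float(q3), float(inside.min()), float(inside.max()), outliers


def summarize_by_type(
    records: list[VariationRecord],
    per_tissue: bool = False,
) -> tuple[list[BoxplotSummary], dict[str, float]]:
    """Boxplot summaries per insertion type (pooled over tissues by default)
    plus descriptive rank-sum p-values for single-vs-none and single-vs-both.
    """
    valid = [r for r in records if not r.excluded]
    groups: dict[tuple[str, str], list[float]] = {}
    for r in valid:
        itype = r.pair.insertion_type or "untyped"
        tissue = r.tissue if per_tissue else "all"
        groups.setdefault((itype, tissue), []).append(r.variation)
    tissues = sorted({t for _, t in groups}) or ["all"]
    summaries = []
    for itype in INSERTION_TYPES:
        for tissue in tissues:
            vals = np.asarray(groups.get((itype, tissue), []), dtype=float)
            if vals.size == 0:
                summaries.append(BoxplotSummary(itype, tissue, 0, None, None, None, None, None))
                continue
            q1, med, q3, wlo, whi, out = _tukey(vals)
            summaries.append(BoxplotSummary(itype, tissue, vals.size, q1, med, q3, wlo, whi, out))
    pooled: dict[str, list[float]] = {}
    for r in valid:
        pooled.setdefault(r.pair.insertion_type or "untyped", []).append(r.variation)
    pvalues: dict[str, float] = {}
    for other in ("none", "both"):
        a, b = pooled.get("single", []), pooled.get(other, [])
        if a and b:
            pvalues[f"single_vs_{other}"] = float(stats.ranksums(a, b).pvalue)
        else:
            pvalues[f"single_vs_{other}"] = math.nan
    return summaries, pvalues


def records_to_frame(records: list[VariationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [r.pair.gene_a for r in records],
            "gene_b": [r.pair.gene_b for r in records],
            "block_id": [r.pair.block_id for r in records],
            "insertion_type": [r.pair.insertion_type for r in records],
            "tissue": [r.tissue for r in records],
            "tpm_a": [r.tpm_a for r in records],
            "tpm_b": [r.tpm_b for r in records],
            "variation": [r.variation for r in records],
            "excluded": [r.excluded for r in records],
        }
    )
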