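"""Collinear-block detection by anchor chaining.

Homolog anchor pairs (gene-by-gene orthology calls carrying ordinal gene
ranks on each genome) are chained into synteny blocks: maximal chains that
are strictly monotone in both ordinal coordinates — increasing/increasing
(forward) or increasing/decreasing (reverse) — with consecutive-anchor
ordinal gaps bounded on both genomes. Chains are extracted greedily longest
first by longest-increasing-subsequence dynamic programming; blocks smaller
than 30 anchor pairs are filtered out before any expression comparison.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "HomologPair",
    "chain_anchors",
    "filter_blocks",
    "pairs_from_blocks",
    "read_anchor_tsv",
    "write_blocks_tsv",
    "MIN_BLOCK_SIZE",
    "DEFAULT_MAX_ORDINAL_GAP",
]

MIN_BLOCK_SIZE = 30
DEFAULT_MAX_ORDINAL_GAP = 25


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    ord_a: int
    ord_b: int
    seqpair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.ord_a < 0 or self.ord_b < 0:
            raise ValueError("ordinals must be non-negative")


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: str
    anchors: tuple[Anchor, ...]
    orientation: str  # forward | reverse

    @property
    def size(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class HomologPair:
    """A synteny-derived homologous gene pair, later typed by promoter-MITE status."""

    gene_a: str
    gene_b: str
    block_id: str
    insertion_type: str | None = None  # single | none | both
    multi_block: bool = False


def _best_chain(anchors: list[Anchor], orientation: str, max_gap: int) -> list[Anchor]:
    """Longest strictly-monotone chain under the gap bound, deterministic.

    Anchors are processed sorted by (ord_a, ord_b); predecessors and the
    chain end are chosen earliest-in-sort-order among maximal, so equal
    length ties resolve to the lexicographically earliest chain.
    """
    sign = 1 if orientation == "forward" else -1
    items = sorted(anchors, key=lambda a: (a.ord_a, sign * a.ord_b))
    n = len(items)
    dp = [1] * n
    prev = [-1] * n
    for i in range(n):
        ai = items[i]
        for j in range(i):
            aj = items[j]
            if aj.ord_a >= ai.ord_a:
                continue
            if ai.ord_a - aj.ord_a > max_gap:
                continue
            db = sign * (ai.ord_b - aj.ord_b)
            if db <= 0 or db > max_gap:
                continue
            if dp[j] + 1 > dp[i]:
                dp[i] = dp[j] + 1
                prev[i] = j
    best = max(range(n), key=lambda i: (dp[i], -i))  # earliest maximal end
    chain = []
    i = best
    while i != -1:
        chain.append(items[i])
        i = prev[i]
    return chain[::-1]


def chain_anchors(
    anchors: list[Anchor],
    max_ordinal_gap: int = DEFAULT_MAX_ORDINAL_GAP,
) -> list[SyntenyBlock]:
    """Iteratively extract monotone chains of length >= 2 per sequence pair.

    Blocks are anchor-disjoint; forward is preferred over reverse at equal
    length. Pre-filter output — apply `filter_blocks` for the size rule.
    """
    if len({(a.gene_a, a.gene_b) for a in anchors}) != len(anchors):
        raise ValueError("anchors must be deduplicated per (gene_a, gene_b)")
    by_seqpair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_seqpair.setdefault(a.seqpair, []).append(a)
    blocks: list[SyntenyBlock] = []
    counter = 0
    for seqpair in sorted(by_seqpair):
        remaining = by_seqpair[seqpair]
        while len(remaining) >= 2:
            fwd = _best_chain(remaining, "forward", max_ordinal_gap)
            rev = _best_chain(remaining, "reverse", max_ordinal_gap)
            chain, orientation = (fwd, "forward") if len(fwd) >= len(rev) else (rev, "reverse")
            if len(chain) < 2:
                break
            counter += 1
            blocks.append(SyntenyBlock(f"block_{counter}", tuple(chain), orientation))
            used = {(a.gene_a, a.gene_b) for a in chain}
            remaining = [a for a in remaining if (a.gene_a, a.gene_b) not in used]
    return blocks


def validate_block(block: SyntenyBlock, max_ordinal_gap: int | None = None) -> None:
    """Raise if a block violates double monotonicity or the gap bound."""
    sign = 1 if block.orientation == "forward" else -1
    for prev_a, cur in zip(block.anchors, block.anchors[1:]):
        da = cur.ord_a - prev_a.ord_a
        db = sign * (cur.ord_b - prev_a.ord_b)
        if da <= 0 or db <= 0:
            raise ValueError(f"{block.block_id}: monotonicity violated")
        if max_ordinal_gap is not None and (da > max_ordinal_gap or db > max_ordinal_gap):
            raise ValueError(f"{block.block_id}: ordinal gap exceeds {max_ordinal_gap}")


def filter_blocks(blocks: list[SyntenyBlock], min_size: int = MIN_BLOCK_SIZE) -> list[SyntenyBlock]:
    """Drop blocks with fewer than min_size anchor pairs (default 30)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [b for b in blocks if b.size >= min_size]


def pairs_from_blocks(blocks: list[SyntenyBlock]) -> list[HomologPair]:
    """One homolog pair per anchor; genes in several blocks are flagged."""
    gene_blocks: dict[str, set[str]] = {}
    for b in blocks:
        for a in b.anchors:
            gene_blocks.setdefault(a.gene_a, set()).add(b.block_id)
            gene_blocks.setdefault(a.gene_b, set()).add(b.block_id)
    pairs = []
    for b in blocks:
        for a in b.anchors:
            multi = len(gene_blocks[a.gene_a]) > 1 or len(gene_blocks[a.gene_b]) > 1
            pairs.append(HomologPair(a.gene_a, a.gene_b, b.block_id, multi_block=multi))
    return pairs


def read_anchor_tsv(path: str | os.PathLike) -> list[Anchor]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene_a", "gene_b", "seq_a", "seq_b", "ord_a", "ord_b"],
    )
    return [
        Anchor(r.gene_a, r.gene_b, int(r.ord_a), int(r.ord_b), (r.seq_a, r.seq_b))
        for r in df.itertuples(index=False)
    ]


def write_blocks_tsv(blocks: list[SyntenyBlock], path: str | os.PathLike) -> None:
    rows = []
    for b in blocks:
        for a in b.anchors:
            rows.append(
                (b.block_id, b.orientation, a.gene_a, a.gene_b,
                 a.seqpair[0], a.seqpair[1], a.ord_a, a.ord_b)
            )
    pd.DataFrame(
        rows,
        columns=["block_id", "orientation", "gene_a", "gene_b",
                 "seq_a", "seq_b", "ord_a", "ord_b"],
    ).to_csv(path, sep="\t", index=False)
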