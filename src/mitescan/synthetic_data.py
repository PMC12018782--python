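"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed seed (numpy PCG64) and emits
a machine-readable truth table, so each downstream module has a recovery
test with no external downloads:

- depth profiles whose breadth-of-coverage falls in the negative/partial/
  full bands with a safety margin from the 0.3/0.75 boundaries;
- a toy genome with MITE copies planted in a subset of 2-kb promoter
  windows at controlled divergence, straddling the 98%-identity filter;
- TPM matrices in which the insertion-carrying homolog of single-insertion
  pairs is transcriptionally suppressed before multiplicative lognormal
  noise;
- bisulfite clone sets drawn per-cytosine from tissue- and context-specific
  methylation probabilities (leaf-like CHH ~ 27%, pollen-like CHH ~ 2%);
- anchor lists with planted collinear blocks plus uniform noise anchors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bisulfite_methylation import classify_context
from .io_formats import GeneModel, GenomicInterval
from .mite_promoters import revcomp
from .synteny_homology import Anchor

__all__ = [
    "SimulationConfig",
    "gen_depth_profiles",
    "gen_genome_with_mites",
    "gen_expression",
    "gen_bisulfite_clones",
    "gen_anchor_pairs",
    "DEFAULT_METH_PROFILE",
]

# Per-context methylation probabilities per tissue label. CHH follows the
# leaf/pollen contrast of the amplified Sli-promoter fragment (leaf ~27%,
# pollen ~2%); CG and CHG do not differ significantly between the tissues,
# so both share typical somatic plant levels.
DEFAULT_METH_PROFILE: dict[str, dict[str, float]] = {
    "leaf": {"CG": 0.85, "CHG": 0.55, "CHH": 0.27},
    "pollen": {"CG": 0.85, "CHG": 0.55, "CHH": 0.02},
}

DEFAULT_TISSUES = ("root", "stem", "leaf", "stolon", "tuber")


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knob set for all generators; defaults mirror the study design."""

    seed: int = 0
    # coverage screen
    n_accessions: int = 200
    class_proportions: tuple[float, float, float] = (0.6, 0.25, 0.15)  # neg, part, full
    cv_band_margins: float = 0.05
    target_interval: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr12_2", 64_820_556, 64_821_104)
    )
    mean_depth: float = 20.0
    partial_speckle: bool = False
    # genome / promoter annotation
    n_genes: int = 25
    n_mites_in_promoters: int = 10
    mite_pass_fraction: float = 0.8
    divergence_pass: float = 0.01
    divergence_fail: float = 0.04
    gene_length: int = 1000
    intergenic_length: int = 2500
    promoter_length: int = 2000
    # expression
    pairs_per_type: int = 300
    suppression_effect: float = 0.3
    tpm_noise_sd: float = 0.2
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    # methylation
    meth_profile: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_METH_PROFILE.items()}
    )
    clones_per_replicate: int = 15
    replicates: int = 3
    non_conversion_rate: float = 0.0
    # synteny
    block_sizes: tuple[int, ...] = (40, 33, 29)
    n_noise_anchors: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        for tissue, probs in self.meth_profile.items():
            for ctx, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"meth_profile[{tissue}][{ctx}] out of [0, 1]")
        if not 0.0 <= self.mite_pass_fraction <= 1.0:
            raise ValueError("mite_pass_fraction must be in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# coverage screen inputs

_CLASS_NAMES = ("negative", "partial", "full")


def _cv_band(cls: str, margin: float) -> tuple[float, float]:
    lo, hi = {"negative": (0.0, 0.3), "partial": (0.3, 0.75), "full": (0.75, 1.0)}[cls]
    band = (lo + margin if lo > 0 else 0.0, hi - margin if hi < 1 else 1.0)
    if band[1] <= band[0]:
        raise ValueError(f"cv_band_margins {margin} leaves no room in the {cls} band")
    return band


def gen_depth_profiles(
    config: SimulationConfig,
) -> tuple[dict[str, list[tuple[str, int, int]]], pd.DataFrame]:
    """Per-accession sparse depth tables plus a truth table of classes.

    Coverage is realized as a contiguous covered run (prefix or suffix of
    the element, emulating a truncated insertion) unless partial_speckle is
    set, in which case covered positions are scattered. The realized CV is
    exact: exactly round(cv * L) positions carry depth >= 1.
    """
    rng = np.random.default_rng(config.seed)
    L = config.target_interval.length
    for cls in _CLASS_NAMES:
        _cv_band(cls, config.cv_band_margins)  # validate margins up front
    n = config.n_accessions
    classes = rng.choice(3, size=n, p=np.asarray(config.class_proportions))
    tables: dict[str, list[tuple[str, int, int]]] = {}
    truth_rows = []
    for i in range(n):
        accession = f"ACC{i:04d}"
        cls = _CLASS_NAMES[classes[i]]
        lo, hi = _cv_band(cls, config.cv_band_margins)
        target_cv = rng.uniform(lo, hi)
        k = int(round(target_cv * L))
        # keep the integer-realized CV inside the band
        while k / L < lo:
            k += 1
        while k / L > hi:
            k -= 1
        if config.partial_speckle and cls == "partial":
            covered = np.sort(rng.choice(L, size=k, replace=False))
        elif rng.random() < 0.5:
            covered = np.arange(k)
        else:
            covered = np.arange(L - k, L)
        rows = []
        if k:
            depths = rng.poisson(config.mean_depth, size=k) + 1
            start = config.target_interval.start
            seq_id = config.target_interval.seq_id
            rows = [(seq_id, int(start + pos), int(d)) for pos, d in zip(covered, depths)]
        tables[accession] = rows
        truth_rows.append((accession, cls, k / L))
    truth = pd.DataFrame(truth_rows, columns=["accession_id", "class", "cv"])
    return tables, truth


# ---------------------------------------------------------------------------
# toy genome with planted promoter MITEs

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _diverge(rng: np.random.Generator, seq: str, divergence: float) -> tuple[str, int]:
    """Substitute round(divergence * len) positions with different bases."""
    k = int(round(divergence * len(seq)))
    if k == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out), k


def gen_genome_with_mites(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], dict[str, str], pd.DataFrame]:
    """A single-chromosome toy genome with MITEs planted in promoters.

    Returns (genome, gene models, MITE library, truth table). Each planted
    copy sits wholly inside its gene's 2-kb upstream window; per-copy
    divergence is divergence_pass for a mite_pass_fraction of copies (these
    survive the >98%-identity filter) and divergence_fail for the rest.
    """
    if config.n_mites_in_promoters > config.n_genes:
        raise ValueError("n_mites_in_promoters must be <= n_genes")
    rng = np.random.default_rng(config.seed + 1)
    mite_consensus = _random_seq(rng, 300)
    mite_lib = {"MITE_hAT_1": mite_consensus}
    carrier_idx = set(
        rng.choice(config.n_genes, size=config.n_mites_in_promoters, replace=False).tolist()
    )
    n_pass = int(round(config.mite_pass_fraction * config.n_mites_in_promoters))
    carriers_sorted = sorted(carrier_idx)
    pass_set = set(carriers_sorted[:n_pass])  # deterministic split

    chrom = "chr1"
    parts: list[str] = []
    pos = 0  # 0-based length so far
    genes: list[GeneModel] = []
    truth_rows = []
    for gi in range(config.n_genes):
        parts.append(_random_seq(rng, config.intergenic_length))
        pos += config.intergenic_length
        # promoter window: promoter_length bp immediately upstream of the gene
        promoter = _random_seq(rng, config.promoter_length)
        if gi in carrier_idx:
            divergence = config.divergence_pass if gi in pass_set else config.divergence_fail
            copy, n_sub = _diverge(rng, mite_consensus, divergence)
            if rng.random() < 0.5:
                copy = revcomp(copy)
                orientation = "-"
            else:
                orientation = "+"
            offset = int(rng.integers(0, config.promoter_length - len(copy) + 1))
            promoter = promoter[:offset] + copy + promoter[offset + len(copy):]
            insert_start = pos + offset + 1  # 1-based on chromosome
            truth_rows.append(
                (
                    f"gene{gi:03d}", "MITE_hAT_1", insert_start,
                    insert_start + len(copy) - 1, orientation,
                    100.0 * (len(copy) - n_sub) / len(copy), gi in pass_set,
                )
            )
        parts.append(promoter)
        pos += config.promoter_length
        gene_start = pos + 1
        parts.append(_random_seq(rng, config.gene_length))
        pos += config.gene_length
        genes.append(
            GeneModel(
                f"gene{gi:03d}",
                GenomicInterval(chrom, gene_start, pos, "+"),
                "+",
                gi,
            )
        )
    genome = {chrom: "".join(parts)}
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "mite_id", "start", "end", "orientation",
                 "pct_identity", "passes_filter"],
    )
    return genome, genes, mite_lib, truth


# ---------------------------------------------------------------------------
# expression matrices

def gen_expression(
    config: SimulationConfig,
    truth_pairs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TPM matrices for the two haplotypes plus a pair truth table.

    When truth_pairs is None, pairs_per_type pairs of each insertion type
    are fabricated. For single-insertion pairs the carrier homolog's TPM is
    multiplied by suppression_effect before lognormal noise; no/both pairs
    differ only by noise.
    """
    rng = np.random.default_rng(config.seed + 2)
    if truth_pairs is None:
        rows = []
        idx = 0
        for itype in ("single", "none", "both"):
            for _ in range(config.pairs_per_type):
                rows.append((f"pa{idx:05d}", f"pb{idx:05d}", itype))
                idx += 1
        truth_pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "insertion_type"])
    tissues = list(config.tissues)
    vals_a, vals_b = [], []
    for row in truth_pairs.itertuples(index=False):
        base = float(rng.lognormal(mean=np.log(20.0), sigma=0.8))
        a_scale = config.suppression_effect if row.insertion_type == "single" else 1.0
        noise_a = rng.lognormal(mean=0.0, sigma=config.tpm_noise_sd, size=len(tissues))
        noise_b = rng.lognormal(mean=0.0, sigma=config.tpm_noise_sd, size=len(tissues))
        vals_a.append(base * a_scale * noise_a)
        vals_b.append(base * noise_b)
    matrix_a = pd.DataFrame(vals_a, index=truth_pairs.gene_a.tolist(), columns=tissues)
    matrix_b = pd.DataFrame(vals_b, index=truth_pairs.gene_b.tolist(), columns=tissues)
    return matrix_a, matrix_b, truth_pairs


# ---------------------------------------------------------------------------
# bisulfite clones

def gen_bisulfite_clones(
    config: SimulationConfig,
    reference_fragment: str,
    tissue: str,
) -> tuple[dict[str, dict[str, str]], dict[str, float]]:
    """Simulated bisulfite clone sets for one tissue.

    Returns ({replicate_id: {clone_id: sequence}}, truth probabilities).
    Each reference cytosine is independently kept as C with its context's
    probability (methylated), else written as T; non-C bases are copied.
    Edge-context cytosines draw the CHH probability (they are excluded from
    calling anyway). An optional non-conversion error keeps unmethylated
    cytosines as C at rate non_conversion_rate.
    """
    probs = config.meth_profile[tissue]
    ref = reference_fragment.upper()
    tissue_offset = zlib.crc32(tissue.encode()) % 997
    rng = np.random.default_rng(config.seed + 3 + tissue_offset)
    contexts = {
        i: classify_context(ref, i + 1)
        for i, base in enumerate(ref)
        if base == "C"
    }
    replicates: dict[str, dict[str, str]] = {}
    for r in range(1, config.replicates + 1):
        clones: dict[str, str] = {}
        for c in range(1, config.clones_per_replicate + 1):
            out = list(ref)
            for i, ctx in contexts.items():
                p = probs.get(ctx if ctx != "edge" else "CHH", 0.0)
                methylated = rng.random() < p
                if not methylated and rng.random() >= config.non_conversion_rate:
                    out[i] = "T"
            clones[f"{tissue}_r{r}_c{c:02d}"] = "".join(out)
        replicates[f"r{r}"] = clones
    return replicates, dict(probs)


# ---------------------------------------------------------------------------
# synteny anchors

def gen_anchor_pairs(config: SimulationConfig) -> tuple[list[Anchor], pd.DataFrame]:
    """Anchor list with planted collinear blocks plus scattered noise.

    Blocks of the configured sizes are planted with consecutive ordinals,
    alternating forward/reverse orientation; n_noise_anchors uniform random
    anchors are sprinkled over the whole ordinal grid. Truth records each
    anchor's block (or "noise").
    """
    rng = np.random.default_rng(config.seed + 4)
    anchors: list[Anchor] = []
    truth_rows = []
    seqpair = ("A1", "B1")
    offset_a = offset_b = 0
    counter = 0
    for bi, size in enumerate(config.block_sizes):
        orientation = "forward" if bi % 2 == 0 else "reverse"
        for k in range(size):
            ord_a = offset_a + k
            ord_b = offset_b + (k if orientation == "forward" else size - 1 - k)
            gene_a, gene_b = f"ga{counter:05d}", f"gb{counter:05d}"
            anchors.append(Anchor(gene_a, gene_b, ord_a, ord_b, seqpair))
            truth_rows.append((gene_a, gene_b, f"truth_block_{bi}", orientation))
            counter += 1
        offset_a += size + 100
        offset_b += size + 100
    grid = max(offset_a, offset_b) + 100
    seen = {(a.ord_a, a.ord_b) for a in anchors}
    made = 0
    while made < config.n_noise_anchors:
        oa, ob = int(rng.integers(0, grid)), int(rng.integers(0, grid))
        if (oa, ob) in seen:
            continue
        seen.add((oa, ob))
        gene_a, gene_b = f"na{made:05d}", f"nb{made:05d}"
        anchors.append(Anchor(gene_a, gene_b, oa, ob, seqpair))
        truth_rows.append((gene_a, gene_b, "noise", "."))
        made += 1
    truth = pd.DataFrame(truth_rows, columns=["gene_a", "gene_b", "block", "orientation"])
    return anchors, truth
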