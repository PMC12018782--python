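# Methods

## Coordinate conventions

All internal coordinates are 1-based inclusive (the convention of SAM and
GFF3); an interval's length is `end − start + 1`. This is forced by the
target element itself: chr12_2:64,820,556–64,821,104 spans 549 bp only under
inclusive arithmetic. BED's 0-based half-open convention is converted at
the I/O boundary (`bed_to_internal` / `internal_to_bed`) and nowhere else;
the converters are tested to compose to identity.

## Coverage rate genotyping

An accession's depth table (samtools-depth dialect: sequence, 1-based
position, integer depth; zero-depth rows may be omitted and are
materialized over the target interval, since the CV denominator must be the
full interval length) is densified into a `DepthProfile`. The coverage rate
value is breadth of coverage,

    CV = #{positions with depth ≥ d_min} / L,      d_min = 1 by default,

the natural reading of a "coverage rate" over a fixed window. An
alternative capped-mean formula `mean(min(depth, d_min)) / d_min` — which
coincides with breadth at d_min = 1 — is available behind a flag for users
who want partial credit for stacked reads at higher thresholds.

Classification: negative iff CV < 0.3, full iff CV > 0.75, partial on the
closed interval [0.3, 0.75]. Assigning both boundary values to partial
follows the published phrasing, which brackets the partial range inclusively
while stating negative and full as strict inequalities. Group percentages
are rounded half-up to one decimal, matching how such tables are printed.

MAPQ filtering, duplicate marking and mapping itself are upstream of this
package: depth tables are assumed to derive from reads already filtered
(e.g. MAPQ > 10).

## Promoter MITE annotation

Alignment records use the 12-column blastn `-outfmt 6` dialect. That
dialect reports gap *opens* only; gapped bases are derived as
`aln_length − round(pident·aln_length/100) − mismatches` (identity defines
the match count; remaining aligned columns are gaps), clipped at zero. The
retention filter is strict on both sides: identity > 98% and gaps < 5 bp.
Because the published rule is phrased in base pairs, the gap filter reads
gapped bases by default; a switch selects gap opens.

Promoter windows are the 2000 bp immediately upstream of the gene feature's
5′ boundary: `[s−2000, s−1]` for a + strand gene starting at s, mirrored
for − strand, clipped at sequence bounds and flagged `truncated` (a window
entirely off-sequence is empty and skipped). The gene-feature start stands
in for the start codon; GFF3 gene structure files do not always carry
usable CDS phase.

Assignment is by any ≥ 1 bp overlap by default — "located within" is
ambiguous between overlap and containment, so containment is one flag away
and both are tested. Multiple hits of one MITE in one promoter collapse to
a single insertion record, because downstream typing is presence/absence
per gene. No minimum alignment-length filter is applied by default,
mirroring the two published filters exactly; `--min-cov` exists for users.

`locate_mites_naive` is a deliberately simple ungapped Hamming scanner
(both strands, windows with > 10% N skipped) so the synthetic test loop
needs no external aligner; it is quadratic and intended for toy genomes.
Production runs ingest outfmt-6 from any aligner.

## Synteny chaining

Anchors are homologous gene pairs with ordinal ranks along each genome.
Per sequence pair, the longest chain strictly monotone in both ordinals —
increasing/increasing (forward) or increasing/decreasing (reverse), with
consecutive-anchor gaps ≤ 25 ordinals (configurable; some finite bound is
required for locality) on both genomes — is found by O(n²)
longest-increasing-subsequence dynamic programming, extracted, and the
procedure repeats until no chain of length ≥ 2 remains. This greedy
longest-first extraction is the common practice approximation rather than a
globally optimal partition; for the *single* longest chain the DP is exact,
which is what the exhaustive-search equivalence tests check (all instances
up to 12 anchors). Chains score by length only — no bitscore weighting, as
no scoring scheme is prescribed. Ties break deterministically: forward
before reverse at equal length, and within an orientation the chain
reconstructed from the earliest sorted end anchor through earliest sorted
predecessors. Blocks under 30 anchor pairs are filtered out before any
expression analysis.

## Insertion typing and expression variation

A homolog pair is *single* iff exactly one gene carries ≥ 1 promoter MITE,
*none* iff neither, *both* iff both. Genes absent from the annotation
universe raise an error rather than silently typing as uninserted. Per
tissue, variation = (max − min)/max of the pair's TPMs: symmetric,
scale-invariant, in [0, 1], equal to 1 exactly when one homolog is silent,
and excluded (not zero) when both are — since TPM ≥ 0, max = 0 is
equivalent to both values being zero.

Quartiles use linear interpolation between order statistics (numpy default,
R type 7); whiskers are the most extreme observations within 1.5×IQR of the
quartiles, outliers beyond. Records pool all (pair, tissue) combinations by
default, with a per-tissue mode. A Wilcoxon rank-sum test compares single
vs none and single vs both descriptively (the statistic is bounded and
skewed, so a rank test is more defensible than a *t*); it gates nothing.
Pairs whose genes occur in several blocks are kept once per block and
flagged, preserving auditability.

## Bisulfite methylation calling

Analysis is forward-strand: clone bisulfite PCR interrogates the amplified
strand only (a reverse-complement mode handles bottom-strand amplicons).
Contexts come from the untreated reference alone: CG, CHG, CHH with
H ∈ {A, C, T}. Two rules make mC% denominators reproducible:

- cytosines with fewer than two downstream reference bases (or an
  ambiguous downstream base) are "edge" and excluded everywhere;
- a clone base other than C/T at a reference C is an anomaly
  (cloning/sequencing error), excluded from numerator and denominator and
  counted per clone.

Clones of unequal length are globally aligned (match 2, mismatch 0, open
−4, extend −1); reference cytosines aligned to a gap yield no call. A clone
whose identity over the bisulfite-invariant backbone (non-C reference
positions) falls below 80% is rejected as mis-cloned. No non-conversion
correction is applied (none is configured by default in the simulator
either; the rate is configurable so its bias can be measured).

mC% = 100 × methylated / assayed per context and over all cytosines; the
per-context site counts sum to the all-cytosine count by construction.
Tissue contrasts use a pooled-variance two-tailed Student's *t* on
replicate-level mC% (n = 3 replicates by design). Degenerate inputs are
fixed rules, not crashes: identical replicate vectors give p = 1 and
difference 0; a nonzero difference with zero within-group variance is
flagged degenerate with p reported as 0.

## Synthetic data: what it emulates and what it does not

All generators use numpy's PCG64 with the configured seed (sub-streams are
derived by fixed offsets, plus a CRC of the tissue label for clone sets),
so outputs are byte-identical across runs and platforms. Defaults mirror
the study design: 393-accession-style screens are scaled to n = 200 with
class proportions (0.60, 0.25, 0.15) ≈ the observed negative/partial/full
mix; the 549-bp target interval at its published coordinates; 2000-bp
promoters; planted synteny blocks of sizes (40, 33, 29) so the 30-pair
filter bites; 3 replicates × 15 clones; per-context methylation
probabilities CG 0.85 / CHG 0.55 for both tissues (typical somatic plant
levels; the CG/CHG contrast between these tissues is not significant) and
CHH 0.27 (leaf-like) vs 0.02 (pollen-like), matching the reported
fragment-level contrast.

Depth profiles are generated directly as depth tables: coverage in the
intended CV band (kept `cv_band_margins` = 0.05 away from the 0.3/0.75
boundaries so integer rounding cannot flip a class) is realized as a
contiguous covered prefix or suffix of the element — a truncated insertion,
the biological reading of "partial" — with Poisson(20)+1 depths; a speckle
mode scatters covered positions instead. Read simulation and mapping are
out of scope; the modeled computation begins at depth.

The toy genome concatenates per-gene cassettes (2.5 kb intergenic, 2 kb
promoter, 1 kb gene body; 25 genes ≈ 137 kb) with one 300-bp MITE consensus
planted in 10 promoters: 80% of copies at 1% divergence (passing the > 98%
filter) and the rest at 4% (failing), both recorded in truth. Expression
matrices apply the suppression effect (default × 0.3 on the carrier homolog
of single-insertion pairs) before multiplicative lognormal noise
(sd 0.2 on the log scale), the standard positive-support noise model; 300
pairs per type across the five tissues root/stem/leaf/stolon/tuber.

What passing the recovery tests shows is internal consistency — the
pipeline recovers what the generator planted under the stated statistical
structure. Real data add everything the generators omit: mappability and
GC-coverage bias, segmental duplication cross-mapping, gapped MITE decay
and nested insertions, annotation errors, shared-count TPM ambiguity
between close homologs, bisulfite non-conversion and PCR jackpot clones.
Conclusions about real accessions still require the usual external
controls.

## Problem sizes

Tests and the acceptance script run at desk scale: 200-accession coverage
screens, a ~137-kb genome, 500 random chaining instances of ≤ 12 anchors
against exhaustive search, 20 seeds for the expression-ordering and
CHH-contrast Monte Carlo suites. The package's published-scale quantities
(genome-wide MITE counts, the 6853-pair catalogue) require full genomes and
resequencing panels and are not recomputed here; the worked-example
quantities (group percentages, screen total, element length, pair totals)
are exact at any scale.

## Known limitations

- Greedy chain extraction can split an optimal two-block partition
  suboptimally in adversarial overlap patterns; only the longest single
  chain is provably optimal.
- The naive scanner is ungapped; indel-diverged MITE copies must come from
  a real aligner's outfmt-6.
- `summarize_groups` assumes each accession belongs to exactly one group.
- Methylation calling trusts the clone-to-reference global alignment; for
  highly diverged or chimeric clones the 80% backbone-identity gate is the
  only defense.
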