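# mitescan

Miniature inverted-repeat transposable elements (MITEs) are short,
non-autonomous DNA transposons that frequently land next to genes, where
they reshape local DNA methylation and hence transcription. In diploid
potato, a 549-bp hAT-superfamily MITE in the promoter of the pollen-expressed
F-box gene *Sli* (*S-locus inhibitor*) governs self-compatibility, making its
presence/absence across germplasm — and the regulatory footprint of promoter
MITEs genome-wide — directly relevant to hybrid breeding.

`mitescan` implements the four bespoke computations such a study needs, as a
tested Python package for genomicists working with resequencing panels and
pangenome annotations:

1. **Locus coverage genotyping** (`locus_coverage`) — from per-base read
   depth over a target interval, each accession's coverage rate value
   CV = |{i : depth_i ≥ d_min}| / L (breadth of coverage) classifies it as
   *negative* (CV < 0.3), *partial* (0.3 ≤ CV ≤ 0.75) or *full* (CV > 0.75)
   for the element, with per-group count/percentage summaries.
2. **Promoter MITE annotation** (`mite_promoters`) — MITE-vs-genome
   alignments (blastn outfmt-6 or a built-in scanner) filtered at identity
   > 98% and gap < 5 bp, assigned to strand-aware 2000-bp upstream promoter
   windows.
3. **Synteny and homolog expression variation** (`synteny_homology`,
   `insertion_expression`) — anchor pairs chained into collinear blocks by
   doubly-monotone dynamic programming, blocks under 30 gene pairs dropped;
   each surviving homolog pair is typed *single*/*none*/*both* by promoter
   MITE status and scored per tissue with the expression-variation statistic
   v = (max(TPM_a, TPM_b) − min(TPM_a, TPM_b)) / max(TPM_a, TPM_b),
   excluded when both TPMs are zero.
4. **Bisulfite clone methylation** (`bisulfite_methylation`) — per-cytosine
   methylation calls of sequenced clones against a reference fragment
   (retained C = methylated, C→T = converted), context-classified as
   CG / CHG / CHH (H ∈ {A, C, T}), with per-replicate mC% and a pooled-
   variance two-tailed Student's *t* contrast between tissues.

A synthetic-data module (`synthetic_data`) generates every input — depth
tables, a toy genome with planted promoter MITEs, TPM matrices, bisulfite
clone sets, anchor lists — with machine-readable truth, so the entire
pipeline is verifiable offline.

## Worked example

```python
from mitescan.locus_coverage import CoverageCall, classify_cv, summarize_groups
from mitescan.insertion_expression import variation
from mitescan.bisulfite_methylation import call_clone, summarize_replicate

cvs = [0.0, 0.05, 0.12, 0.22, 0.31, 0.55, 0.74, 0.80, 0.92, 1.0]
calls = [CoverageCall(f"a{i}", cv, classify_cv(cv)) for i, cv in enumerate(cvs)]
group, _ = summarize_groups(calls, {c.accession_id: "demo" for c in calls})
print(group.n_negative, group.n_partial, group.n_full, group.pct_full)
# 4 3 3 30.0   <- 4 accessions lack the element, 3 truncated, 3 full copies

print(variation(12.4, 3.1))
# 0.75          <- (12.4 - 3.1) / 12.4: strong expression divergence

result = call_clone("ATGACAATCGATTTA", "ACGACAATCGATTCA", "clone1")
for s in summarize_replicate([result]):
    print(s.context, s.n_methylated, s.n_sites)
# CG 1 2  / CHG 0 0 / CHH 1 1 / all 2 3
# the clone kept C at one CG site and the CHH site (methylated) and read T
# at the other CG site (converted, i.e. unmethylated)
```

The command line mirrors the modules: `mitescan simulate`, `coverage`,
`annotate`, `synteny`, `variation`, `methylation`, and `all`, which runs a
fully simulated end-to-end analysis with a run manifest:

```bash
mitescan all --seed 7 --out-dir runs/demo
```

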