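# Methods

## Problem and model

Editing-based RBP profiling fuses an RNA-binding protein to one or two
RNA deaminases; transcripts bound by the protein accumulate C→U and A→I
edits near the binding site. The analysis must separate three sources of
sequence variants in stranded RNA-seq:

1. guided editing near true binding sites (the signal),
2. stochastic, context-biased editing by the free deaminase modules
   (present equally in the non-targeting control), and
3. genetic variation and systematic artifacts (present even in a
   deaminase-free empty control).

`rbpedit` models a site's reads as a two-allele count: `r` reference and
`e` edited reads, with third-allele reads set aside. The editing rate is
`e/(r+e)`. The choice to exclude third alleles from the denominator makes
the rate robust to sequencing error and matches per-allele chromatogram
quantification; it slightly raises rates at noisy sites relative to an
all-reads denominator.

Differential calling treats the RBP and control samples as two binomial
proportions and uses the pooled two-proportion z-score. The upstream
literature for this assay family delegates its "log-likelihood z-score"
to an external variant caller whose statistic is not printed; we use the
pooled z instead because it is closed-form, deterministic and keeps the
published thresholds interpretable on the same scale (z ≥ 4 for cultured
cells). The score function is isolated in `target_calling.z_score` so a
likelihood-ratio variant can be swapped in.

### Target predicate

A site is a target when all three hold (cultured preset; every comparison
is against pooled control counts at the same position and allele pair):

- rate ≥ `min_rate` = 0.05 (inclusive),
- rate ≥ `min_fold` × max(control rate, 1/(control coverage + 2)),
  `min_fold` = 2.0 (inclusive). The continuity floor defines fold change
  when the control has zero edited reads: fold is large but finite, and
  deeper control coverage earns a larger fold,
- z ≥ `min_z` = 4.0 (inclusive).

The in vivo preset is fold ≥ 1.5 and z > 1 *strict*, following the
different wording of the two regimes ("≥4" vs ">1"). Control coverage
below the 5-read cutoff makes a site *untestable* rather than
non-target, so low-coverage positions never count as evidence of
absence. The 5-read cutoff is applied per side: both the RBP and the
control sample must reach it.

Replicates are pooled by summing counts (the default; it maximizes
coverage at low input). A `per_replicate` mode calls each replicate
against the pooled control and reports the union with a `reproducible`
flag (target in every replicate), reproducing Venn-style replicate
intersections.

### Gene aggregation

Genes with ≥ 1 target site are target genes, categorized as
`CtoU_only`, `AtoI_only` or `both` by the edit types among their target
sites. Hyper-editing flags (≥ `hyper_min_sites` = 20 sites of one type in
a gene, the boundary inclusive at 20) are computed over *all* editing
sites of the gene, not just targets, because stochastic hyper-editing is
a property of the editing landscape rather than of differential calls.
`rank_score` is the sum of z-scores over target sites and orders the
output table.

## Motif analysis

The deaminases' residual context preference (C edited in ACH, A in WAS)
contaminates any motif analysis that includes the edited base, so flanks
exclude it: up to 50 nt ending 1 nt before and starting 1 nt after the
site, on the sense strand, truncated at contig ends. Enrichment is
DREME-style: exact k-mers (k = 4..8), window-level presence/absence, a
one-sided Fisher exact test of foreground (target-site flanks) vs
background (control-site flanks), and E-value = number of candidate
k-mers × p. Candidates are k-mers present in at least `min_fg`
foreground windows. When both flanks are tested as one unit they are
joined with a separator no k-mer can span, preserving the exclusion. The
one-sided Fisher p equals the hypergeometric upper tail with fixed
margins and is computed vectorized from that identity.

Distance profiles scan the sense strand within ±50 nt of each site for
IUPAC motif matches; each site contributes its nearest occurrence
(distance measured to the motif body, ties to the most upstream match).
Offsets are `site − motif_start` under the `first_base` anchor; under
`length_scaled`, the motif body maps to 0 and downstream offsets shift by
−(L−1), making motifs of different lengths comparable. Flanks and
distance windows are contiguous genomic sequence, not splice-aware;
splice-aware windows are future work.

Deaminase context matrices are column-normalized base frequencies over
±4 nt windows centered on the edited base (sense strand, N-padded at
contig ends, padding ignored in counts); the consensus letter per column
is the smallest IUPAC code covering all bases with frequency ≥ 0.25.

## Annotation and set comparison

Region calls use the precedence CDS > 3'UTR > 5'UTR > noncoding_exon >
intron > intergenic across all overlapping transcripts; this exon-first
order mirrors common CLIP annotators and is stable under transcript
order. UTR labels require an annotated CDS. Overlap significance is the
hypergeometric upper tail P(X ≥ overlap); the default universe for gene
sets should be genes detected in both experiments, which avoids
expression bias — the universe is always an explicit argument. Sample
distances are Euclidean on binary presence vectors (√Hamming; both
reported). Ordination (PCA, clustering, heatmaps) is deliberately out of
the computational core: matrices are emitted for standard tools.

## Synthetic data

The generator emits one contig per gene (200-nt intergenic flanks),
single-exon gene models with 10% 5'UTR / 50% CDS / 40% 3'UTR, and pileup
tables at every position that can carry a variant. Defaults define the
study conditions: 500 genes of 1000–3000 nt, 10% target genes, motif
UGUAAAUA planted (3 copies per target 3'UTR, spaced beyond the profile
window so nearest-occurrence assignment is unambiguous), 2 editing sites
per motif at offsets −10..−1 with rate 0.20, zero editing in the 0..+9
footprint, context background 0.01 (C in ACH) and 0.003 (A in WAS) in
both deaminase-bearing roles, 2% hyper genes with 25 forced ACH sites at
rate 0.10, SNPs (rate 0.5 or 1.0, all roles) in 5% of genes, Poisson(50)
coverage, Binomial edits, 2 replicates per role. Chance occurrences of
the motif in target genes are disrupted by a single base change so the
planted footprint is exact truth. All randomness derives from one seed;
outputs are byte-identical across runs.

What the generator does *not* emulate: read-level error and mapping
artifacts, splicing, expression-level variation between genes beyond
Poisson depth, overlapping genes, doublet/ambient effects in single
cells, and position-dependent coverage. Passing recovery tests therefore
demonstrates the correctness of the statistics and bookkeeping under the
assay's idealized generative model, not robustness to alignment
artifacts — those must be handled upstream of the pileup tables.

At these conditions the end-to-end harness (`run_recovery`) attains
gene-level sensitivity 1.0 and FDR 0.0, site-level sensitivity ≈ 0.88
(sites lost to the z ≥ 4 cutoff by sampling noise at coverage ~100), a
top enriched k-mer inside the planted motif, all distance mass in the
planted offsets, an empty footprint, and ACH/WAS context consensus —
and zero called targets when the planted rate is set to 0. The
`scripts/acceptance.py` runtime is dominated by the two 500-gene
pipeline runs (~15 s on one core).

## Numerical and interface choices

- Coordinates: internal intervals 0-based half-open; pileup TSV and VCF
  1-based; BED/bedGraph 0-based half-open. Site positions are 1-based
  throughout the API. Contig names match exactly (no "chr" aliasing).
- Unstranded pileup input is rejected, never guessed; sites outside
  annotated genes are dropped by default (gene-centric analysis) unless
  `keep_unannotated` trusts the pileup's strand column.
- `min_edit_reads` defaults to 2: one edited read at coverage 5 is
  indistinguishable from error. Configurable.
- Degenerate statistics are defined, not special-cased downstream:
  z = 0 when the pooled proportion is 0 or 1; reproducibility ratios with
  no qualifying sites are reported as missing; empty candidate sets give
  empty (not failing) enrichment results.
- Down-sampling is binomial thinning per count cell under an explicit
  seed; fraction 1 is an exact identity.
- Ties in enrichment ranking break by descending foreground support then
  lexicographically; nearest-motif ties break to the most upstream
  occurrence. Both make outputs order-stable.
- The multiple-testing question for site calling is deliberately left to
  the thresholded raw scores (as in the source assay's published
  criteria); a Benjamini–Hochberg column can be added downstream but is
  not used for calling.

## Known limitations

- The pooled two-proportion z is a large-sample approximation; at the
  5-read floor it is conservative mainly through the fold and rate
  criteria, not through calibrated error control.
- Windows and flanks use genomic, not transcript, coordinates; sites
  within 50 nt of a splice junction see intronic sequence.
- A site overlapping two same-strand genes is assigned to both
  (logged); counts derived from such sites are not deduplicated across
  genes.
- The empty-control filter excludes positions, not alleles: a true
  editing site coinciding with a SNP position is lost.
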