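# rbpedit

RBP target identification from deaminase-induced RNA editing.

Fusing an RNA-binding protein (RBP) to RNA base editors — a cytidine
deaminase writing C→U and an adenosine deaminase writing A→I (read as G) —
leaves sequence edits on the transcripts the protein binds. `rbpedit`
implements the computational half of such an experiment: it detects
editing sites in stranded RNA-seq pileup counts, calls RBP *target sites*
and *target genes* by differential editing against a non-targeting
deaminase-only control, and characterizes binding through
edited-base-excluded motif enrichment, site-to-motif distance
footprinting, genomic region annotation and target-set comparison. A
bundled synthetic-data generator produces ground-truthed inputs, so every
stage is testable without any sequencing data.

It is intended for computational biologists analyzing TRIBE/STAMP-style
editing-based binding assays (bulk or low-input/single-cell), and for
method developers who need a transparent, fully seeded reference
implementation with planted-truth benchmarks.

## The statistics at the core

At a candidate site with `e` edited and `r` reference reads, the editing
rate is `p = e / (r + e)` (third-allele reads are excluded from the
denominator). A site is a **target site** when, against the pooled
control,

1. `p_rbp ≥ 0.05`,
2. `p_rbp ≥ 2 × max(p_ctrl, 1/(n_ctrl + 2))` (fold change with a
   continuity floor on the control rate), and
3. the pooled two-proportion z-score
   `z = (p_rbp − p_ctrl) / sqrt(p̄(1−p̄)(1/n_rbp + 1/n_ctrl)) ≥ 4`,

where `n` are allelic coverages and `p̄` the pooled rate. These are the
cultured-cell cutoffs; an `in_vivo` preset uses fold ≥ 1.5 and z > 1
(strict). Genes with ≥ 1 target site are **target genes**, ranked by the
sum of z-scores over their target sites; a gene with ≥ 20 editing sites
of one type is flagged **hyper-edited**. Known SNPs and any site variant
in the deaminase-free empty control are filtered out first.

Motif discovery excludes the edited base (the enzymes' own context bias —
C in ACH, A in WAS — would otherwise dominate) and tests window-level
k-mer presence between target-site and control-site flanks with a
one-sided Fisher exact test; `E-value = (number of candidate k-mers) × p`.
Set overlaps use the hypergeometric upper tail; sample relatedness uses
Euclidean distance between binary site-presence vectors.

## Worked example

Run the whole pipeline on a simulated experiment (500 genes, 10% true
target genes carrying the Pumilio response element UGUAAAUA in their
3'UTR, planted editing rate 0.20 at 1–10 nt upstream of the motif, mean
coverage 50, two replicates per role):

```python
from rbpedit.synthetic_data import SimConfig, run_recovery
report = run_recovery(SimConfig(seed=1))
```

which prints (via `json.dumps(report, indent=1)`):

```
{
 "n_true_target_genes": 50,
 "n_called_target_genes": 50,
 "gene_sensitivity": 1.0,
 "gene_fdr": 0.0,
 "n_planted_sites": 300,
 "n_called_target_sites": 264,
 "site_sensitivity": 0.88,
 "site_fdr": 0.0,
 "hyper_gene_recall": 1.0,
 "n_empty_control_exclusions": 25,
 "top_kmer": "GTAAAT",
 "top_kmer_overlaps_motif": true,
 "profile_upstream_mass": 1.0,
 "footprint_zone_count": 0,
 "ctou_context_consensus": "AYWACHGST",
 "atoi_context_consensus": "RSMWASDKW",
 ...
}
```

All 50 planted target genes are recovered with no false positives; 88% of
individual planted sites pass the site-level thresholds (the remainder
fall below the z ≥ 4 cutoff by sampling noise). The top enriched k-mer,
GTAAAT, is the core of the planted motif; every profiled site sits in the
planted upstream offsets and none in the 10-nt footprint downstream of
the motif's first base, and the deaminase context consensus recovered
from the control recapitulates ACH around edited C and WAS around edited
A (offsets −1..+1 of the center).

The same stages are exposed as a command line:

```sh
rbpedit simulate --seed 3 --n-genes 100 --out-dir sim/
rbpedit call --rbp sim/rbp_rep1.pileup.tsv --rbp sim/rbp_rep2.pileup.tsv \
             --ctrl sim/control_rep1.pileup.tsv --ctrl sim/control_rep2.pileup.tsv \
             --empty sim/empty_rep1.pileup.tsv --empty sim/empty_rep2.pileup.tsv \
             --gtf sim/genes.gtf --fasta sim/reference.fa --out-dir calls/
rbpedit annotate --sites det/sites.tsv --gtf sim/genes.gtf --out-dir anno/
```

`call` writes per-site comparisons, BED6 target sites, a delta-editing
bedGraph, a ranked target-gene table and a reproducibility manifest.
Pileup tables (TSV with header `contig pos strand ref A C G T`) are the
entry point; producing them from BAM is an upstream step outside this
package.

## Layout

- `rbpedit.io_formats` — pileup TSV, FASTA, GTF, VCF/BED exclusion lists,
  BED6/bedGraph output; fixed coordinate conventions.
- `rbpedit.editing_detection` — edit classification, site calling,
  background filtering, ±k context windows.
- `rbpedit.target_calling` — thresholds/presets, z-score, differential
  comparison, gene aggregation, replicate reproducibility, down-sampling.
- `rbpedit.motif_analysis` — edited-base-excluded flanks, k-mer
  enrichment with E-values, deaminase context matrices, distance
  profiles.
- `rbpedit.annotation` — CDS/UTR/intron region assignment and regional
  enrichment.
- `rbpedit.set_comparison` — hypergeometric overlap, binary distances,
  rate matrices.
- `rbpedit.synthetic_data` — the generator and the end-to-end recovery
  harness.
- `rbpedit.cli` — `simulate | detect | call | motif | annotate | compare`.

See `docs/methods.md` for the model, parameter choices and limitations.
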