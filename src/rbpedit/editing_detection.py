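"""Turn coverage-filtered pileups into classified candidate editing sites.

The two deaminase chemistries leave distinct sense-strand signatures:
Apobec1-style C-to-U editing reads as C>T, and ADAR-style A-to-I editing
reads as A>G (inosine pairs like G). On the genomic minus strand these
appear as G>A and T>C respectively. All classification is done in
sense-strand space using the transcribed strand of the overlapping gene.

The editing rate at a site is defined as ``edited / (reference + edited)``:
reads carrying a third allele (sequencing error or an unrelated variant)
are excluded from the denominator, matching per-allele chromatogram
quantification.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from intervaltree import IntervalTree

from .errors import ValidationError
from .io_formats import BASES, ExclusionSet, GeneModel, PileupTable
from .sequence import revcomp

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: sense-strand (ref, alt) -> edit type
_EDIT_TYPES = {("C", "T"): "CtoU", ("A", "G"): "AtoI"}


@dataclass(frozen=True)
class EditingSite:
    """A candidate C-to-U or A-to-I event at one reference position.

    ``position`` is 1-based; ``gene_strand`` is the transcribed strand the
    call was made on. ``rate`` = edit_count / (ref_count + edit_count).
    """

    contig: str
    position: int
    gene_strand: str
    edit_type: str
    ref_count: int
    edit_count: int
    other_count: int
    gene_id: str = ""

    @property
    def rate(self) -> float:
        denom = self.ref_count + self.edit_count
        return self.edit_count / denom if denom else 0.0

    @property
    def coverage(self) -> int:
        """Allelic coverage used in the rate denominator."""
        return self.ref_count + self.edit_count

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.edit_type)


def classify_edit(ref_base: str, alt_base: str, gene_strand: str) -> str | None:
    """Classify a genomic substitution as CtoU, AtoI or neither.

    ``ref_base``/``alt_base`` are genomic forward-strand bases; the change
    is projected onto the sense strand before classification.
    """
    if ref_base not in _COMPLEMENT or alt_base not in _COMPLEMENT:
        raise ValidationError(f"invalid base: {ref_base!r}>{alt_base!r}")
    if gene_strand not in {"+", "-"}:
        raise ValidationError(f"invalid strand: {gene_strand!r}")
    if gene_strand == "-":
        ref_base, alt_base = _COMPLEMENT[ref_base], _COMPLEMENT[alt_base]
    return _EDIT_TYPES.get((ref_base, alt_base))


def _gene_trees(gene_models: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)
    return trees


def call_editing_sites(
    pileup: PileupTable,
    gene_models: Sequence[GeneModel] | None = None,
    reference: Mapping[str, str] | None = None,
    min_coverage: int = 5,
    min_edit_reads: int = 2,
    keep_unannotated: bool = False,
) -> list[EditingSite]:
    """Emit one :class:`EditingSite` per (position, edit type) with evidence.

    A site must have at least ``min_coverage`` total reads and at least
    ``min_edit_reads`` edited reads. The transcribed strand comes from the
    overlapping gene model; by default positions outside annotated genes are
    dropped (the analysis is gene-centric), unless ``keep_unannotated`` is
    set, in which case the pileup's own strand column is trusted.

    When a reference is supplied, the pileup's ref base is checked against
    it and a mismatch raises, naming the site.
    """
    trees = _gene_trees(gene_models) if gene_models else {}
    sites: list[EditingSite] = []
    seen: set[tuple[str, int, str, str]] = set()
    for row in pileup.df.itertuples(index=False):
        counts = {b: getattr(row, b) for b in BASES}
        total = sum(counts.values())
        if total < min_coverage:
            continue
        ref = row.ref
        if reference is not None:
            actual = reference[row.contig][row.pos - 1].upper()
            if actual != ref:
                raise ValidationError(
                    f"ref base mismatch at {row.contig}:{row.pos}: "
                    f"pileup says {ref}, reference says {actual}"
                )
        if gene_models is not None:
            hits = trees.get(row.contig, IntervalTree())[row.pos - 1]
            gene_hits = [(iv.data.strand, iv.data.gene_id) for iv in hits]
            if not gene_hits and keep_unannotated:
                gene_hits = [(row.strand, "")]
        else:
            gene_hits = [(row.strand, "")]
        for strand, gene_id in sorted(set(gene_hits)):
            # sense-strand edited base, mapped back to genomic space
            sense_ref = ref if strand == "+" else _COMPLEMENT[ref]
            for (s_ref, s_alt), etype in _EDIT_TYPES.items():
                if sense_ref != s_ref:
                    continue
                genomic_alt = s_alt if strand == "+" else _COMPLEMENT[s_alt]
                edit_count = counts[genomic_alt]
                if edit_count < min_edit_reads:
                    continue
                dedup = (row.contig, row.pos, strand, etype)
                if dedup in seen:
                    continue
                seen.add(dedup)
                ref_count = counts[ref]
                sites.append(
                    EditingSite(
                        contig=row.contig,
                        position=int(row.pos),
                        gene_strand=strand,
                        edit_type=etype,
                        ref_count=int(ref_count),
                        edit_count=int(edit_count),
                        other_count=int(total - ref_count - edit_count),
                        gene_id=gene_id,
                    )
                )
    sites.sort(key=lambda s: (s.contig, s.position, s.edit_type))
    return sites


def filter_background(
    sites: Sequence[EditingSite],
    empty_control_sites: ExclusionSet,
    snp_set: ExclusionSet,
) -> list[EditingSite]:
    """Remove sites at known SNPs or at positions edited in the empty control.

    Both exclusion lists are positional: any site whose (contig, position)
    appears in either set is dropped. Removal counts are logged per category.
    """
    kept: list[EditingSite] = []
    n_empty = n_snp = 0
    for s in sites:
        key = (s.contig, s.position)
        if key in empty_control_sites:
            n_empty += 1
        elif key in snp_set:
            n_snp += 1
        else:
            kept.append(s)
    logger.info(
        "filter_background: removed %d empty-control, %d SNP; kept %d of %d",
        n_empty,
        n_snp,
        len(kept),
        len(sites),
    )
    return kept


def context_window(
    site: EditingSite, reference: Mapping[str, str], k: int = 4
) -> str:
    """Sense-strand sequence of length 2k+1 centered on the edited base.

    Windows running off a contig end are padded with N so the edited base
    always sits at index ``k``. Minus-strand sites are reverse-complemented.
    """
    if k < 1:
        raise ValidationError("context half-width k must be >= 1")
    seq = reference[site.contig]
    center = site.position - 1
    lo, hi = center - k, center + k + 1
    window = seq[max(lo, 0) : min(hi, len(seq))].upper()
    window = "N" * max(0, -lo) + window + "N" * max(0, hi - len(seq))
    return revcomp(window) if site.gene_strand == "-" else window
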