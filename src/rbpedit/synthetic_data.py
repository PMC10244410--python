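"""Ground-truthed synthetic editing data.

The generator emulates the statistical structure of a deaminase-fusion
profiling experiment on a transcriptome of independent single-exon genes
(one contig per gene, with intergenic flanks):

* a fraction of genes are true RBP targets: the binding motif is planted
  in their 3'UTR, and editing is elevated at defined sense-strand offsets
  upstream of the motif's first base while a footprint zone downstream of
  it receives no editing at all (the bound protein occludes the enzyme);
* background editing appears in both the RBP and the deaminase-only
  control, and only in the enzymes' preferred sequence contexts (C in ACH
  for the cytidine deaminase, A in WAS for the adenosine deaminase), so
  context-recovery analyses have a defined truth;
* a small set of genes is hyper-edited (many C-to-U sites at moderate
  rate in all deaminase-bearing samples), mimicking stochastic editing;
* heterozygous/homozygous SNPs contaminate every role including the
  deaminase-free empty control, which is what makes empty-control
  filtering meaningful.

Counts are Poisson coverage with Binomial edited reads, fully determined
by the configuration seed.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .editing_detection import (
    EditingSite,
    call_editing_sites,
    filter_background,
)
from .errors import ValidationError
from .io_formats import (
    BASES,
    ExclusionSet,
    GeneModel,
    PileupTable,
    PILEUP_COLUMNS,
)
from .motif_analysis import (
    deaminase_context,
    extract_flanks,
    kmer_enrichment,
    site_motif_distances,
)
from .sequence import IUPAC_BASES, normalize_motif, revcomp
from .target_calling import Thresholds, aggregate_genes, call_targets

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ROLE_INDEX = {"rbp": 1, "control": 2, "empty": 3}


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment."""

    seed: int = 0
    n_genes: int = 500
    gene_length: tuple[int, int] = (1000, 3000)
    fraction_target_genes: float = 0.10
    motif: str = "TGTAAATA"  # UGUAAAUA, the Pumilio response element
    edit_offset_weights: dict[int, float] = field(
        default_factory=lambda: {o: 1.0 for o in range(-10, 0)}
    )
    footprint_zone: tuple[int, int] = (0, 9)
    target_edit_rate: float = 0.20
    background_ctou_rate: float = 0.01
    background_atoi_rate: float = 0.003
    hyper_gene_fraction: float = 0.02
    hyper_site_count: int = 25
    hyper_edit_rate: float = 0.10
    coverage_mean: float = 50.0
    n_replicates: int = 2
    snp_fraction: float = 0.05
    motifs_per_target_gene: int = 3
    sites_per_motif: int = 2
    flank: int = 200

    def __post_init__(self) -> None:
        self.motif = normalize_motif(self.motif)
        for r in (
            self.target_edit_rate,
            self.background_ctou_rate,
            self.background_atoi_rate,
            self.hyper_edit_rate,
        ):
            if not 0 <= r <= 1:
                raise ValidationError("rates must lie in [0, 1]")
        if any(wt < 0 for wt in self.edit_offset_weights.values()):
            raise ValidationError("offset weights must be non-negative")
        lo, hi = self.footprint_zone
        if any(lo <= o <= hi for o in self.edit_offset_weights if self.edit_offset_weights[o] > 0):
            raise ValidationError("edit offsets must not fall inside the footprint zone")


@dataclass(frozen=True)
class PlantedSite:
    contig: str
    position: int  # 1-based genomic
    strand: str
    edit_type: str
    offset: int  # sense-strand offset from the motif's first base
    rate: float
    gene_id: str


@dataclass(frozen=True)
class EditEvent:
    """One position that can carry non-reference reads in some roles."""

    contig: str
    position: int
    strand: str
    ref: str  # genomic forward-strand base
    alt: str
    rate: float
    roles: frozenset  # subset of {rbp, control, empty}
    kind: str  # planted | background | hyper | snp


@dataclass
class TruthTable:
    planted_sites: list[PlantedSite] = field(default_factory=list)
    target_genes: set[str] = field(default_factory=set)
    hyper_genes: set[str] = field(default_factory=set)
    snps: list[tuple[str, int, str, str]] = field(default_factory=list)
    events: list[EditEvent] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _disrupt_spurious_motifs(
    sense: list[str],
    motif: str,
    keep_starts: set[int],
    blocked: set[int],
    rng: np.random.Generator,
) -> None:
    """Mutate chance motif occurrences so only planted instances remain.

    The distance footprint around planted sites is part of the ground
    truth; an accidental occurrence of the motif near a planted site would
    blur it. Each spurious match gets one base flipped to a base the motif
    letter does not allow, avoiding planted/blocked positions.
    """
    from .sequence import matches_iupac

    L = len(motif)
    for _ in range(3):  # re-scan in case a mutation shifted a match
        changed = False
        seq = "".join(sense)
        for m in range(len(seq) - L + 1):
            if m in keep_starts or not matches_iupac(seq[m : m + L], motif):
                continue
            for j in range(m, m + L):
                if j in blocked:
                    continue
                allowed = IUPAC_BASES[motif[j - m]]
                options = sorted(set("ACGT") - allowed)
                if options:
                    sense[j] = options[int(rng.integers(0, len(options)))]
                    changed = True
                    break
        if not changed:
            break


def _sense_to_genomic0(p: int, gene_start: int, length: int, strand: str) -> int:
    return gene_start + p if strand == "+" else gene_start + length - 1 - p


def simulate_reference(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], TruthTable]:
    """Build the reference FASTA content, gene models and ground truth.

    Deterministic under ``config.seed``: the same configuration always
    yields identical sequences, models and truth.
    """
    rng = np.random.default_rng([config.seed, 0])
    truth = TruthTable()
    reference: dict[str, str] = {}
    models: list[GeneModel] = []
    motif = config.motif
    L_motif = len(motif)
    offsets = sorted(o for o, wt in config.edit_offset_weights.items() if wt > 0)
    weights = np.array([config.edit_offset_weights[o] for o in offsets], dtype=float)
    weights /= weights.sum()
    fp_lo, fp_hi = config.footprint_zone

    n_targets = int(round(config.fraction_target_genes * config.n_genes))
    target_idx = set(
        rng.choice(config.n_genes, size=n_targets, replace=False).tolist()
    )
    non_targets = [i for i in range(config.n_genes) if i not in target_idx]
    n_hyper = int(np.ceil(config.hyper_gene_fraction * config.n_genes))
    hyper_idx = set(
        rng.choice(len(non_targets), size=min(n_hyper, len(non_targets)), replace=False).tolist()
    )
    hyper_idx = {non_targets[i] for i in hyper_idx}
    n_snp_genes = int(round(config.snp_fraction * config.n_genes))
    snp_idx = set(rng.choice(config.n_genes, size=n_snp_genes, replace=False).tolist())

    for i in range(config.n_genes):
        gene_id = f"g{i:04d}"
        contig = gene_id
        length = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        sense = list(_random_seq(rng, length))
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = length // 10
        cds_len = length // 2
        utr3_start = u5 + cds_len
        blocked: set[int] = set()  # sense positions that may not carry background
        planted_here: list[tuple[int, str, int]] = []  # (sense pos, type, offset)
        motif_starts: list[int] = []

        if i in target_idx:
            truth.target_genes.add(gene_id)
            utr3_len = length - utr3_start
            spacing = max(2 * 50 + L_motif + 20, (utr3_len - 40) // max(config.motifs_per_target_gene, 1))
            n_fit = max(0, min(config.motifs_per_target_gene, (utr3_len - 40) // spacing + 1))
            if n_fit == 0:
                raise ValidationError(
                    f"gene {gene_id} too short to hold the motif and its flanks"
                )
            for j in range(n_fit):
                m = utr3_start + 20 + j * spacing
                if m + L_motif > length:
                    break
                concrete = "".join(
                    b if b in "ACGT" else rng.choice(sorted(IUPAC_BASES[b]))
                    for b in motif
                )
                sense[m : m + L_motif] = list(concrete)
                motif_starts.append(m)
                blocked.update(range(m + fp_lo, m + fp_hi + 1))
                chosen = rng.choice(
                    len(offsets),
                    size=min(config.sites_per_motif, len(offsets)),
                    replace=False,
                    p=weights,
                )
                for ci in sorted(chosen.tolist()):
                    o = offsets[ci]
                    p = m + o
                    if p < 0 or p >= length or p in blocked:
                        continue
                    etype = "CtoU" if rng.random() < 0.7 else "AtoI"
                    sense[p] = "C" if etype == "CtoU" else "A"
                    planted_here.append((p, etype, o))
                    blocked.add(p)
            _disrupt_spurious_motifs(sense, motif, set(motif_starts), blocked, rng)

        hyper_positions: list[int] = []
        if i in hyper_idx:
            truth.hyper_genes.add(gene_id)
            step = max(9, (length - u5 - 20) // (config.hyper_site_count + 1))
            p = u5 + 10
            while len(hyper_positions) < config.hyper_site_count and p < length - 2:
                # force an ACH context so hyper sites share the enzyme's bias
                sense[p - 1], sense[p] = "A", "C"
                if sense[p + 1] == "G":
                    sense[p + 1] = "T"
                hyper_positions.append(p)
                blocked.add(p)
                p += step

        # SNP in a random position clear of everything planted
        snp_here: tuple[int, str] | None = None
        if i in snp_idx:
            for _ in range(50):
                p = int(rng.integers(10, length - 10))
                if p in blocked or any(m <= p < m + L_motif for m in motif_starts):
                    continue
                snp_rate = 1.0 if rng.random() < 0.5 else 0.5
                snp_here = (p, snp_rate)
                blocked.add(p)
                break

        sense_str = "".join(sense)
        gene_start = config.flank
        genomic_gene = sense_str if strand == "+" else revcomp(sense_str)
        contig_seq = (
            _random_seq(rng, config.flank) + genomic_gene + _random_seq(rng, config.flank)
        )
        reference[contig] = contig_seq

        cds_sense = (u5, u5 + cds_len)
        if strand == "+":
            cds_genomic = (gene_start + cds_sense[0], gene_start + cds_sense[1])
        else:
            cds_genomic = (
                gene_start + length - cds_sense[1],
                gene_start + length - cds_sense[0],
            )
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                exons=((gene_start, gene_start + length),),
                cds=(cds_genomic,),
                transcript_id=gene_id + ".t1",
            )
        )

        def _event(p_sense: int, sense_ref: str, sense_alt: str, rate: float,
                   roles: frozenset, kind: str) -> EditEvent:
            g0 = _sense_to_genomic0(p_sense, gene_start, length, strand)
            ref = sense_ref if strand == "+" else _COMPLEMENT[sense_ref]
            alt = sense_alt if strand == "+" else _COMPLEMENT[sense_alt]
            return EditEvent(contig, g0 + 1, strand, ref, alt, rate, roles, kind)

        for p, etype, o in planted_here:
            sref, salt = ("C", "T") if etype == "CtoU" else ("A", "G")
            ev = _event(p, sref, salt, config.target_edit_rate, frozenset({"rbp"}), "planted")
            truth.events.append(ev)
            truth.planted_sites.append(
                PlantedSite(contig, ev.position, strand, etype, o, config.target_edit_rate, gene_id)
            )
        for p in hyper_positions:
            truth.events.append(
                _event(p, "C", "T", config.hyper_edit_rate,
                       frozenset({"rbp", "control"}), "hyper")
            )
        if snp_here is not None:
            p, snp_rate = snp_here
            sref = sense_str[p]
            salt = rng.choice([b for b in "ACGT" if b != sref])
            ev = _event(p, sref, salt, snp_rate, frozenset({"rbp", "control", "empty"}), "snp")
            truth.events.append(ev)
            truth.snps.append((contig, ev.position, ev.ref, ev.alt))

        # context-biased background: C in ACH, A in WAS, outside blocked zones
        for p in range(1, length - 1):
            if p in blocked:
                continue
            b_prev, b, b_next = sense_str[p - 1], sense_str[p], sense_str[p + 1]
            if b == "C" and b_prev == "A" and b_next in "ACT":
                truth.events.append(
                    _event(p, "C", "T", config.background_ctou_rate,
                           frozenset({"rbp", "control"}), "background")
                )
            elif b == "A" and b_prev in "AT" and b_next in "GC":
                truth.events.append(
                    _event(p, "A", "G", config.background_atoi_rate,
                           frozenset({"rbp", "control"}), "background")
                )

    logger.info(
        "simulated %d genes (%d targets, %d hyper, %d SNP genes), %d events",
        config.n_genes, len(truth.target_genes), len(truth.hyper_genes),
        n_snp_genes, len(truth.events),
    )
    return reference, models, truth


def simulate_pileups(
    reference: Mapping[str, str],
    truth: TruthTable,
    config: SimConfig,
    role: str,
) -> list[PileupTable]:
    """Draw per-replicate pileup tables for one sample role.

    Every event position is covered in every role (the row universe is
    shared), but edited reads only appear where the event is active for
    the role: planted sites in the RBP fusion only, context background and
    hyper sites in both deaminase-bearing roles, SNPs everywhere.
    """
    if role not in _ROLE_INDEX:
        raise ValidationError(f"unknown role {role!r}")
    events = sorted(truth.events, key=lambda e: (e.contig, e.position))
    n = len(events)
    rates = np.array([e.rate if role in e.roles else 0.0 for e in events])
    contigs = [e.contig for e in events]
    positions = np.array([e.position for e in events])
    strands = [e.strand for e in events]
    refs = [e.ref for e in events]
    ref_idx = np.array([BASES.index(r) for r in refs])
    alt_idx = np.array([BASES.index(e.alt) for e in events])
    tables = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, _ROLE_INDEX[role], rep])
        cov = rng.poisson(config.coverage_mean, n)
        edited = rng.binomial(cov, rates)
        counts = np.zeros((n, 4), dtype=np.int64)
        counts[np.arange(n), ref_idx] = cov - edited
        counts[np.arange(n), alt_idx] += edited
        df = pd.DataFrame(
            {
                "contig": contigs,
                "pos": positions,
                "strand": strands,
                "ref": refs,
                **{b: counts[:, j] for j, b in enumerate(BASES)},
            }
        )[PILEUP_COLUMNS]
        tables.append(PileupTable(sample_id=f"{role}_rep{rep + 1}", df=df))
    return tables


def variant_positions(
    pileup: PileupTable, min_alt_reads: int = 2, min_coverage: int = 5
) -> ExclusionSet:
    """Positions carrying any non-reference evidence, as an exclusion set.

    This is how the empty-control sample is turned into a background
    variation filter: every covered position with ``min_alt_reads`` or
    more reads of any alternative base is excluded downstream.
    """
    keys = []
    for row in pileup.df.itertuples(index=False):
        counts = {b: getattr(row, b) for b in BASES}
        if sum(counts.values()) < min_coverage:
            continue
        if any(c >= min_alt_reads for b, c in counts.items() if b != row.ref):
            keys.append((row.contig, int(row.pos)))
    return ExclusionSet.from_keys(keys)


def _kmer_overlaps(kmer: str, motif: str, min_overlap: int = 4) -> bool:
    """True when some alignment of kmer against motif matches >= min_overlap nt."""
    for shift in range(-len(kmer) + 1, len(motif)):
        n_match = 0
        for i, base in enumerate(kmer):
            j = shift + i
            if 0 <= j < len(motif) and base in IUPAC_BASES[motif[j]]:
                n_match += 1
            elif 0 <= j < len(motif):
                n_match = -1000
                break
        if n_match >= min_overlap:
            return True
    return False


def run_recovery(
    config: SimConfig | None = None,
    thresholds: Thresholds | None = None,
    max_bg_windows: int = 5000,
) -> dict:
    """Simulate, run the full pipeline, and score it against the truth.

    Returns a report with gene- and site-level sensitivity and false
    discovery, the top enriched k-mer and whether it overlaps the planted
    motif, the site-to-motif distance mass in the planted offset range and
    the footprint zone, and the recovered deaminase context consensus.
    """
    from .io_formats import pool_pileups

    config = config or SimConfig()
    thresholds = thresholds or Thresholds.cultured()
    reference, models, truth = simulate_reference(config)
    rbp = simulate_pileups(reference, truth, config, "rbp")
    ctrl = simulate_pileups(reference, truth, config, "control")
    empty = simulate_pileups(reference, truth, config, "empty")

    empty_excl = variant_positions(
        pool_pileups(empty, "empty_pooled"),
        min_alt_reads=thresholds.min_edit_reads,
        min_coverage=thresholds.min_coverage,
    )
    comparisons = call_targets(
        rbp, ctrl, models, thresholds, mode="pooled",
        reference=reference, exclude=empty_excl,
    )
    targets = [c for c in comparisons if c.is_target]

    all_sites = call_editing_sites(
        pool_pileups(rbp, "rbp_pooled"), models, reference,
        min_coverage=thresholds.min_coverage,
        min_edit_reads=thresholds.min_edit_reads,
    )
    all_sites = filter_background(all_sites, empty_excl, ExclusionSet())
    genes = aggregate_genes(comparisons, models, thresholds, all_sites=all_sites)
    called_genes = {g.gene_id for g in genes}

    tp = len(called_genes & truth.target_genes)
    sensitivity = tp / len(truth.target_genes) if truth.target_genes else None
    fdr = (
        len(called_genes - truth.target_genes) / len(called_genes)
        if called_genes
        else 0.0
    )
    planted_keys = {(s.contig, s.position, s.edit_type) for s in truth.planted_sites}
    called_keys = {c.key for c in targets}
    site_sens = (
        len(called_keys & planted_keys) / len(planted_keys) if planted_keys else None
    )
    site_fdr = (
        len(called_keys - planted_keys) / len(called_keys) if called_keys else 0.0
    )
    # hyper-editing is a property of all edited genes, not just targets
    hyper_by_gene: dict[str, set[int]] = {}
    for s in all_sites:
        if s.edit_type == "CtoU" and s.gene_id:
            hyper_by_gene.setdefault(s.gene_id, set()).add(s.position)
    hyper_called = {
        g for g, sites in hyper_by_gene.items()
        if len(sites) >= thresholds.hyper_min_sites
    }

    report: dict = {
        "n_true_target_genes": len(truth.target_genes),
        "n_called_target_genes": len(called_genes),
        "gene_sensitivity": sensitivity,
        "gene_fdr": fdr,
        "n_planted_sites": len(planted_keys),
        "n_called_target_sites": len(called_keys),
        "site_sensitivity": site_sens,
        "site_fdr": site_fdr,
        "hyper_gene_recall": (
            len(hyper_called & truth.hyper_genes) / len(truth.hyper_genes)
            if truth.hyper_genes
            else None
        ),
        "n_empty_control_exclusions": len(empty_excl),
    }

    # --- motif enrichment and distance footprint ------------------------
    rng = np.random.default_rng([config.seed, 99])
    ctrl_sites = call_editing_sites(
        pool_pileups(ctrl, "ctrl_pooled"), models, reference,
        min_coverage=thresholds.min_coverage,
        min_edit_reads=thresholds.min_edit_reads,
    )
    ctrl_sites = filter_background(ctrl_sites, empty_excl, ExclusionSet())
    if targets:
        target_sites = [
            EditingSite(c.contig, c.position, c.gene_strand, c.edit_type, 0, 1, 0,
                        gene_id=c.gene_id)
            for c in targets
        ]
        fg = [extract_flanks(s, reference) for s in target_sites]
        bg_pool = ctrl_sites
        if len(bg_pool) > max_bg_windows:
            idx = rng.choice(len(bg_pool), size=max_bg_windows, replace=False)
            bg_pool = [bg_pool[i] for i in sorted(idx)]
        bg = [extract_flanks(s, reference) for s in bg_pool]
        enrich = kmer_enrichment(
            fg, bg, k_range=(4, 8), min_fg=max(2, len(fg) // 20)
        )
        top = enrich[0] if enrich else None
        profile = site_motif_distances(target_sites, config.motif, reference, w=50)
        active = [o for o, wt in config.edit_offset_weights.items() if wt > 0]
        fp_lo, fp_hi = config.footprint_zone
        report.update(
            {
                "top_kmer": top.kmer if top else None,
                "top_kmer_e_value": top.e_value if top else None,
                "top_kmer_overlaps_motif": (
                    _kmer_overlaps(top.kmer, config.motif) if top else None
                ),
                "profile_upstream_mass": profile.mass(min(active), max(active)),
                "footprint_zone_count": sum(
                    v for o, v in profile.histogram.items() if fp_lo <= o <= fp_hi
                ),
                "n_profiled_sites": profile.total,
            }
        )
    else:
        report.update(
            {
                "top_kmer": None,
                "top_kmer_e_value": None,
                "top_kmer_overlaps_motif": None,
                "profile_upstream_mass": None,
                "footprint_zone_count": 0,
                "n_profiled_sites": 0,
            }
        )

    # --- deaminase context recovery from the non-targeting control ------
    ctou = [s for s in ctrl_sites if s.edit_type == "CtoU"]
    atoi = [s for s in ctrl_sites if s.edit_type == "AtoI"]
    k = 4
    if ctou:
        _, consensus_c = deaminase_context(ctou, reference, k=k)
        report["ctou_context_consensus"] = consensus_c
        report["ctou_context_ok"] = (
            IUPAC_BASES[consensus_c[k - 1]] <= IUPAC_BASES["A"]
            and IUPAC_BASES[consensus_c[k + 1]] <= IUPAC_BASES["H"]
        )
    if atoi:
        _, consensus_a = deaminase_context(atoi, reference, k=k)
        report["atoi_context_consensus"] = consensus_a
        report["atoi_context_ok"] = (
            IUPAC_BASES[consensus_a[k - 1]] <= IUPAC_BASES["W"]
            and IUPAC_BASES[consensus_a[k + 1]] <= IUPAC_BASES["S"]
        )
    return report
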