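"""Differential editing between RBP-fusion and non-targeting control samples.

A site is a *target* when three predicates hold simultaneously against the
deaminase-only control:

* the editing rate in the RBP sample reaches ``min_rate`` (inclusive);
* that rate is at least ``min_fold`` times the control rate (inclusive),
  with the control rate floored at a continuity correction
  ``1 / (control coverage + 2)`` so a clean control with deep coverage
  yields a large but finite fold change;
* the pooled two-proportion z-score between the two samples reaches
  ``min_z`` (inclusive for the cultured-cell preset, strict for the
  in vivo preset, mirroring the ">=" vs ">" wording of the two regimes).

Genes holding at least one target site are target genes; a gene carrying
20 or more editing sites of one type (targets or not) is flagged as
hyper-edited, a signature of stochastic deaminase activity rather than
guided binding.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

from .editing_detection import EditingSite, call_editing_sites, filter_background
from .errors import ValidationError
from .io_formats import BASES, ExclusionSet, GeneModel, PileupTable, pool_pileups

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class Thresholds:
    """Target-calling cutoffs.

    Defaults are the cultured-cell regime; :meth:`in_vivo` switches to the
    brain-tissue regime (lower fold, z > 1 strict).
    """

    min_rate: float = 0.05
    min_fold: float = 2.0
    min_z: float = 4.0
    z_strict: bool = False
    hyper_min_sites: int = 20
    reproducibility_rate: float = 0.05
    min_coverage: int = 5
    min_edit_reads: int = 2

    def __post_init__(self) -> None:
        for name in ("min_rate", "min_fold", "min_z", "hyper_min_sites"):
            if getattr(self, name) < 0:
                raise ValidationError(f"threshold {name} must be non-negative")

    @classmethod
    def cultured(cls, **overrides) -> "Thresholds":
        return cls(**overrides)

    @classmethod
    def in_vivo(cls, **overrides) -> "Thresholds":
        base = dict(min_fold=1.5, min_z=1.0, z_strict=True)
        base.update(overrides)
        return cls(**base)

    def z_passes(self, z: float) -> bool:
        return z > self.min_z if self.z_strict else z >= self.min_z


@dataclass(frozen=True)
class SiteComparison:
    """RBP-vs-control differential statistics at one candidate site."""

    contig: str
    position: int
    edit_type: str
    gene_strand: str
    rate_rbp: float
    rate_ctrl: float
    coverage_rbp: int
    coverage_ctrl: int
    fold_change: float
    z_score: float
    is_target: bool
    untestable: bool = False
    gene_id: str = ""
    reproducible: bool | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.edit_type)


@dataclass
class TargetGene:
    """Gene-level aggregation of target sites."""

    gene_id: str
    target_sites: list[SiteComparison] = field(default_factory=list)
    category: str = ""
    n_sites_CtoU: int = 0
    n_sites_AtoI: int = 0
    hyper_CtoU: bool = False
    hyper_AtoI: bool = False
    rank_score: float = 0.0


def z_score(edit_rbp: int, cov_rbp: int, edit_ctrl: int, cov_ctrl: int) -> float:
    """Pooled two-proportion z statistic on allelic counts.

    ``cov`` values are rate denominators (reference + edited reads). When
    the pooled proportion is degenerate (0 or 1) the statistic is defined
    as 0.
    """
    if cov_rbp <= 0 or cov_ctrl <= 0:
        raise ValidationError("z_score requires positive coverages")
    p1 = edit_rbp / cov_rbp
    p2 = edit_ctrl / cov_ctrl
    pooled = (edit_rbp + edit_ctrl) / (cov_rbp + cov_ctrl)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / cov_rbp + 1.0 / cov_ctrl))
    return (p1 - p2) / se


def control_rate_floor(cov_ctrl: int) -> float:
    """Continuity correction used as the minimum effective control rate."""
    return 1.0 / (cov_ctrl + 2)


def compare_site(
    site_rbp: EditingSite,
    site_ctrl: EditingSite | None,
    thresholds: Thresholds,
    ctrl_coverage: int | None = None,
) -> SiteComparison:
    """Score one site's editing in the RBP sample against the control.

    ``site_ctrl`` may be None for a position the control covers without any
    edited reads; pass the control's allelic coverage via ``ctrl_coverage``
    in that case. A control covered below ``thresholds.min_coverage`` makes
    the site *untestable* (neither target nor non-target evidence).
    """
    if site_ctrl is not None:
        edit_ctrl, cov_ctrl = site_ctrl.edit_count, site_ctrl.coverage
    else:
        edit_ctrl, cov_ctrl = 0, int(ctrl_coverage or 0)
    cov_rbp = site_rbp.coverage
    rate_rbp = site_rbp.rate
    rate_ctrl = edit_ctrl / cov_ctrl if cov_ctrl else 0.0
    untestable = cov_ctrl < thresholds.min_coverage
    if untestable:
        z = 0.0
        fold = 0.0
        is_target = False
    else:
        z = z_score(site_rbp.edit_count, cov_rbp, edit_ctrl, cov_ctrl)
        rate_ctrl_eff = max(rate_ctrl, control_rate_floor(cov_ctrl))
        fold = rate_rbp / rate_ctrl_eff
        is_target = (
            rate_rbp >= thresholds.min_rate
            and rate_rbp >= thresholds.min_fold * rate_ctrl_eff
            and thresholds.z_passes(z)
        )
    return SiteComparison(
        contig=site_rbp.contig,
        position=site_rbp.position,
        edit_type=site_rbp.edit_type,
        gene_strand=site_rbp.gene_strand,
        rate_rbp=rate_rbp,
        rate_ctrl=rate_ctrl,
        coverage_rbp=cov_rbp,
        coverage_ctrl=cov_ctrl,
        fold_change=fold,
        z_score=z,
        is_target=is_target,
        untestable=untestable,
        gene_id=site_rbp.gene_id,
    )


def _counts_at(pileup: PileupTable) -> dict[tuple[str, int], dict[str, int]]:
    lookup: dict[tuple[str, int], dict[str, int]] = {}
    for row in pileup.df.itertuples(index=False):
        lookup[(row.contig, int(row.pos))] = {b: int(getattr(row, b)) for b in BASES}
    return lookup


def _ctrl_site_for(
    candidate: EditingSite,
    ctrl_counts: Mapping[tuple[str, int], Mapping[str, int]],
) -> tuple[EditingSite | None, int]:
    """Control-side counts at a candidate site, using the same allele pair."""
    counts = ctrl_counts.get((candidate.contig, candidate.position))
    if counts is None:
        return None, 0
    sense_ref, sense_alt = ("C", "T") if candidate.edit_type == "CtoU" else ("A", "G")
    if candidate.gene_strand == "-":
        sense_ref, sense_alt = _COMPLEMENT[sense_ref], _COMPLEMENT[sense_alt]
    ref_count, edit_count = counts[sense_ref], counts[sense_alt]
    total = sum(counts.values())
    site = replace(
        candidate,
        ref_count=ref_count,
        edit_count=edit_count,
        other_count=total - ref_count - edit_count,
    )
    return site, site.coverage


def call_targets(
    rbp_pileups: Sequence[PileupTable],
    ctrl_pileups: Sequence[PileupTable],
    gene_models: Sequence[GeneModel] | None = None,
    thresholds: Thresholds | None = None,
    mode: str = "pooled",
    reference: Mapping[str, str] | None = None,
    exclude: ExclusionSet | None = None,
    keep_unannotated: bool = False,
) -> list[SiteComparison]:
    """Call differential editing sites between replicate groups.

    ``pooled`` mode sums counts across replicates on each side and performs
    one comparison per site; ``per_replicate`` mode calls each RBP replicate
    against the pooled control and reports the union, flagging sites that
    are targets in every replicate as *reproducible*. The 5-read coverage
    cutoff is applied per side: sites whose control coverage falls below it
    are reported as untestable.
    """
    if not rbp_pileups or not ctrl_pileups:
        raise ValidationError("need at least one replicate per side")
    if mode not in {"pooled", "per_replicate"}:
        raise ValidationError(f"unknown mode {mode!r}")
    thresholds = thresholds or Thresholds()
    exclude = exclude or ExclusionSet()
    ctrl_pool = pool_pileups(list(ctrl_pileups), "ctrl_pooled")
    ctrl_counts = _counts_at(ctrl_pool)

    def _compare_table(pileup: PileupTable) -> dict[tuple[str, int, str, str], SiteComparison]:
        candidates = call_editing_sites(
            pileup,
            gene_models=gene_models,
            reference=reference,
            min_coverage=thresholds.min_coverage,
            min_edit_reads=thresholds.min_edit_reads,
            keep_unannotated=keep_unannotated,
        )
        candidates = filter_background(candidates, exclude, ExclusionSet())
        out = {}
        for cand in candidates:
            ctrl_site, _ = _ctrl_site_for(cand, ctrl_counts)
            comp = compare_site(cand, ctrl_site, thresholds)
            out[(cand.contig, cand.position, cand.edit_type, cand.gene_id)] = comp
        return out

    if mode == "pooled":
        rbp_pool = pool_pileups(list(rbp_pileups), "rbp_pooled")
        comparisons = list(_compare_table(rbp_pool).values())
    else:
        per_rep = [_compare_table(p) for p in rbp_pileups]
        all_keys = sorted(set().union(*(d.keys() for d in per_rep)))
        comparisons = []
        for key in all_keys:
            present = [d[key] for d in per_rep if key in d]
            best = max(present, key=lambda c: c.z_score)
            comparisons.append(
                replace(
                    best,
                    is_target=any(c.is_target for c in present),
                    reproducible=all(key in d and d[key].is_target for d in per_rep),
                )
            )
    comparisons.sort(key=lambda c: (c.contig, c.position, c.edit_type, c.gene_id))
    if not any(not c.untestable for c in comparisons):
        logger.warning("no shared testable sites between RBP and control")
    return comparisons


def _exon_trees(gene_models: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        tree = trees.setdefault(g.contig, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, g.gene_id)
    return trees


def _genes_for(
    contig: str, position: int, gene_id: str, trees: dict[str, IntervalTree]
) -> list[str]:
    if gene_id:
        return [gene_id]
    hits = trees.get(contig)
    if not hits:
        return []
    found = sorted({iv.data for iv in hits[position - 1]})
    if len(found) > 1:
        logger.info("site %s:%d overlaps %d genes; assigned to all", contig, position, len(found))
    return found


def aggregate_genes(
    comparisons: Sequence[SiteComparison],
    gene_models: Sequence[GeneModel],
    thresholds: Thresholds | None = None,
    all_sites: Sequence[EditingSite] | None = None,
) -> list[TargetGene]:
    """Roll target sites up to genes with category, hyper flags and rank.

    Sites map to genes through exon intervals (or a gene id already carried
    from detection). The hyper-editing flags count *all* editing sites of
    each type in the gene — supplied via ``all_sites`` — not only targets,
    since stochastic hyper-editing is a property of the editing landscape,
    not of the differential calls. ``rank_score`` is the sum of z-scores
    over the gene's target sites.
    """
    thresholds = thresholds or Thresholds()
    trees = _exon_trees(gene_models)
    by_gene: dict[str, TargetGene] = {}
    for comp in comparisons:
        if not comp.is_target:
            continue
        for gid in _genes_for(comp.contig, comp.position, comp.gene_id, trees):
            by_gene.setdefault(gid, TargetGene(gene_id=gid)).target_sites.append(comp)
    edit_counts: dict[tuple[str, str], set[tuple[str, int]]] = {}
    for site in all_sites or ():
        for gid in _genes_for(site.contig, site.position, site.gene_id, trees):
            edit_counts.setdefault((gid, site.edit_type), set()).add(
                (site.contig, site.position)
            )
    genes = []
    for gid, tg in sorted(by_gene.items()):
        tg.n_sites_CtoU = sum(1 for c in tg.target_sites if c.edit_type == "CtoU")
        tg.n_sites_AtoI = sum(1 for c in tg.target_sites if c.edit_type == "AtoI")
        if tg.n_sites_CtoU and tg.n_sites_AtoI:
            tg.category = "both"
        elif tg.n_sites_CtoU:
            tg.category = "CtoU_only"
        else:
            tg.category = "AtoI_only"
        tg.hyper_CtoU = (
            len(edit_counts.get((gid, "CtoU"), ())) >= thresholds.hyper_min_sites
        )
        tg.hyper_AtoI = (
            len(edit_counts.get((gid, "AtoI"), ())) >= thresholds.hyper_min_sites
        )
        tg.rank_score = float(sum(c.z_score for c in tg.target_sites))
        genes.append(tg)
    genes.sort(key=lambda g: -g.rank_score)
    return genes


def replicate_site_reproducibility(
    rep_a_sites: Sequence[EditingSite],
    rep_b_sites: Sequence[EditingSite],
    min_rate: float = 0.05,
) -> tuple[float | None, float | None]:
    """Fraction of qualifying sites in one replicate recovered in the other.

    A site qualifies when its editing rate exceeds ``min_rate`` (strictly).
    Returns (A recovered in B, B recovered in A); a direction with no
    qualifying sites is reported as None.
    """

    def _qualifying(sites: Sequence[EditingSite]) -> set[tuple[str, int, str]]:
        return {s.key for s in sites if s.rate > min_rate}

    qa, qb = _qualifying(rep_a_sites), _qualifying(rep_b_sites)

    def _ratio(src: set, dst: set) -> float | None:
        return len(src & dst) / len(src) if src else None

    return _ratio(qa, qb), _ratio(qb, qa)


def downsample_counts(pileup: PileupTable, fraction: float, seed: int) -> PileupTable:
    """Binomially thin every base count to emulate reduced sequencing depth.

    Each count c is replaced by a Binomial(c, fraction) draw; fraction 1 is
    an exact identity. Coverage filters are re-applied by downstream calls,
    not here.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    df = pileup.df.copy()
    if fraction < 1:
        rng = np.random.default_rng(seed)
        for b in BASES:
            df[b] = rng.binomial(df[b].to_numpy(), fraction)
    return PileupTable(sample_id=f"{pileup.sample_id}@{fraction:g}", df=df)
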