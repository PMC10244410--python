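"""Assign sites to genomic feature classes and compare regional distributions.

Each site receives exactly one region. When transcripts disagree (a site
can be exonic in one isoform and intronic in another) the call follows a
fixed precedence — CDS > 3'UTR > 5'UTR > noncoding exon > intron >
intergenic — mirroring the exon-first convention of CLIP-annotation
pipelines. UTR labels require an annotated CDS; noncoding transcripts
contribute only noncoding_exon and intron calls.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from .editing_detection import EditingSite
from .errors import ValidationError
from .io_formats import GeneModel

REGIONS = ("CDS", "3UTR", "5UTR", "noncoding_exon", "intron", "intergenic")
_PRECEDENCE = {r: i for i, r in enumerate(REGIONS)}


@dataclass(frozen=True)
class RegionCall:
    contig: str
    position: int
    edit_type: str
    region: str


def _transcript_region(pos0: int, model: GeneModel) -> str | None:
    if not model.contains(pos0):
        return None
    if not model.in_exon(pos0):
        return "intron"
    if not model.is_coding:
        return "noncoding_exon"
    if any(s <= pos0 < e for s, e in model.cds):
        return "CDS"
    cds_start, cds_end = model.cds[0][0], model.cds[-1][1]
    if model.strand == "+":
        return "3UTR" if pos0 >= cds_end else "5UTR"
    return "3UTR" if pos0 < cds_start else "5UTR"


def annotate_site(site: EditingSite, gene_models: Sequence[GeneModel]) -> RegionCall:
    """Classify one site by the highest-precedence region over transcripts."""
    pos0 = site.position - 1
    best = "intergenic"
    for model in gene_models:
        if model.contig != site.contig:
            continue
        region = _transcript_region(pos0, model)
        if region is not None and _PRECEDENCE[region] < _PRECEDENCE[best]:
            best = region
    return RegionCall(site.contig, site.position, site.edit_type, best)


def annotate_sites(
    sites: Sequence[EditingSite], gene_models: Sequence[GeneModel]
) -> list[RegionCall]:
    return [annotate_site(s, gene_models) for s in sites]


def region_distribution(
    calls_rbp: Sequence[RegionCall], calls_ctrl: Sequence[RegionCall]
) -> pd.DataFrame:
    """Per-region proportions plus a two-sided Fisher enrichment test.

    For each region occurring in either set, the 2x2 table is
    (in-region vs elsewhere) x (RBP vs control); the reported odds ratio is
    the sample odds ratio. Regions absent from both sets are omitted.
    """
    if not calls_rbp or not calls_ctrl:
        raise ValidationError("both call sets must be non-empty")
    n_rbp, n_ctrl = len(calls_rbp), len(calls_ctrl)
    count_rbp = Counter(c.region for c in calls_rbp)
    count_ctrl = Counter(c.region for c in calls_ctrl)
    rows = []
    for region in REGIONS:
        a, c = count_rbp[region], count_ctrl[region]
        if a == 0 and c == 0:
            continue
        table = [[a, n_rbp - a], [c, n_ctrl - c]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "region": region,
                "n_rbp": a,
                "n_ctrl": c,
                "frac_rbp": a / n_rbp,
                "frac_ctrl": c / n_ctrl,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
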