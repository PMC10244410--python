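"""Cross-sample comparisons of target sets.

Overlap significance between two gene (or site) sets uses the
hypergeometric upper tail on a stated universe; sample relatedness is
summarized by the Euclidean distance between binary presence vectors
(the square root of the Hamming distance, i.e. of the symmetric-difference
size), and editing-rate matrices are emitted for ordination by any
standard tool.
"""

from __future__ import annotations

from collections.abc import Hashable, Mapping, Sequence, Set
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .editing_detection import EditingSite
from .errors import ValidationError


@dataclass(frozen=True)
class OverlapResult:
    size_a: int
    size_b: int
    intersection: int
    universe: int
    p_value: float


def overlap_test(
    a: Set[Hashable], b: Set[Hashable], universe: Set[Hashable]
) -> OverlapResult:
    """Hypergeometric upper-tail test of the overlap between two sets.

    p = P(X >= |a & b|) for X ~ Hypergeometric(N=|universe|, K=|a|,
    n=|b|): the chance of seeing at least the observed overlap when b is
    drawn uniformly from the universe.
    """
    a, b, universe = set(a), set(b), set(universe)
    if not a <= universe or not b <= universe:
        raise ValidationError("compared sets must be subsets of the universe")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return OverlapResult(len(a), len(b), k, len(universe), min(p, 1.0))


def binary_distance_matrix(
    samples: Sequence[Set[Hashable]], metric: str = "euclidean"
) -> np.ndarray:
    """Pairwise distances between samples' site sets as presence vectors.

    ``euclidean`` gives sqrt(|symmetric difference|); ``hamming`` the raw
    symmetric-difference size. The matrix is symmetric with a zero
    diagonal.
    """
    if len(samples) < 2:
        raise ValidationError("need at least two samples")
    if metric not in {"euclidean", "hamming"}:
        raise ValidationError(f"unknown metric {metric!r}")
    n = len(samples)
    sets = [set(s) for s in samples]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h = len(sets[i] ^ sets[j])
            out[i, j] = out[j, i] = np.sqrt(h) if metric == "euclidean" else h
    return out


def build_rate_matrix(
    samples: Mapping[str, Sequence[EditingSite]],
    level: str = "site",
    value: str = "rate",
) -> pd.DataFrame:
    """Samples x features matrix of editing rates or presence indicators.

    Features are sites (contig:pos:editType) or genes; columns are sorted
    for a deterministic layout and features missing from a sample are 0.
    At gene level the rate is the maximum site rate within the gene.
    """
    if len(samples) < 2:
        raise ValidationError("need at least two samples")
    if level not in {"site", "gene"} or value not in {"rate", "presence"}:
        raise ValidationError(f"unknown level/value: {level!r}/{value!r}")

    def _feature(site: EditingSite) -> str:
        if level == "site":
            return f"{site.contig}:{site.position}:{site.edit_type}"
        return site.gene_id or f"{site.contig}:unassigned"

    columns = sorted({_feature(s) for sites in samples.values() for s in sites})
    mat = pd.DataFrame(0.0, index=sorted(samples), columns=columns)
    for sample_id in mat.index:
        for site in samples[sample_id]:
            feat = _feature(site)
            if value == "presence":
                mat.loc[sample_id, feat] = 1.0
            else:
                mat.loc[sample_id, feat] = max(mat.loc[sample_id, feat], site.rate)
    return mat
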