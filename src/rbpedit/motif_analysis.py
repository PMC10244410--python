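"""Motif discovery and footprinting around editing sites.

Because the deaminases themselves prefer particular bases (a C in an ACH
context for Apobec1, an A in a WAS context for the ADAR deaminase domain),
any motif analysis that includes the edited base is confounded by enzyme
chemistry. Flank extraction therefore *excludes* the edited base and treats
the up-to-50-nt sequences upstream and downstream of it separately.

Enrichment follows the DREME-style contingency construction: for each
exact k-mer, windows are scored for presence/absence and a one-sided
Fisher exact test compares foreground (target-site flanks) against
background (control-site flanks); the reported E-value is the number of
candidate k-mers times the Fisher p-value.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .editing_detection import EditingSite
from .errors import ValidationError
from .sequence import iupac_code, iupac_regex, normalize_motif, revcomp


@dataclass(frozen=True)
class MotifWindow:
    """Edited-base-excluded sense-strand flanks around one site.

    ``upstream_seq`` ends one nucleotide before the edited base and
    ``downstream_seq`` starts one nucleotide after it; the edited base
    itself never appears. Windows are truncated (not padded) at contig
    ends.
    """

    contig: str
    position: int
    edit_type: str
    upstream_seq: str
    downstream_seq: str

    def side(self, which: str) -> str:
        if which == "upstream":
            return self.upstream_seq
        if which == "downstream":
            return self.downstream_seq
        raise ValidationError(f"unknown side {which!r}")


@dataclass(frozen=True)
class KmerEnrichment:
    kmer: str
    fg_with: int
    fg_without: int
    bg_with: int
    bg_without: int
    p_value: float
    e_value: float


@dataclass
class DistanceProfile:
    """Histogram of site positions relative to their nearest motif match.

    With the ``first_base`` anchor, offset 0 is the motif's first base and
    upstream sites are negative. With ``length_scaled``, the whole motif
    body collapses to offset 0 and downstream offsets shift accordingly,
    so motifs of different lengths become comparable.
    """

    motif: str
    anchor: str
    histogram: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.histogram.values())

    def mass(self, lo: int, hi: int) -> float:
        """Fraction of counted sites with offset in [lo, hi]."""
        if self.total == 0:
            return 0.0
        return sum(v for k, v in self.histogram.items() if lo <= k <= hi) / self.total

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.histogram.items())
        return pd.DataFrame(items, columns=["offset", "count"])


def _sense_window(
    site: EditingSite, reference: Mapping[str, str], w: int
) -> tuple[str, int]:
    """Sense-strand sequence within +-w of a site and the site's index in it."""
    seq = reference[site.contig]
    pos0 = site.position - 1
    lo, hi = max(0, pos0 - w), min(len(seq), pos0 + w + 1)
    window = seq[lo:hi].upper()
    if site.gene_strand == "-":
        return revcomp(window), hi - 1 - pos0
    return window, pos0 - lo


def extract_flanks(
    site: EditingSite, reference: Mapping[str, str], w: int = 50
) -> MotifWindow:
    """Extract the <=w-nt sense-strand flanks, excluding the edited base."""
    window, idx = _sense_window(site, reference, w)
    return MotifWindow(
        contig=site.contig,
        position=site.position,
        edit_type=site.edit_type,
        upstream_seq=window[:idx],
        downstream_seq=window[idx + 1 :],
    )


def flank_seqs(windows: Sequence[MotifWindow], side: str = "both") -> list[str]:
    """Flatten windows into the sequence lists enrichment operates on.

    ``both`` keeps each window as one unit by joining its two flanks with a
    separator that no k-mer can span, preserving the edited-base exclusion.
    """
    if side == "both":
        return [w.upstream_seq + "|" + w.downstream_seq for w in windows]
    return [w.side(side) for w in windows]


def _present_kmers(seq: str, k_values: Sequence[int]) -> set[str]:
    out: set[str] = set()
    n = len(seq)
    for k in k_values:
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            if "|" not in kmer and "N" not in kmer:
                out.add(kmer)
    return out


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Equals the hypergeometric upper tail P(X >= a) with the table's margins
    fixed.
    """
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def kmer_enrichment(
    fg_windows: Sequence[MotifWindow | str],
    bg_windows: Sequence[MotifWindow | str],
    k_range: tuple[int, int] = (4, 8),
    min_fg: int = 2,
    side: str = "both",
) -> list[KmerEnrichment]:
    """Rank exact k-mers enriched in foreground vs background windows.

    Candidates are k-mers (k over the inclusive ``k_range``) present in at
    least ``min_fg`` foreground windows; each is tested on window-level
    presence/absence with a one-sided Fisher exact test, and
    E-value = (number of candidates) x p. Results come back sorted by
    ascending E-value, ties broken by descending foreground support then
    lexicographically.
    """
    if not fg_windows:
        raise ValidationError("empty foreground window set")

    def _as_seqs(windows: Sequence[MotifWindow | str]) -> list[str]:
        if windows and isinstance(windows[0], MotifWindow):
            return flank_seqs(windows, side)  # type: ignore[arg-type]
        return list(windows)  # type: ignore[arg-type]

    fg_seqs, bg_seqs = _as_seqs(fg_windows), _as_seqs(bg_windows)
    k_values = list(range(k_range[0], k_range[1] + 1))
    fg_counts: Counter[str] = Counter()
    for seq in fg_seqs:
        fg_counts.update(_present_kmers(seq, k_values))
    candidates = {kmer for kmer, n in fg_counts.items() if n >= min_fg}
    if not candidates:
        return []
    bg_counts: Counter[str] = Counter()
    for seq in bg_seqs:
        bg_counts.update(_present_kmers(seq, k_values) & candidates)
    n_fg, n_bg, n_cand = len(fg_seqs), len(bg_seqs), len(candidates)
    kmers = sorted(candidates)
    a = np.array([fg_counts[k] for k in kmers])
    c = np.array([bg_counts[k] for k in kmers])
    p = hypergeom.sf(a - 1, n_fg + n_bg, a + c, n_fg)
    results = [
        KmerEnrichment(
            kmer=kmer,
            fg_with=int(ai),
            fg_without=n_fg - int(ai),
            bg_with=int(ci),
            bg_without=n_bg - int(ci),
            p_value=float(pi),
            e_value=float(n_cand * pi),
        )
        for kmer, ai, ci, pi in zip(kmers, a, c, p)
    ]
    results.sort(key=lambda r: (r.e_value, -r.fg_with, r.kmer))
    return results


def deaminase_context(
    sites: Sequence[EditingSite],
    reference: Mapping[str, str],
    k: int = 4,
    min_freq: float = 0.25,
) -> tuple[pd.DataFrame, str]:
    """Position frequency matrix and IUPAC consensus of +-k editing contexts.

    Returns a (2k+1) x 4 column-normalized frequency table indexed by
    offset (-k..k, 0 = edited base) and a consensus string whose letter at
    each offset is the smallest IUPAC code covering every base with
    frequency >= ``min_freq``. N padding at contig ends is ignored.
    """
    from .editing_detection import context_window

    if not sites:
        raise ValidationError("no sites for context analysis")
    offsets = list(range(-k, k + 1))
    counts = np.zeros((2 * k + 1, 4), dtype=float)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for site in sites:
        window = context_window(site, reference, k)
        for i, base in enumerate(window):
            if base in base_idx:
                counts[i, base_idx[base]] += 1
    col_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(col_tot > 0, counts / np.maximum(col_tot, 1), 0.0)
    pfm = pd.DataFrame(freqs, index=offsets, columns=["A", "C", "G", "T"])
    consensus = []
    for i in range(2 * k + 1):
        bases = {b for j, b in enumerate("ACGT") if freqs[i, j] >= min_freq}
        consensus.append(iupac_code(bases) if bases else "N")
    return pfm, "".join(consensus)


def site_motif_distances(
    sites: Sequence[EditingSite],
    motif: str,
    reference: Mapping[str, str],
    w: int = 50,
    anchor: str = "first_base",
) -> DistanceProfile:
    """Profile where editing sites fall relative to a motif.

    For each site, IUPAC ``motif`` occurrences are searched on the sense
    strand within +-w; the site contributes one count at its offset from
    the *nearest* occurrence (distance to the motif body; ties resolved to
    the most upstream occurrence). Sites with no occurrence in range are
    skipped.
    """
    motif = normalize_motif(motif)
    if anchor not in {"first_base", "length_scaled"}:
        raise ValidationError(f"unknown anchor {anchor!r}")
    L = len(motif)
    if L > 2 * w + 1:
        raise ValidationError("motif longer than the search window")
    pattern = iupac_regex(motif)
    profile = DistanceProfile(motif=motif, anchor=anchor)
    for site in sites:
        window, idx = _sense_window(site, reference, w)
        starts = [m.start() for m in _finditer_overlapping(pattern, window)]
        if not starts:
            continue

        def _body_distance(m: int) -> int:
            if m <= idx <= m + L - 1:
                return 0
            return min(abs(idx - m), abs(idx - (m + L - 1)))

        best = min(starts, key=lambda m: (_body_distance(m), m))
        raw = idx - best
        if anchor == "length_scaled":
            if 0 <= raw <= L - 1:
                offset = 0
            elif raw >= L:
                offset = raw - (L - 1)
            else:
                offset = raw
        else:
            offset = raw
        profile.histogram[offset] = profile.histogram.get(offset, 0) + 1
    return profile


def _finditer_overlapping(pattern, text: str):
    pos = 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1
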