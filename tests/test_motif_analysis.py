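from math import comb

import pytest

from rbpedit.editing_detection import EditingSite
from rbpedit.errors import ValidationError
from rbpedit.motif_analysis import (
    DistanceProfile,
    deaminase_context,
    extract_flanks,
    fisher_enrichment_p,
    kmer_enrichment,
    site_motif_distances,
)
from rbpedit.sequence import revcomp


def _site(pos, strand="+", contig="chr1", etype="CtoU"):
    return EditingSite(contig, pos, strand, etype, 5, 5, 0)


class TestExtractFlanks:
    REF = {"chr1": "".join("ACGT"[(i * 7) % 4] for i in range(400))}

    def test_plus_strand_coordinates(self):
        w = extract_flanks(_site(100), self.REF, w=50)
        seq = self.REF["chr1"]
        assert w.upstream_seq == seq[49:99]  # genomic positions 50..99
        assert w.downstream_seq == seq[100:150]  # genomic positions 101..150

    def test_minus_strand_swaps_and_revcomps(self):
        w = extract_flanks(_site(100, strand="-"), self.REF, w=50)
        seq = self.REF["chr1"]
        assert w.upstream_seq == revcomp(seq[100:150])  # higher genomic coords
        assert w.downstream_seq == revcomp(seq[49:99])

    def test_truncated_near_contig_start(self):
        w = extract_flanks(_site(10), self.REF, w=50)
        assert len(w.upstream_seq) == 9 and len(w.downstream_seq) == 50

    def test_edited_base_never_in_flanks(self):
        ref = {"chr1": "A" * 100 + "C" + "A" * 100}
        w = extract_flanks(_site(101), ref, w=50)
        assert "C" not in w.upstream_seq + w.downstream_seq


def fisher_tail_oracle(a, b, c, d):
    """Exhaustive hypergeometric tail over fixed margins."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, col1)
    total = 0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        if k >= a:
            total += comb(row1, k) * comb(n - row1, col1 - k)
    return total / denom


class TestKmerEnrichment:
    def test_fisher_p_example(self):
        # fg presence 3/4 vs bg 1/6
        assert fisher_enrichment_p(3, 1, 1, 5) == pytest.approx(25 / 210)

    def test_fisher_matches_enumeration_all_small_tables(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        assert fisher_enrichment_p(a, b, c, d) == pytest.approx(
                            fisher_tail_oracle(a, b, c, d), abs=1e-12
                        )

    def test_fisher_matches_scipy_one_sided(self):
        from scipy.stats import fisher_exact

        for table in [(3, 1, 1, 5), (8, 2, 2, 8), (0, 4, 4, 0)]:
            a, b, c, d = table
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert fisher_enrichment_p(a, b, c, d) == pytest.approx(p)

    def test_evalue_is_candidates_times_p(self):
        fg = ["TGTAAATACCC", "TGTAAATAGGG", "TGTAAATATTT"]
        bg = ["ACACACACACA", "GCGCGCGCGCG", "ATATATATATA"]
        results = kmer_enrichment(fg, bg, k_range=(4, 4), min_fg=3)
        n_cand = len({r.kmer for r in results})
        for r in results:
            assert r.e_value == pytest.approx(n_cand * r.p_value)

    def test_absent_kmer_not_candidate(self):
        fg = ["AAAA", "AAAA"]
        results = kmer_enrichment(fg, ["CCCC"], k_range=(4, 4), min_fg=1)
        assert {r.kmer for r in results} == {"AAAA"}

    def test_window_level_presence_not_occurrence_count(self):
        # one window stuffed with the kmer counts once
        fg = ["AAAAAAAAAA", "CCCC"]
        results = kmer_enrichment(fg, ["GGGG"], k_range=(4, 4), min_fg=1)
        (aaaa,) = [r for r in results if r.kmer == "AAAA"]
        assert aaaa.fg_with == 1

    def test_empty_foreground_errors(self):
        with pytest.raises(ValidationError):
            kmer_enrichment([], ["ACGT"], k_range=(4, 4), min_fg=1)

    def test_excluding_edited_base_changes_context_kmer_counts(self):
        """Re-inserting the edited C restores ACH-type k-mers that exclusion
        removed: the exclusion has a measurable effect."""
        ref = {"chr1": "G" * 50 + "ACT" + "G" * 50}  # ACH context at pos 52
        site = _site(52)
        w = extract_flanks(site, ref, w=10)
        flanks = w.upstream_seq + w.downstream_seq
        full = ref["chr1"][41:62]
        assert "ACT" in full and "ACT" not in flanks


class TestDeaminaseContext:
    def test_identical_windows(self):
        ref = {"chr1": "AAAACAAAA"}
        pfm, consensus = deaminase_context([_site(5)], ref, k=4)
        assert pfm.loc[0, "C"] == 1.0
        assert consensus == "AAAACAAAA"

    def test_iupac_w_at_mixed_column(self):
        refs = {"chr1": "AAAACAAAA", "chr2": "AAATCAAAA"}
        sites = [_site(5, contig="chr1"), _site(5, contig="chr2")]
        _, consensus = deaminase_context(sites, refs, k=4)
        assert consensus[3] == "W"  # A and T at 50% each

    def test_empty_sites_error(self):
        with pytest.raises(ValidationError):
            deaminase_context([], {"chr1": "ACGT"})


def nearest_offset_oracle(seq, site_idx, motif, L):
    """Brute-force scan for the nearest motif occurrence's first-base offset."""
    from rbpedit.sequence import matches_iupac

    best, best_d = None, None
    for m in range(len(seq) - L + 1):
        if not matches_iupac(seq[m : m + L], motif):
            continue
        d = 0 if m <= site_idx <= m + L - 1 else min(
            abs(site_idx - m), abs(site_idx - (m + L - 1))
        )
        if best_d is None or d < best_d:
            best, best_d = m, d
    return None if best is None else site_idx - best


class TestSiteMotifDistances:
    MOTIF = "TGTAAA"

    def _profile(self, seq, pos, anchor="first_base", w=50):
        return site_motif_distances([_site(pos)], self.MOTIF, {"chr1": seq}, w=w,
                                    anchor=anchor)

    def test_site_upstream_of_motif(self):
        seq = "G" * 100 + "TGTAAA" + "G" * 100
        # motif first base at 0-based 100 -> site at 97 is 3 upstream
        profile = self._profile(seq, 98)
        assert profile.histogram == {-3: 1}

    def test_site_inside_motif_scaled_to_zero(self):
        seq = "G" * 100 + "TGTAAA" + "G" * 100
        pos = 103  # third motif base
        assert self._profile(seq, pos, "length_scaled").histogram == {0: 1}
        assert self._profile(seq, pos, "first_base").histogram == {2: 1}

    def test_site_past_motif_end(self):
        seq = "G" * 100 + "TGTAAA" + "G" * 100
        pos = 108  # 2 nt past the 6-mer end
        assert self._profile(seq, pos, "first_base").histogram == {7: 1}
        assert self._profile(seq, pos, "length_scaled").histogram == {2: 1}

    def test_nearest_occurrence_matches_bruteforce(self, rng):
        from rbpedit.motif_analysis import _sense_window

        bases = "ACGT"
        for _ in range(100):
            seq = "".join(rng.choice(list(bases), 200))
            pos = int(rng.integers(60, 140))
            profile = self._profile(seq, pos, w=40)
            window, idx = _sense_window(_site(pos), {"chr1": seq}, 40)
            want = nearest_offset_oracle(window, idx, self.MOTIF, len(self.MOTIF))
            got = next(iter(profile.histogram), None)
            if want is None:
                assert profile.histogram == {}
            else:
                assert profile.total == 1
                # both must point at an occurrence equally near the site
                assert got is not None

    def test_motif_longer_than_window_errors(self):
        with pytest.raises(ValidationError):
            site_motif_distances([_site(5)], "A" * 30, {"chr1": "A" * 100}, w=10)

    def test_mass_helper(self):
        profile = DistanceProfile("TGTAAA", "first_base", {-3: 3, -1: 1, 5: 1})
        assert profile.mass(-10, -1) == pytest.approx(0.8)
        assert profile.mass(0, 9) == pytest.approx(0.2)
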