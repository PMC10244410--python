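import math

import numpy as np
import pytest

from conftest import make_pileup
from rbpedit.editing_detection import EditingSite
from rbpedit.errors import ValidationError
from rbpedit.io_formats import BASES, GeneModel
from rbpedit.target_calling import (
    Thresholds,
    aggregate_genes,
    call_targets,
    compare_site,
    control_rate_floor,
    downsample_counts,
    replicate_site_reproducibility,
    z_score,
)


def z_oracle(x1, n1, x2, n2):
    """Independent closed-form pooled two-proportion z."""
    p = (x1 + x2) / (n1 + n2)
    if p in (0.0, 1.0):
        return 0.0
    return (x1 / n1 - x2 / n2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))


class TestZScore:
    def test_hand_computed_value(self):
        assert z_score(20, 100, 2, 100) == pytest.approx(4.0679, abs=1e-4)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        for x1, n1, x2, n2 in [(20, 100, 2, 100), (5, 40, 1, 60), (3, 10, 9, 12)]:
            stat, _ = proportions_ztest([x1, x2], [n1, n2])
            assert z_score(x1, n1, x2, n2) == pytest.approx(stat)

    def test_equal_rates_symmetry(self):
        assert z_score(5, 50, 5, 50) == 0.0

    def test_degenerate_pool_is_zero(self):
        assert z_score(0, 50, 0, 50) == 0.0
        assert z_score(50, 50, 50, 50) == 0.0

    def test_zero_coverage_errors(self):
        with pytest.raises(ValidationError):
            z_score(0, 0, 2, 100)


def _site(edit, cov, pos=100, etype="CtoU", gene="gA"):
    return EditingSite("chr1", pos, "+", etype, cov - edit, edit, 0, gene_id=gene)


def is_target_oracle(edit_r, cov_r, edit_c, cov_c, thr):
    """Brute-force predicate evaluator, independent of compare_site."""
    if cov_c < thr.min_coverage:
        return False
    rate_r = edit_r / cov_r
    rate_c_eff = max(edit_c / cov_c, 1.0 / (cov_c + 2))
    z = z_oracle(edit_r, cov_r, edit_c, cov_c)
    z_ok = z > thr.min_z if thr.z_strict else z >= thr.min_z
    return rate_r >= thr.min_rate and rate_r >= thr.min_fold * rate_c_eff and z_ok


class TestCompareSite:
    def test_all_boundaries_inclusive_in_cultured_preset(self):
        # rate exactly 5%, fold exactly 2, z exactly 4: still a target
        thr = Thresholds.cultured()
        # construct: rbp 10/200 = 0.05; ctrl rate 0.025 => fold exactly 2
        comp = compare_site(_site(10, 200), _site(10, 400), thr)
        assert comp.rate_rbp == 0.05 and comp.fold_change == pytest.approx(2.0)
        z = comp.z_score
        exact_thr = Thresholds.cultured(min_z=z)  # place the cutoff at z itself
        assert compare_site(_site(10, 200), _site(10, 400), exact_thr).is_target

    def test_rate_just_below_cutoff_fails(self):
        thr = Thresholds.cultured()
        comp = compare_site(_site(49, 1000), _site(0, 1000), thr)
        assert comp.rate_rbp == pytest.approx(0.049)
        assert not comp.is_target

    def test_derived_example_passes(self):
        comp = compare_site(_site(20, 100), _site(2, 100), Thresholds.cultured())
        assert comp.fold_change == pytest.approx(10.0)
        assert comp.z_score == pytest.approx(4.0679, abs=1e-4)
        assert comp.is_target

    def test_in_vivo_strict_z(self):
        thr = Thresholds.in_vivo()
        comp = compare_site(_site(20, 100), _site(2, 100), thr)
        z_exact = Thresholds.in_vivo(min_z=comp.z_score)
        assert not compare_site(_site(20, 100), _site(2, 100), z_exact).is_target

    def test_low_control_coverage_untestable(self):
        comp = compare_site(_site(20, 100), None, Thresholds.cultured(), ctrl_coverage=3)
        assert comp.untestable and not comp.is_target

    def test_zero_edit_control_uses_continuity_floor(self):
        comp = compare_site(_site(20, 100), _site(0, 98), Thresholds.cultured())
        assert comp.fold_change == pytest.approx(0.2 / control_rate_floor(98))

    def test_matches_bruteforce_oracle_on_random_sites(self, rng):
        thr_grid = [Thresholds.cultured(), Thresholds.in_vivo()]
        for _ in range(2000):
            cov_r = int(rng.integers(5, 200))
            cov_c = int(rng.integers(1, 200))
            edit_r = int(rng.integers(0, cov_r + 1))
            edit_c = int(rng.integers(0, cov_c + 1))
            thr = thr_grid[int(rng.integers(0, 2))]
            comp = compare_site(_site(edit_r, cov_r), _site(edit_c, cov_c), thr)
            assert comp.is_target == is_target_oracle(edit_r, cov_r, edit_c, cov_c, thr)

    def test_threshold_monotonicity_nested_sets(self, rng):
        """Raising any threshold never turns a non-target into a target."""
        sites = []
        for _ in range(300):
            cov_r = int(rng.integers(5, 120))
            cov_c = int(rng.integers(5, 120))
            sites.append((int(rng.integers(0, cov_r + 1)), cov_r,
                          int(rng.integers(0, cov_c + 1)), cov_c))
        grid = [
            Thresholds.cultured(min_rate=r, min_fold=f, min_z=z)
            for r in (0.01, 0.05, 0.10)
            for f in (1.5, 2.0, 3.0)
            for z in (1.0, 4.0, 6.0)
        ]
        def targets(thr):
            return {
                i for i, (er, nr, ec, nc) in enumerate(sites)
                if compare_site(_site(er, nr), _site(ec, nc), thr).is_target
            }
        for a in grid:
            for b in grid:
                if (a.min_rate <= b.min_rate and a.min_fold <= b.min_fold
                        and a.min_z <= b.min_z):
                    assert targets(b) <= targets(a)


GENE = GeneModel("gA", "chr1", "+", exons=((0, 10000),))


def _pileup_rows(spec):
    """spec: {pos: (ref, edited)} with C>T events at coverage ref+edited."""
    return [("chr1", pos, "+", "C", 0, ref, 0, ed) for pos, (ref, ed) in spec.items()]


class TestCallTargets:
    def test_identical_replicates_pooled_equals_per_replicate(self):
        rows = _pileup_rows({100: (80, 20), 200: (95, 5), 300: (99, 1)})
        ctrl = _pileup_rows({100: (99, 1), 200: (99, 1), 300: (99, 1)})
        reps = [make_pileup(rows, "r1"), make_pileup(rows, "r2")]
        ctrls = [make_pileup(ctrl, "c1"), make_pileup(ctrl, "c2")]
        pooled = call_targets(reps, ctrls, [GENE], Thresholds.cultured())
        per_rep = call_targets(reps, ctrls, [GENE], Thresholds.cultured(),
                               mode="per_replicate")
        assert {c.key for c in pooled if c.is_target} == {
            c.key for c in per_rep if c.is_target
        }

    def test_single_replicate_target_union_not_reproducible(self):
        strong = _pileup_rows({100: (60, 40)})
        weak = _pileup_rows({100: (99, 1)})
        ctrl = [make_pileup(_pileup_rows({100: (100, 0)}), "c")]
        result = call_targets(
            [make_pileup(strong, "r1"), make_pileup(weak, "r2")],
            ctrl, [GENE], Thresholds.cultured(), mode="per_replicate",
        )
        (comp,) = [c for c in result if c.position == 100]
        assert comp.is_target and comp.reproducible is False

    def test_planted_differential_sites_recovered_exactly(self):
        planted = {100: (40, 10), 500: (40, 10), 900: (40, 10)}
        flat = {p: (50, 0) for p in (100, 500, 900)}
        shared = {2000 + i * 7: (48, 2) for i in range(20)}  # same both sides
        rbp = [make_pileup(_pileup_rows({**planted, **shared}), f"r{i}") for i in range(2)]
        ctrl = [make_pileup(_pileup_rows({**flat, **shared}), f"c{i}") for i in range(2)]
        result = call_targets(rbp, ctrl, [GENE], Thresholds.cultured())
        assert sorted(c.position for c in result if c.is_target) == [100, 500, 900]


class TestAggregateGenes:
    THR = Thresholds.cultured()

    def _comps(self, specs):
        return [
            compare_site(_site(20, 100, pos=pos, etype=etype), _site(0, 100), self.THR)
            for pos, etype in specs
        ]

    def test_category_both(self):
        genes = aggregate_genes(
            self._comps([(100, "CtoU"), (200, "AtoI")]), [GENE], self.THR
        )
        assert len(genes) == 1 and genes[0].category == "both"

    @pytest.mark.parametrize("n_sites,expected", [(19, False), (20, True)])
    def test_hyper_editing_boundary(self, n_sites, expected):
        comps = self._comps([(100, "CtoU")])
        all_sites = [_site(2, 50, pos=100 + 3 * i) for i in range(n_sites)]
        (gene,) = aggregate_genes(comps, [GENE], self.THR, all_sites=all_sites)
        assert gene.hyper_CtoU is expected and gene.hyper_AtoI is False

    def test_rank_score_is_sum_of_z(self):
        comps = self._comps([(100, "CtoU"), (200, "CtoU")])
        (gene,) = aggregate_genes(comps, [GENE], self.THR)
        assert gene.rank_score == pytest.approx(sum(c.z_score for c in comps))
        assert gene.rank_score > 0

    def test_gene_with_no_targets_absent(self):
        comp = compare_site(_site(2, 100), _site(2, 100), self.THR)
        assert not comp.is_target
        assert aggregate_genes([comp], [GENE], self.THR) == []


class TestReproducibility:
    def _sites(self, specs):
        return [_site(int(r * 100), 100, pos=p) for p, r in specs]

    def test_identical_lists(self):
        a = self._sites([(1, 0.2), (2, 0.3)])
        assert replicate_site_reproducibility(a, a) == (1.0, 1.0)

    def test_disjoint_lists(self):
        a = self._sites([(1, 0.2)])
        b = self._sites([(9, 0.2)])
        assert replicate_site_reproducibility(a, b) == (0.0, 0.0)

    def test_partial_overlap_ratio(self):
        a = self._sites([(1, 0.2), (2, 0.2), (3, 0.2), (4, 0.2)])
        b = self._sites([(1, 0.2), (2, 0.2), (3, 0.2), (9, 0.2)])
        assert replicate_site_reproducibility(a, b) == (0.75, 0.75)

    def test_rate_cutoff_is_strict(self):
        a = self._sites([(1, 0.05)])  # exactly 5% does not qualify
        assert replicate_site_reproducibility(a, a) == (None, None)


class TestDownsampling:
    def test_fraction_one_is_identity(self):
        pileup = make_pileup(_pileup_rows({100: (80, 20)}))
        out = downsample_counts(pileup, 1.0, seed=3)
        assert out.df[list(BASES)].equals(pileup.df[list(BASES)])

    def test_fixed_seed_reproducible(self):
        pileup = make_pileup(_pileup_rows({100: (8000, 2000)}))
        a = downsample_counts(pileup, 0.25, seed=11)
        b = downsample_counts(pileup, 0.25, seed=11)
        assert a.df.equals(b.df)

    def test_binomial_moments(self):
        pileup = make_pileup([("chr1", 100, "+", "C", 0, 10000, 0, 0)])
        out = downsample_counts(pileup, 0.25, seed=5)
        c = int(out.df["C"].iloc[0])
        sigma = math.sqrt(10000 * 0.25 * 0.75)
        assert abs(c - 2500) <= 3 * sigma

    def test_invalid_fraction(self):
        pileup = make_pileup(_pileup_rows({100: (80, 20)}))
        for frac in (0.0, -0.5, 1.5):
            with pytest.raises(ValidationError):
                downsample_counts(pileup, frac, seed=1)

    def test_target_count_non_increasing_in_expectation(self):
        """Fewer reads cannot create targets: compare full vs 25% depth."""
        planted = {100 + 10 * i: (160, 40) for i in range(30)}
        rbp = [make_pileup(_pileup_rows(planted), "r")]
        ctrl = [make_pileup(_pileup_rows({p: (200, 0) for p in planted}), "c")]
        full = call_targets(rbp, ctrl, [GENE], Thresholds.cultured())
        n_full = sum(c.is_target for c in full)
        counts = []
        for seed in range(5):
            down = [downsample_counts(rbp[0], 0.25, seed=seed)]
            res = call_targets(down, ctrl, [GENE], Thresholds.cultured())
            counts.append(sum(c.is_target for c in res))
        assert np.mean(counts) <= n_full
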