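"""ASE statistics against exhaustive oracles, and the filter cascades."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triallele import ase
from triallele.io import GenomicInterval
from triallele.simulate import AseEffectSpec, generate_ase_counts


# ------------------------------------------------------------ oracles

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: (math.comb(c1, k) * math.comb(n - c1, r1 - k)
               / math.comb(n, r1)) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)
    u_obs = u_stat(x, y)
    us = [u_stat([pooled[i] for i in comb],
                 [pooled[i] for i in range(len(pooled)) if i not in comb])
          for comb in itertools.combinations(range(len(pooled)), n1)]
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestPooledFisher:
    def test_balanced_table(self):
        assert ase.pooled_fisher(5, 5, 5, 5) == 1.0

    def test_matches_hypergeometric_oracle(self):
        assert ase.pooled_fisher(12, 2, 3, 11) == pytest.approx(
            fisher_oracle(12, 2, 3, 11), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 12, 4)
            if a + b == 0 or c + d == 0:
                continue
            assert ase.pooled_fisher(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-9)

    def test_zero_total_cross_rejected(self):
        with pytest.raises(ValueError):
            ase.pooled_fisher(0, 0, 5, 5)


class TestLogRatio:
    @pytest.mark.parametrize("ref,alt,expect", [
        (8, 2, 2.0),
        (4, 4, 0.0),
        (10, 0, math.log2(10.5 / 0.5)),
        (0, 10, -math.log2(10.5 / 0.5)),
    ])
    def test_values(self, ref, alt, expect):
        assert ase.log_ratio(ref, alt) == pytest.approx(expect)

    def test_both_zero_excluded(self):
        with pytest.raises(ValueError):
            ase.log_ratio(0, 0)


class TestMwu:
    def test_identical_groups(self):
        p, diff = ase.mwu_reciprocal_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0 and diff == 0.0

    def test_complete_separation_small_n(self):
        p, diff = ase.mwu_reciprocal_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2/20, two-sided exact
        assert diff == pytest.approx(-3.0)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2),
                                            (2, 6, 3)])
    def test_exact_p_matches_permutation_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            x = rng.permutation(np.arange(n1 + n2, dtype=float))[:n1]
            y = np.setdiff1d(np.arange(n1 + n2, dtype=float), x)
            p, _ = ase.mwu_reciprocal_test(x, y)
            assert p == pytest.approx(mwu_exact_oracle(x, y), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ase.mwu_reciprocal_test([], [1.0])


class TestBinomialTest:
    def test_balanced(self):
        assert ase.binomial_allele_test(5, 5) == 1.0

    def test_nine_one(self):
        # exact tail enumeration of Binomial(10, 1/2): outcomes with
        # probability <= P(9) are {0,1,9,10}, total mass 22/1024
        assert ase.binomial_allele_test(9, 1) == pytest.approx(22 / 1024)

    def test_extreme_tail_closed_form(self):
        assert ase.binomial_allele_test(0, 20) == pytest.approx(2 * 0.5**20)


class TestDownsampling:
    def _table(self, totals, ref_frac=0.5, tissue="DS", cross="MarineXLong"):
        rows = []
        for i, t in enumerate(totals):
            ref = int(round(t * ref_frac))
            rows.append(("s1", "chrI", 100, "g1", True, cross, tissue,
                         f"lib{i}", f"f{i}", ref, t - ref, "ref"))
        return pd.DataFrame(rows, columns=[
            "snp_id", "chrom", "pos", "gene_id", "exonic", "cross", "tissue",
            "library_id", "individual_id", "ref_count", "alt_count",
            "fw_allele"])

    def test_at_or_below_median_unchanged(self):
        t = self._table([10, 20, 30, 40, 50])
        out = ase.downsample_to_median(t, seed=1)
        med_mask = (t.ref_count + t.alt_count) <= 30
        pd.testing.assert_frame_equal(out[med_mask], t[med_mask])

    def test_equal_depths_unchanged(self):
        t = self._table([20] * 6)
        pd.testing.assert_frame_equal(ase.downsample_to_median(t, seed=0), t)

    def test_never_increases_counts(self):
        t = self._table([10, 20, 400, 800])
        out = ase.downsample_to_median(t, seed=3)
        assert (out.ref_count <= t.ref_count).all()
        assert (out.alt_count <= t.alt_count).all()

    def test_thinning_preserves_expected_ratio(self):
        t = self._table([100, 100, 100, 400], ref_frac=0.5)
        fracs = []
        for seed in range(400):
            out = ase.downsample_to_median(t, seed=seed)
            row = out.iloc[3]
            tot = row.ref_count + row.alt_count
            if tot > 0:
                fracs.append(row.ref_count / tot)
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.5) < 3 * se
        # expected thinned total equals the group median
        assert np.mean([ase.downsample_to_median(t, seed=s).iloc[3][
            ["ref_count", "alt_count"]].sum() for s in range(100)]) == \
            pytest.approx(100, rel=0.05)


class TestEligibility:
    def _counts(self, n_informative, n_total=24):
        rows = []
        for i in range(n_total):
            ref, alt = (10, 10) if i < n_informative else (10, 1)
            rows.append(("s1", "chrI", 1, "g1", True, "MarineXLong", "DS",
                         f"lib{i}", f"f{i}", ref, alt, "ref"))
        return pd.DataFrame(rows, columns=[
            "snp_id", "chrom", "pos", "gene_id", "exonic", "cross", "tissue",
            "library_id", "individual_id", "ref_count", "alt_count",
            "fw_allele"])

    def test_twenty_of_twentyfour_kept(self):
        assert ase.filter_eligible_snps(self._counts(24)) == ["s1"]
        assert ase.filter_eligible_snps(self._counts(20)) == ["s1"]

    def test_nineteen_of_twentyfour_dropped(self):
        assert ase.filter_eligible_snps(self._counts(19)) == []

    def test_minor_allele_fraction_rule(self):
        # (100, 3): 3 reads >= min_reads but 3/103 < 5%, so not informative
        t = self._counts(24)
        t.loc[0, ["ref_count", "alt_count"]] = [100, 3]
        t.loc[1:, "alt_count"] = 10
        # 23 informative of 24 -> still kept; drop 4 more to go below 20
        assert ase.filter_eligible_snps(t) == ["s1"]
        t.loc[1:4, ["ref_count", "alt_count"]] = [100, 3]
        assert ase.filter_eligible_snps(t) == []


def _stats_row(snp, tissue, mwu_p, diff, exonic=True, total=3000, **kw):
    row = {"snp_id": snp, "tissue": tissue, "chrom": "chrI", "pos": 1,
           "gene_id": "g1", "exonic": exonic, "total_reads": total,
           "mwu_p": mwu_p, "diff_ase": diff, "fisher_p": mwu_p,
           "binom_p_MarineXLong": 0.5, "binom_p_MarineXShort": 0.5,
           "mean_lr_long": diff / 2, "mean_lr_short": -diff / 2,
           "ref_MarineXLong": 100, "alt_MarineXLong": 100,
           "ref_MarineXShort": 100, "alt_MarineXShort": 100}
    row.update(kw)
    return row


class TestSpineCandidateFilter:
    def _frame(self, ds, ps, pf, h, **kw):
        return pd.DataFrame([
            _stats_row("s1", "DS", *ds, **kw), _stats_row("s1", "PS", *ps, **kw),
            _stats_row("s1", "PF", *pf, **kw), _stats_row("s1", "H", *h, **kw)])

    def test_concordant_spines_quiet_controls_kept(self):
        f = self._frame((0.01, 1.5), (0.02, 1.2), (0.4, 0.1), (0.6, -0.2))
        assert ase.spine_candidate_filter(f) == ["s1"]

    def test_discordant_sign_dropped(self):
        f = self._frame((0.01, 1.5), (0.02, -1.2), (0.4, 0.1), (0.6, -0.2))
        assert ase.spine_candidate_filter(f) == []

    def test_depth_outlier_dropped(self):
        f = self._frame((0.01, 1.5), (0.02, 1.2), (0.4, 0.1), (0.6, -0.2),
                        total=6000)
        assert ase.spine_candidate_filter(f) == []

    def test_active_control_tissue_dropped(self):
        f = self._frame((0.01, 1.5), (0.02, 1.2), (0.01, 0.1), (0.6, -0.2))
        assert ase.spine_candidate_filter(f) == []
        f = self._frame((0.01, 1.5), (0.02, 1.2), (0.4, 1.5), (0.6, -0.2))
        assert ase.spine_candidate_filter(f) == []

    def test_non_exonic_dropped(self):
        f = self._frame((0.01, 1.5), (0.02, 1.2), (0.4, 0.1), (0.6, -0.2),
                        exonic=False)
        assert ase.spine_candidate_filter(f) == []

    def test_missing_tissue_excluded(self):
        f = self._frame((0.01, 1.5), (0.02, 1.2), (0.4, 0.1),
                        (0.6, -0.2)).iloc[:3]
        assert ase.spine_candidate_filter(f) == []


class TestReciprocalGeneFilter:
    def test_planted_reciprocal_genes_recovered(self):
        spec = AseEffectSpec(n_genes=10, frac_reciprocal=0.5, seed=21)
        counts, truth = generate_ase_counts(spec)
        stats_df = ase.compute_snp_stats(counts, seed=1)
        calls, _ = ase.reciprocal_gene_filter(stats_df)
        called = {c.gene_id for c in calls}
        planted = set(truth.gene_id[truth.reciprocal])
        assert planted <= called
        assert all(c.passes_2snp for c in calls if c.gene_id in planted)

    def test_single_snp_gene_stringency_flags(self):
        row = _stats_row("s1", "DS", 0.001, 1.6, fisher_p=0.001,
                         binom_p_MarineXLong=0.001,
                         binom_p_MarineXShort=0.001)
        calls, snps = ase.reciprocal_gene_filter(pd.DataFrame([row]))
        assert snps == ["s1"]
        assert calls[0].passes_1snp and not calls[0].passes_2snp

    def test_fold_change_threshold(self):
        row = _stats_row("s1", "DS", 0.001, 0.9, fisher_p=0.001,
                         binom_p_MarineXLong=0.001,
                         binom_p_MarineXShort=0.001)
        calls, _ = ase.reciprocal_gene_filter(pd.DataFrame([row]))
        assert calls == []  # |diff| < log2(2)


class TestProximityEnrichment:
    def _universe(self, n=40):
        return {f"g{i}": GenomicInterval("chrI", i * 200_000,
                                         i * 200_000 + 1000)
                for i in range(n)}

    def test_saturated_universe(self):
        uni = self._universe(10)
        regions = [GenomicInterval("chrI", 0, 2_000_000)]
        obs, exp, p = ase.proximity_enrichment(
            list(uni)[:4], uni, regions, window_bp=50_000, n_perm=200, seed=0)
        assert obs == 4 and p == 1.0 and exp == pytest.approx(4.0)

    def test_empty_regions(self):
        uni = self._universe(10)
        obs, _, p = ase.proximity_enrichment(list(uni)[:3], uni, [],
                                             n_perm=100, seed=0)
        assert obs == 0 and p == 1.0

    def test_called_set_from_near_genes_is_enriched(self):
        uni = self._universe(100)
        # regions near the first 10 genes only
        regions = [GenomicInterval("chrI", i * 200_000, i * 200_000 + 10)
                   for i in range(10)]
        called = [f"g{i}" for i in range(10)]
        obs, exp, p = ase.proximity_enrichment(called, uni, regions,
                                               window_bp=50_000,
                                               n_perm=5000, seed=3)
        assert obs == 10 and exp < 2.0 and p < 0.001

    def test_seeded_permutation_invariant_to_universe_order(self):
        uni = self._universe(30)
        regions = [GenomicInterval("chrI", 0, 1_000_000)]
        called = ["g1", "g2", "g7"]
        shuffled = dict(reversed(list(uni.items())))
        r1 = ase.proximity_enrichment(called, uni, regions, n_perm=500, seed=9)
        r2 = ase.proximity_enrichment(called, shuffled, regions, n_perm=500,
                                      seed=9)
        assert r1 == r2

    def test_called_larger_than_universe_rejected(self):
        uni = self._universe(3)
        with pytest.raises(ValueError):
            ase.proximity_enrichment(["g0", "g1", "g2", "gX"], uni, [],
                                     n_perm=10, seed=0)
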