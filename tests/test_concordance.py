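"""Unit, oracle and property tests for the agreement statistics."""

import itertools
import math

import numpy as np
import pytest

from rscore import (
    EmptyResultError,
    UndefinedMetricError,
    ValidationError,
    VariantCall,
    compare_groups,
    compute_ppa,
    correlate_vaf,
    generate_paired_vaf,
    match_calls,
    quadrant_analysis,
    rscore_cutoff_sweep,
)
from rscore.concordance import PairedCallRecord


def call(sample, vid, vclass, platform, detected=True, vaf=2.0, mapd=None):
    return VariantCall(
        sample_id=sample,
        variant_id=vid,
        variant_class=vclass,
        platform=platform,
        detected=detected,
        vaf_percent=vaf if detected else None,
        mapd=mapd,
    )


def record(vaf=2.0, mapd=0.3, detected=True, sample="S1", vclass="L858R"):
    return PairedCallRecord(
        sample_id=sample,
        variant_class=vclass,
        reference_platform="dpcr",
        comparison_platform="ngs",
        reference_vaf_percent=vaf,
        comparison_detected=detected,
        comparison_vaf_percent=vaf * 1.1 if detected else None,
        mapd=mapd,
        r_score=math.log10(mapd / vaf) if mapd and mapd > 0 and vaf > 0 else None,
    )


class TestMatchCalls:
    def test_same_variant_is_concordant(self):
        recs = match_calls(
            [call("S1", "EGFR L858R", "L858R", "dpcr")],
            [call("S1", "EGFR L858R", "L858R", "ngs", mapd=0.3)],
        )
        assert len(recs) == 1 and recs[0].concordant
        assert recs[0].mapd == 0.3
        assert recs[0].r_score == pytest.approx(math.log10(0.3 / 2.0))

    def test_exon19_deletions_match_by_class_not_allele(self):
        ref = [call("S1", "ex19del c.2235_2249del", "ex19del", "dpcr")]
        cmp = [call("S1", "ex19del c.2236_2250del", "ex19del", "ngs")]
        assert match_calls(ref, cmp, level="variant_class")[0].concordant
        assert not match_calls(ref, cmp, level="exact_variant")[0].concordant
        # the mixed default treats ex19del at class level
        assert match_calls(ref, cmp, level="auto")[0].concordant

    def test_absent_comparison_call_is_discordant(self):
        recs = match_calls([call("S1", "EGFR T790M", "T790M", "dpcr")], [])
        assert len(recs) == 1 and not recs[0].concordant
        assert recs[0].comparison_vaf_percent is None

    def test_undetected_comparison_call_contributes_its_sample_mapd(self):
        recs = match_calls(
            [call("S1", "EGFR T790M", "T790M", "dpcr", vaf=1.0)],
            [call("S1", "EGFR T790M", "T790M", "ngs", detected=False, mapd=0.4)],
        )
        assert not recs[0].concordant
        assert recs[0].mapd == 0.4
        assert recs[0].r_score == pytest.approx(math.log10(0.4))

    def test_duplicate_reference_calls_rejected(self):
        ref = [call("S1", "EGFR L858R", "L858R", "dpcr")] * 2
        with pytest.raises(ValidationError, match="duplicate"):
            match_calls(ref, [])

    def test_nonpositive_reference_call_rejected(self):
        with pytest.raises(ValidationError):
            match_calls([call("S1", "x", "x", "dpcr", detected=False, vaf=None)], [])


class TestPpa:
    @pytest.mark.parametrize(
        "c,d,expected", [(91, 46, 66.42), (28, 24, 53.85), (0, 5, 0.0)]
    )
    def test_point_estimates_match_printed_values(self, c, d, expected):
        assert round(compute_ppa(c, d).ppa_percent, 2) == expected

    def test_undefined_for_zero_counts(self):
        with pytest.raises(UndefinedMetricError):
            compute_ppa(0, 0)

    @pytest.mark.parametrize("method", ["clopper_pearson", "wald"])
    def test_ci_contains_point_estimate(self, method):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 200))
            c = int(rng.integers(0, n + 1))
            est = compute_ppa(c, n - c, ci_method=method)
            assert est.ci_low_percent <= est.ppa_percent + 1e-9
            assert est.ppa_percent <= est.ci_high_percent + 1e-9

    def test_ci_width_shrinks_with_sample_size(self):
        small = compute_ppa(9, 5)
        large = compute_ppa(900, 500)
        assert (large.ci_high_percent - large.ci_low_percent) < (
            small.ci_high_percent - small.ci_low_percent
        )

    def test_equals_brute_force_count(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            flags = rng.random(int(rng.integers(1, 60))) < rng.random()
            est = compute_ppa(int(flags.sum()), int((~flags).sum()))
            assert est.ppa_percent == pytest.approx(100.0 * sum(flags) / len(flags))


class TestQuadrants:
    def test_partition_and_concordant_counts_reconcile(self):
        rng = np.random.default_rng(3)
        recs = [
            record(
                vaf=float(10 ** rng.normal(0.27, 0.5)),
                mapd=float(rng.gamma(4, 0.08)),
                detected=bool(rng.random() < 0.6),
                sample=f"S{i}",
            )
            for i in range(200)
        ]
        res = quadrant_analysis(recs)
        totals = [p.n_total for p in res.quadrants.values() if p is not None]
        concs = [p.n_concordant for p in res.quadrants.values() if p is not None]
        assert sum(totals) == res.n_records == len(recs)
        assert sum(concs) == sum(r.concordant for r in recs)

    def test_boundary_record_goes_to_low_side(self):
        recs = [record(vaf=1.0, mapd=0.5, sample="S1"), record(vaf=10.0, mapd=0.9, sample="S2")]
        res = quadrant_analysis(recs, vaf_cut_log10=0.0, mapd_cut_log10=math.log10(0.5))
        assert res.quadrants[("low", "low")].n_total == 1
        assert res.quadrants[("high", "high")].n_total == 1

    def test_all_concordant_gives_full_ppa_in_nonempty_quadrants(self):
        recs = [record(vaf=v, mapd=m, detected=True, sample=f"S{v}{m}")
                for v in (0.5, 5.0) for m in (0.2, 0.6)]
        res = quadrant_analysis(recs)
        for p in res.quadrants.values():
            if p is not None:
                assert p.ppa_percent == 100.0

    def test_all_records_without_mapd_rejected(self):
        recs = [record(mapd=None)]
        with pytest.raises(EmptyResultError):
            quadrant_analysis(recs)


class TestSweep:
    def test_all_concordant_gives_constant_ppa_and_undefined_correlation(self):
        recs = [record(vaf=v, detected=True, sample=f"S{v}") for v in (0.2, 1.0, 5.0, 20.0)]
        res = rscore_cutoff_sweep(recs)
        for p in res.ppa_at_cutoff:
            if p is not None:
                assert p.ppa_percent == 100.0
        assert res.correlation_r is None

    def test_empty_subset_marked_undefined(self):
        recs = [record(vaf=0.2, mapd=0.9, sample="S1")]  # r_score ~ 0.65 > all cutoffs
        res = rscore_cutoff_sweep(recs, cutoffs=[-1.0, 0.0, 1.0])
        assert res.ppa_at_cutoff[0] is None and res.ppa_at_cutoff[1] is None
        assert res.ppa_at_cutoff[2].n_total == 1

    def test_undefined_rscores_excluded_and_counted(self):
        recs = [record(sample="S1"), record(mapd=None, sample="S2")]
        res = rscore_cutoff_sweep(recs)
        assert res.n_excluded_undefined_rscore == 1

    def test_nonincreasing_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            rscore_cutoff_sweep([record()], cutoffs=[0.0, 0.0])


def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided p over all rank assignments."""
    pooled = sorted(a + b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    mean_u = n_a * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in grp_a for y in grp_b if x > y) + 0.5 * sum(
            1 for x in grp_a for y in grp_b if x == y
        )
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_identical_groups_show_no_shift(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_of_three_vs_three(self):
        # 2 / C(6,3) = 2/20 rank assignments are at least as extreme
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_groups(a, b)
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(exact_rank_sum_p(a, b))

    def test_matches_enumeration_oracle_on_small_untied_samples(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n_a, n_b = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            vals = rng.permutation(np.arange(1.0, 30.0))  # distinct -> no ties
            a, b = list(vals[:n_a]), list(vals[n_a : n_a + n_b])
            res = compare_groups(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_rank_sum_p(a, b))

    def test_separated_lognormal_groups_detected(self):
        rng = np.random.default_rng(5)
        conc = np.exp(rng.normal(math.log(2.0), 0.8, 50))
        disc = np.exp(rng.normal(math.log(0.5), 0.8, 50))
        assert compare_groups(conc, disc).p_value < 1e-3

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        a = 10 ** rng.normal(0.3, 0.5, 40)
        b = 10 ** rng.normal(0.0, 0.5, 35)
        raw = compare_groups(a, b)
        logged = compare_groups(np.log(a), np.log(b))
        assert raw.p_value == pytest.approx(logged.p_value)
        assert raw.u_statistic == pytest.approx(logged.u_statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([], [1.0])


class TestCorrelateVaf:
    def test_monotone_pairs(self):
        pairs = [(0.1, 0.2), (1.0, 1.5), (5.0, 6.0), (20.0, 30.0)]
        r, p, n, excl = correlate_vaf(pairs)
        assert r == pytest.approx(1.0)
        assert n == 4 and excl == 0

    def test_anti_monotone_pairs(self):
        pairs = [(0.1, 30.0), (1.0, 6.0), (5.0, 1.5), (20.0, 0.2)]
        assert correlate_vaf(pairs)[0] == pytest.approx(-1.0)

    def test_missing_members_excluded_and_counted(self):
        pairs = [(1.0, 2.0), (None, 3.0), (2.0, None), (4.0, 5.0), (6.0, 7.0)]
        r, p, n, excl = correlate_vaf(pairs)
        assert n == 3 and excl == 2

    def test_too_few_complete_pairs_rejected(self):
        with pytest.raises(ValidationError):
            correlate_vaf([(1.0, 2.0), (3.0, None)])

    def test_copula_generator_recovers_target_rank_correlation(self):
        pairs = generate_paired_vaf(10_000, rank_corr=0.9, seed=21)
        r, _, _, _ = correlate_vaf(pairs)
        assert r == pytest.approx(0.9, abs=0.02)
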