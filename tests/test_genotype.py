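"""Genotype statistics: fragment conversion, summaries, stability, Wilcoxon."""

import itertools
import math

import numpy as np
import pytest

from cng_screen.genotype import (
    POLYMORPHIC,
    STABLE,
    AlleleCall,
    CohortTable,
    catalog_alleles,
    catalog_report,
    classify_stability,
    compare_cohorts,
    expected_heterozygosity,
    fragment_to_units,
    load_external_catalog,
    locus_summary,
    rank_sum_test,
    read_calls_tsv,
    read_summary_tsv,
    signed_rank_test,
    stability_from_range,
    summarize_cohort,
    write_summary_tsv,
)


def calls(pairs, locus="L1"):
    return [AlleleCall(f"s{i}", locus, a, b) for i, (a, b) in enumerate(pairs)]


class TestFragmentConversion:
    @pytest.mark.parametrize("frag,flank,unit,expected",
                             [(100, 70, 3, 10), (73, 70, 3, 1), (101.4, 70, 3, 10),
                              (70 + 3 * 17, 70, 3, 17), (90, 70, 4, 5)])
    def test_rounding(self, frag, flank, unit, expected):
        assert fragment_to_units(frag, flank, unit) == expected

    def test_off_grid_residual_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            fragment_to_units(101.4, 70, 3)
        assert "off the repeat grid" in caplog.text

    def test_fragment_not_exceeding_flank_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            fragment_to_units(70, 70, 3)


class TestLocusSummary:
    def test_monomorphic(self):
        s = locus_summary(calls([(12, 12)] * 10))
        assert (s.min_units, s.max_units, s.n_alleles, s.hi) == (12, 12, 1, 0.0)
        assert (s.mean, s.sd, s.n_chromosomes) == (12.0, 0.0, 20)
        assert s.expected_het == 0.0

    def test_hand_computed_mixture(self):
        s = locus_summary(calls([(10, 12), (12, 12), (10, 10), (10, 12)]))
        assert s.hi == 0.5
        assert s.mode == 10  # tie over {10 x4, 12 x4} breaks toward the smaller
        assert (s.mean, s.median) == (11.0, 11.0)
        assert (s.n_chromosomes, s.n_alleles) == (8, 2)
        assert s.expected_het == pytest.approx(0.5)

    def test_single_heterozygous_sample(self):
        s = locus_summary(calls([(10, 14)]))
        assert (s.hi, s.min_units, s.max_units) == (1.0, 10, 14)

    def test_sample_sd_and_even_median(self):
        s = locus_summary(calls([(10, 11), (13, 14)]))
        assert s.median == 12.0
        assert s.sd == pytest.approx(np.std([10, 11, 13, 14], ddof=1))

    def test_invariant_under_order_and_allele_swap(self):
        base = calls([(10, 12), (11, 15), (9, 9)])
        swapped = [AlleleCall(c.sample, c.locus, c.a2, c.a1) for c in base]
        assert locus_summary(base) == locus_summary(swapped)
        assert locus_summary(list(reversed(base))) == locus_summary(base)

    def test_empty_or_mixed_locus_rejected(self):
        with pytest.raises(ValueError, match="no calls"):
            locus_summary([])
        with pytest.raises(ValueError, match="multiple loci"):
            locus_summary(calls([(1, 2)]) + calls([(1, 2)], locus="L2"))

    def test_hi_bounds_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pairs = [tuple(rng.integers(5, 20, 2)) for _ in range(30)]
            s = locus_summary(calls(pairs))
            assert 0.0 <= s.hi <= 1.0
            assert (s.hi == 0.0) == all(a == b for a, b in pairs)
            assert (s.hi == 1.0) == all(a != b for a, b in pairs)
            assert s.min_units <= s.mode <= s.max_units
            assert s.min_units <= s.median <= s.max_units
            assert s.min_units <= s.mean <= s.max_units


class TestStability:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(18, 23, STABLE), (6, 29, POLYMORPHIC), (12, 12, STABLE),
         (10, 16, STABLE), (10, 17, POLYMORPHIC)],
    )
    def test_span_rule(self, lo, hi, expected):
        assert stability_from_range(lo, hi) == expected

    def test_monotone_in_span(self):
        for lo in range(5, 15):
            state = STABLE
            for hi in range(lo, lo + 30):
                now = stability_from_range(lo, hi)
                assert not (state == POLYMORPHIC and now == STABLE)
                state = now

    def test_override_forces_polymorphic(self):
        s = locus_summary(calls([(11, 13), (12, 17)], locus="RAI1"), locus="RAI1")
        assert classify_stability(s) == STABLE
        assert classify_stability(s, overrides=("RAI1",)) == POLYMORPHIC


def exact_rank_sum_pvalue(x, y):
    """Two-sided p by full enumeration of rank assignments (no ties)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mid = len(x) * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total


def exact_signed_rank_pvalue(d, alternative="two-sided"):
    """P by full enumeration of sign patterns on the rank magnitudes."""
    d = [v for v in d if v != 0]
    mags = sorted(abs(v) for v in d)
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    w_obs = sum(ranks[abs(v)] for v in d if v > 0)
    n = len(d)
    mid = n * (n + 1) / 4
    count = total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(sorted(ranks.values()), signs) if s)
        total += 1
        if alternative == "greater":
            hit = w >= w_obs
        elif alternative == "less":
            hit = w <= w_obs
        else:
            hit = abs(w - mid) >= abs(w_obs - mid) - 1e-12
        count += hit
    return count / total


class TestWilcoxon:
    def test_most_extreme_rank_assignment(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments

    def test_identical_multisets_give_p_one(self):
        res = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_signed_rank_all_positive_small(self):
        res = signed_rank_test([2.0, 1.0, 3.0], alternative="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 8)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            rank_sum_test([1], [2, 3])

    def test_rank_sum_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n1, n2 = rng.integers(2, 5, 2)
            pool = rng.permutation(20)[: n1 + n2]  # distinct values, no ties
            x, y = list(pool[:n1]), list(pool[n1:])
            res = rank_sum_test(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_rank_sum_pvalue(x, y))

    def test_signed_rank_matches_enumeration_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            mags = 1 + rng.permutation(30)[:n]  # distinct magnitudes
            d = mags * rng.choice([-1, 1], size=n)
            res = signed_rank_test(d.astype(float))
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_signed_rank_pvalue(list(d)))

    def test_tied_data_uses_midrank_normal_approximation(self):
        x = [10] * 10 + [12] * 10
        y = [10] * 8 + [12] * 12
        res = rank_sum_test(x, y)
        assert res.method == "normal-approx"
        assert 0.0 < res.p_value <= 1.0


class TestCompareCohorts:
    def make_cohorts(self):
        a = CohortTable("ctrl", tuple(calls([(10, 12), (11, 13), (10, 10)], "L1")
                                      + calls([(5, 6), (6, 7), (5, 5)], "L2")))
        b = CohortTable("case", tuple(calls([(14, 16), (15, 17), (18, 18)], "L1")
                                      + calls([(5, 6), (6, 7), (5, 5)], "L2")))
        return a, b

    def test_rank_sum_at_one_locus(self):
        a, b = self.make_cohorts()
        res = compare_cohorts(a, b, "L1")
        assert res.n_a == res.n_b == 6
        assert res.p_value < 0.05  # clearly shifted distributions

    def test_signed_rank_across_loci_pairs_modes(self):
        a, b = self.make_cohorts()
        res = compare_cohorts(a, b, mode="signed_rank")
        assert res.n_a == 2  # two shared loci
        assert 0.0 < res.p_value <= 1.0

    def test_rank_sum_requires_locus(self):
        a, b = self.make_cohorts()
        with pytest.raises(ValueError, match="requires a locus"):
            compare_cohorts(a, b)


class TestCohortIO:
    def test_duplicate_sample_locus_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CohortTable("c", tuple(calls([(1, 2)]) + calls([(2, 3)])))

    def test_read_calls_units_and_fragments(self, tmp_path):
        units = tmp_path / "u.tsv"
        units.write_text(
            "sample\tcohort\tlocus\ta1_units\ta2_units\n"
            "s1\tctrl\tL1\t10\t12\ns2\tctrl\tL1\t12\t12\ns1\tcase\tL1\t9\t9\n"
        )
        tables = read_calls_tsv(units)
        assert set(tables) == {"ctrl", "case"}
        assert tables["ctrl"].alleles_at("L1").tolist() == [10, 12, 12, 12]

        frags = tmp_path / "f.tsv"
        frags.write_text(
            "sample\tcohort\tlocus\tfrag1_bp\tfrag2_bp\ns1\tctrl\tL1\t100\t106\n"
        )
        cfg = tmp_path / "cfg.tsv"
        cfg.write_text("locus\tflank_bp\tunit_len\nL1\t70\t3\n")
        tables = read_calls_tsv(frags, cfg)
        [call] = tables["ctrl"].calls
        assert (call.a1, call.a2) == (10, 12)
        with pytest.raises(ValueError, match="locus config"):
            read_calls_tsv(frags)

    def test_summary_tsv_round_trip(self, tmp_path):
        table = CohortTable("ctrl", tuple(calls([(10, 12), (10, 10)])))
        summaries = summarize_cohort(table)
        path = tmp_path / "summary.tsv"
        write_summary_tsv(summaries, path)
        [back] = read_summary_tsv(path)
        assert (back.locus, back.n_chromosomes, back.mode) == ("L1", 4, 10)
        assert back.stability == STABLE


class TestExternalCatalog:
    def test_single_entry(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("population\tlocus\tallele_units\tcount\nEUR\tL1\t12\t10\n")
        cat = load_external_catalog(path)
        report = catalog_report(cat)
        assert report.loc[0, "display"] == "12 (12-12)"
        assert catalog_alleles(cat, "EUR", "L1").tolist() == [12] * 10

    def test_mode_range_report_matches_fixture_truth(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(
            "population\tlocus\tallele_units\tcount\n"
            "AFR\tGLS\t14\t30\nAFR\tGLS\t5\t2\nAFR\tGLS\t24\t1\n"
            "SAS\tGLS\t14\t9\nSAS\tGLS\t6\t9\nSAS\tGLS\t26\t3\n"
        )
        report = catalog_report(load_external_catalog(path)).set_index("population")
        assert report.loc["AFR", "display"] == "14 (5-24)"
        # mode tie between 6 and 14 breaks toward the smaller allele
        assert report.loc["SAS", "display"] == "6 (6-26)"

    def test_empty_file_warns_and_malformed_row_names_line(self, tmp_path, caplog):
        import logging

        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with caplog.at_level(logging.WARNING):
            cat = load_external_catalog(empty)
        assert cat.empty and "empty" in caplog.text

        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "population\tlocus\tallele_units\tcount\nEUR\tL1\t12\t10\nEUR\tL1\tx\t3\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            load_external_catalog(bad)


class TestExpectedHeterozygosity:
    def test_closed_form(self):
        assert expected_heterozygosity([0.5, 0.5]) == pytest.approx(0.5)
        assert expected_heterozygosity([1.0]) == 0.0
        with pytest.raises(ValueError, match="sum to 1"):
            expected_heterozygosity([0.5, 0.4])
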