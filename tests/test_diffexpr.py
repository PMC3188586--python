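"""Counting, normalizations, Fisher exact test, FDR adjustment."""

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from readkit.diffexpr import (
    CountTable,
    DiffExprRecord,
    count_reads_per_region,
    diff_expression,
    fdr_filter,
    fisher_exact,
    interquartile_indices,
    make_count_table,
    normalize_interquartile,
    normalize_mean,
    window_averaged_counts,
    window_counts,
)
from readkit.model import GenomicInterval
from readkit.simulate import simulate_two_condition_reads

from _oracles import bh_adjust, fisher_enumeration


def region(start, end, name, chrom="chr1"):
    return GenomicInterval(chrom, start, end, "+", name=name)


def read_at(start, size=30, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, start + size, strand)


class TestCounting:
    def test_read_spanning_two_regions_counts_in_both(self):
        regions = [region(0, 100, "a"), region(90, 200, "b")]
        counts = count_reads_per_region([read_at(85, 10)], regions)
        assert counts.tolist() == [1.0, 1.0]

    def test_no_overlap_gives_zero_vector(self):
        counts = count_reads_per_region(
            [read_at(5000)], [region(0, 100, "a"), region(200, 300, "b")]
        )
        assert counts.tolist() == [0.0, 0.0]

    def test_planted_reads_are_recovered_exactly(self, rng):
        target = region(10_000, 11_000, "hot")
        cold = region(50_000, 51_000, "cold")
        reads = [
            read_at(int(rng.integers(10_000, 10_970))) for _ in range(50)
        ]
        counts = count_reads_per_region(reads, [target, cold])
        assert counts.tolist() == [50.0, 0.0]

    def test_strand_specific_counting(self):
        regions = [region(0, 100, "a")]
        minus_read = read_at(10, strand="-")
        assert count_reads_per_region([minus_read], regions,
                                      strand_specific=True).tolist() == [0.0]


class TestNormalizeMean:
    def test_scaling_factors(self):
        table = CountTable([region(0, 10, "a"), region(20, 30, "b")],
                           [10, 20], [40, 60], total_a=100, total_b=200)
        out = normalize_mean(table)
        assert out.total_a == out.total_b == 150
        assert out.counts_a.tolist() == [15.0, 30.0]   # x1.5
        assert out.counts_b.tolist() == [30.0, 45.0]   # x0.75

    def test_equal_totals_is_identity(self):
        table = CountTable([region(0, 10, "a")], [7], [9],
                           total_a=50, total_b=50)
        out = normalize_mean(table)
        assert out.counts_a.tolist() == [7.0]
        assert out.counts_b.tolist() == [9.0]

    def test_zero_total_rejected(self):
        table = CountTable([region(0, 10, "a")], [0], [0],
                           total_a=0, total_b=10)
        with pytest.raises(ValueError):
            normalize_mean(table)


class TestNormalizeInterquartile:
    def test_hand_computed_example(self):
        """n=8: averages sort the regions in place; IQR ranks 2..5 give
        SA = 2+3+4+5 = 14, SB = 4+6+8+10 = 28, factor = 0.5."""
        a = [0, 1, 2, 3, 4, 5, 6, 100]
        b = [0, 2, 4, 6, 8, 10, 12, 10]
        table = CountTable(
            [region(i * 10, i * 10 + 5, f"g{i}") for i in range(8)],
            a, b, total_a=sum(a), total_b=sum(b),
        )
        out = normalize_interquartile(table)
        assert out.counts_a.tolist() == a
        np.testing.assert_allclose(out.counts_b, np.array(b) * 0.5)
        np.testing.assert_allclose(out.total_b, table.total_b * 0.5)

    def test_defining_property_on_random_tables(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 60))
            a = rng.poisson(30, n).astype(float)
            b = rng.poisson(80, n).astype(float) + 1
            table = CountTable(
                [region(i * 10, i * 10 + 5, f"g{i}") for i in range(n)],
                a, b, total_a=a.sum(), total_b=b.sum(),
            )
            out = normalize_interquartile(table)
            order = np.argsort((a + b) / 2, kind="stable")
            iqr = order[interquartile_indices(n)]
            np.testing.assert_allclose(
                out.counts_a[iqr].sum(), out.counts_b[iqr].sum(),
                rtol=1e-9,
            )

    def test_identical_samples_give_unit_factor(self):
        a = [1.0, 2.0, 3.0, 4.0]
        table = CountTable(
            [region(i * 10, i * 10 + 5, f"g{i}") for i in range(4)],
            a, a, total_a=10, total_b=10,
        )
        out = normalize_interquartile(table)
        assert out.counts_b.tolist() == a

    def test_too_few_regions_rejected(self):
        table = CountTable([region(0, 10, "a")], [1], [1], 1, 1)
        with pytest.raises(ValueError):
            normalize_interquartile(table)


class TestWindowCounts:
    def test_uniform_coverage_analytic_value(self):
        """1-nt reads at every position of a 100-nt region: every 50-nt
        window holds exactly 50 reads, so the mean is 50."""
        reads = [read_at(s, size=1) for s in range(100, 200)]
        counts = window_counts(reads, [region(100, 200, "g")], window=50)
        assert counts.tolist() == [50.0]

    def test_region_length_equal_to_window_is_plain_count(self):
        reads = [read_at(100, 10), read_at(150, 10), read_at(500, 10)]
        regions = [region(100, 200, "g")]
        counts = window_counts(reads, regions, window=100)
        plain = count_reads_per_region(reads, regions)
        assert counts.tolist() == plain.tolist()

    def test_linearity_under_read_duplication(self, rng):
        reads = [read_at(int(rng.integers(0, 970))) for _ in range(40)]
        regions = [region(0, 1000, "g"), region(300, 500, "h")]
        once = window_counts(reads, regions, window=150)
        twice = window_counts(reads + reads, regions, window=150)
        np.testing.assert_allclose(twice, 2 * once)

    def test_window_defaults_to_smallest_region(self):
        regions = [region(0, 1000, "long"), region(2000, 2050, "short")]
        reads = [read_at(10, 30)]
        assert window_counts(reads, regions).tolist() == \
            window_counts(reads, regions, window=50).tolist()

    def test_brute_force_window_means(self, rng):
        """Difference-array sliding counts equal literal per-placement
        recounting."""
        reads = [read_at(int(rng.integers(0, 500)),
                         size=int(rng.integers(1, 60)))
                 for _ in range(60)]
        reg = region(100, 400, "g")
        w = 75
        expected = []
        for p in range(reg.start, reg.end - w + 1):
            expected.append(
                sum(1 for r in reads if r.start < p + w and r.end > p)
            )
        got = window_counts(reads, [reg], window=w)
        np.testing.assert_allclose(got, [np.mean(expected)])


class TestFisherExact:
    def test_symmetric_table_is_exact_unity(self):
        assert fisher_exact(5, 5, 5, 5) == 1.0

    def test_degenerate_rows(self):
        assert fisher_exact(0, 0, 7, 7) == 1.0
        assert fisher_exact(0, 0, 0, 0) == 1.0

    def test_example_against_enumeration_oracle(self):
        p = fisher_exact(10, 50, 90, 50)
        expected = fisher_enumeration(10, 50, 90, 50)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_random_tables_match_enumeration_and_scipy(self, rng):
        for _ in range(300):
            a, b, ra, rb = (int(x) for x in rng.integers(0, 100, size=4))
            if a + b + ra + rb == 0:
                continue
            p = fisher_exact(a, b, ra, rb)
            assert p == pytest.approx(fisher_enumeration(a, b, ra, rb),
                                      rel=1e-7)
            scipy_p = scipy_fisher([[a, ra], [b, rb]])[1]
            assert p == pytest.approx(scipy_p, rel=1e-6, abs=1e-12)

    def test_one_sided_alternatives(self):
        greater = fisher_exact(15, 5, 85, 95, alternative="greater")
        less = fisher_exact(15, 5, 85, 95, alternative="less")
        assert greater == pytest.approx(
            scipy_fisher([[15, 85], [5, 95]], alternative="greater")[1],
            rel=1e-9,
        )
        assert less == pytest.approx(
            scipy_fisher([[15, 85], [5, 95]], alternative="less")[1],
            rel=1e-9,
        )

    def test_fractional_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(1.5, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact(-1, 2, 3, 4)


class TestFDR:
    def test_textbook_bh_example(self):
        records = [
            DiffExprRecord(region(i, i + 1, f"g{i}"), 0, 0, 0, 0, p)
            for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
        ]
        out = fdr_filter(records, alpha=0.05)
        assert [r.q_value for r in out] == pytest.approx([0.04] * 4)
        assert all(r.significant for r in out)

    def test_single_record_q_equals_p(self):
        (rec,) = fdr_filter(
            [DiffExprRecord(region(0, 1, "g"), 0, 0, 0, 0, 0.0123)]
        )
        assert rec.q_value == pytest.approx(0.0123)

    def test_all_unit_pvalues_never_significant(self):
        records = [
            DiffExprRecord(region(i, i + 1, f"g{i}"), 0, 0, 0, 0, 1.0)
            for i in range(10)
        ]
        assert not any(r.significant
                       for r in fdr_filter(records, alpha=0.99))

    def test_matches_direct_stepup_on_random_pvalues(self, rng):
        pvals = rng.random(200)
        records = [
            DiffExprRecord(region(i, i + 1, f"g{i}"), 0, 0, 0, 0, float(p))
            for i, p in enumerate(pvals)
        ]
        out = fdr_filter(records, alpha=0.1)
        np.testing.assert_allclose(
            [r.q_value for r in out], bh_adjust(pvals), rtol=1e-12
        )
        # original order preserved
        assert [r.region.name for r in out] == [f"g{i}" for i in range(200)]


class TestEndToEnd:
    def test_margins_consistent(self, rng):
        reads_a, reads_b, genes = simulate_two_condition_reads(
            rng, [500] * 6, 0.05, 0.05
        )
        table = make_count_table(reads_a, reads_b, genes)
        records = diff_expression(table, normalization="none")
        for rec in records:
            assert rec.a + rec.rest_a == len(reads_a)
            assert rec.b + rec.rest_b == len(reads_b)
            assert 0 <= rec.p_value <= 1 and 0 <= rec.q_value <= 1

    def test_planted_fold_change_recovered(self, rng):
        """A 4-fold up-regulated region at ~50x depth is flagged at
        alpha=0.05 in at least 95 of 100 simulated replicates."""
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            base = rng.poisson(50, size=20).astype(float)
            counts_a = base.copy()
            counts_b = rng.poisson(50, size=20).astype(float)
            counts_a[7] = rng.poisson(200)  # 4-fold up in condition A
            table = CountTable(
                [region(i * 1000, i * 1000 + 500, f"g{i}")
                 for i in range(20)],
                counts_a, counts_b,
                total_a=counts_a.sum(), total_b=counts_b.sum(),
            )
            records = diff_expression(table, normalization="mean",
                                      alpha=0.05)
            if records[7].significant:
                hits += 1
        assert hits >= 95

    def test_window_normalization_pipeline_runs(self, rng):
        reads_a, reads_b, genes = simulate_two_condition_reads(
            rng, [200, 2000, 400], 0.05, 0.1
        )
        table = window_averaged_counts(reads_a, reads_b, genes)
        records = diff_expression(table, normalization="window")
        assert len(records) == 3
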