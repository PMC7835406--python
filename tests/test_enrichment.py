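"""Dual-strategy enrichment calls, dedup, EST categories, group tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lincrip.catalog import GenomicInterval, TranscriptRecord
from lincrip.enrichment import (
    DedupPolicy,
    EnrichmentValidationError,
    EstCategory,
    Strategy,
    categorize_est,
    classify_all,
    compare_groups,
    dedup_groups,
    deduplicate,
    enrichment_ratio,
    est_category_counts,
    strategy_subtotals,
)
from lincrip.filters import ThresholdConfig

from _naive import naive_call, naive_dedup_groups, naive_pooled_t
from conftest import single_exon

CFG = ThresholdConfig()

fpkm = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


class TestEnrichmentRatio:
    @pytest.mark.parametrize(
        "linc,ezh2,igg,strategy,ratio,bound",
        [
            (3.0, 6.0, 2.0, Strategy.IGG_RATIO, 1.0, True),   # log2(8/4)
            (5.0, 5.0, 5.0, Strategy.IGG_RATIO, 0.0, False),
            (2.0, 14.0, 0.0, Strategy.INPUT_RATIO, 2.0, True),  # log2(16/4)
            (6.0, 0.5, 0.0, Strategy.INPUT_RATIO,
             math.log2(2.5 / 8.0), False),
        ],
    )
    def test_worked_examples_to_machine_precision(
        self, linc, ezh2, igg, strategy, ratio, bound
    ):
        call = enrichment_ratio("t", linc, ezh2, igg, CFG)
        assert call.strategy is strategy
        assert call.ratio == pytest.approx(ratio, abs=1e-12)
        assert call.bound is bound

    def test_negative_fpkm_rejected(self):
        with pytest.raises(EnrichmentValidationError):
            enrichment_ratio("t", -1.0, 2.0, 0.0, CFG)

    @given(linc=fpkm, ezh2=fpkm, igg=fpkm)
    @settings(max_examples=200, deadline=None)
    def test_matches_scalar_oracle_and_strategy_rule(self, linc, ezh2, igg):
        call = enrichment_ratio("t", linc, ezh2, igg, CFG)
        strategy, ratio, bound = naive_call(linc, ezh2, igg, CFG)
        assert call.strategy.value == strategy
        assert call.ratio == pytest.approx(ratio, abs=1e-12)
        assert call.bound == bound
        # strategy is selected solely by IgG == 0
        assert (call.strategy is Strategy.INPUT_RATIO) == (igg == 0.0)

    def test_ratio_monotone_in_numerator_and_denominator(self):
        base = enrichment_ratio("t", 3.0, 6.0, 2.0, CFG).ratio
        assert enrichment_ratio("t", 3.0, 7.0, 2.0, CFG).ratio > base
        assert enrichment_ratio("t", 3.0, 6.0, 3.0, CFG).ratio < base
        zero_base = enrichment_ratio("t", 3.0, 6.0, 0.0, CFG).ratio
        assert enrichment_ratio("t", 4.0, 6.0, 0.0, CFG).ratio < zero_base

    def test_undetected_transcript_cannot_be_called_bound(self):
        # numerator and denominator both reduce to the pseudo-count
        call = enrichment_ratio("t", 0.0, 0.0, 0.0, CFG)
        assert call.ratio == 0.0
        assert not call.bound


class TestClassifyAll:
    def test_hand_built_partition(self):
        expr = pd.DataFrame(
            {
                "transcript_id": ["a", "b", "c", "d"],
                "lincRNA_FPKM": [3.0, 5.0, 2.0, 6.0],
                "EZH2_FPKM": [6.0, 5.0, 14.0, 0.5],
                "IgG_FPKM": [2.0, 5.0, 0.0, 0.0],
            }
        )
        bound, non_bound, calls = classify_all(expr, CFG)
        assert bound == {"a", "c"}
        assert non_bound == {"b", "d"}
        assert set(calls["transcript_id"]) == {"a", "b", "c", "d"}

    def test_empty_table(self):
        expr = pd.DataFrame(
            columns=["transcript_id", "lincRNA_FPKM", "EZH2_FPKM", "IgG_FPKM"]
        )
        bound, non_bound, calls = classify_all(expr, CFG)
        assert bound == frozenset() and non_bound == frozenset()
        assert calls.empty

    def test_rowwise_identical_to_scalar_function(self, rng):
        n = 500
        expr = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "lincRNA_FPKM": rng.lognormal(0, 1, n),
                "EZH2_FPKM": rng.lognormal(0, 1, n),
                "IgG_FPKM": rng.lognormal(0, 1, n)
                * (rng.random(n) < 0.5),
            }
        )
        _, _, calls = classify_all(expr, CFG)
        for row, (_, call) in zip(expr.itertuples(index=False),
                                  calls.iterrows()):
            scalar = enrichment_ratio(
                row.transcript_id, row.lincRNA_FPKM, row.EZH2_FPKM,
                row.IgG_FPKM, CFG
            )
            assert call["strategy"] == scalar.strategy.value
            assert call["ratio"] == pytest.approx(scalar.ratio, abs=1e-12)
            assert bool(call["bound"]) == scalar.bound

    def test_subtotals_conserve_total(self, rng):
        n = 300
        expr = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "lincRNA_FPKM": rng.lognormal(0, 1, n),
                "EZH2_FPKM": rng.lognormal(0, 1, n),
                "IgG_FPKM": rng.lognormal(0, 1, n) * (rng.random(n) < 0.3),
            }
        )
        bound, non_bound, calls = classify_all(expr, CFG)
        subtotals = strategy_subtotals(calls)
        assert subtotals["count"].sum() == n
        assert len(bound) + len(non_bound) == n
        assert not (bound & non_bound)


class TestDeduplicate:
    def iso(self, tid, start, end, strand="+", chrom="chr1"):
        return single_exon(chrom, start, end, strand=strand, tid=tid)

    def expr_for(self, pairs):
        return pd.DataFrame(
            {
                "transcript_id": [t for t, _ in pairs],
                "lincRNA_FPKM": [v for _, v in pairs],
                "EZH2_FPKM": [1.0] * len(pairs),
                "IgG_FPKM": [0.0] * len(pairs),
            }
        )

    def test_higher_fpkm_isoform_survives(self):
        a = self.iso("a", 0, 500)
        b = self.iso("b", 400, 900)
        expr = self.expr_for([("a", 5.0), ("b", 3.0)])
        assert deduplicate([a, b], expr) == {"a"}

    def test_disjoint_transcripts_unchanged(self):
        a = self.iso("a", 0, 100)
        b = self.iso("b", 5_000, 5_100)
        expr = self.expr_for([("a", 1.0), ("b", 2.0)])
        assert deduplicate([a, b], expr) == {"a", "b"}

    def test_opposite_strands_do_not_group_when_strand_aware(self):
        a = self.iso("a", 0, 500, "+")
        b = self.iso("b", 100, 400, "-")
        expr = self.expr_for([("a", 1.0), ("b", 2.0)])
        assert deduplicate([a, b], expr) == {"a", "b"}
        relaxed = DedupPolicy(strand_aware=False)
        assert deduplicate([a, b], expr, relaxed) == {"b"}

    def test_span_overlap_without_exon_overlap_does_not_group(self):
        # b sits entirely inside a's intron
        a = TranscriptRecord(
            "a", "a",
            (GenomicInterval("chr1", 0, 100, "+"),
             GenomicInterval("chr1", 10_000, 10_100, "+")),
        )
        b = self.iso("b", 2_000, 2_100)
        expr = self.expr_for([("a", 1.0), ("b", 2.0)])
        assert deduplicate([a, b], expr) == {"a", "b"}

    def test_missing_expression_is_an_error(self):
        a = self.iso("a", 0, 100)
        expr = self.expr_for([("b", 1.0)])
        with pytest.raises(EnrichmentValidationError):
            deduplicate([a], expr)

    def test_idempotent_and_order_invariant(self, rng):
        records, expr = self.random_case(rng, 40)
        reps = deduplicate(records, expr)
        again = deduplicate([r for r in records if r.transcript_id in reps],
                            expr)
        assert again == reps
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert deduplicate(shuffled, expr) == reps

    def random_case(self, rng, n):
        records = []
        for i in range(n):
            start = int(rng.integers(0, 5_000))
            length = int(rng.integers(50, 1_500))
            records.append(
                self.iso(f"t{i:03d}", start, start + length,
                         strand="+" if rng.random() < 0.5 else "-")
            )
        expr = self.expr_for(
            [(r.transcript_id, float(rng.lognormal(0, 1))) for r in records]
        )
        return records, expr

    def test_groups_equal_brute_force_transitive_closure(self, rng):
        for _ in range(5):
            records, _ = self.random_case(rng, 30)
            got = {
                frozenset(r.transcript_id for r in g)
                for g in dedup_groups(records)
            }
            assert got == naive_dedup_groups(records)


class TestEstCategories:
    @pytest.mark.parametrize(
        "flags,category",
        [
            ((True, True, True), EstCategory.ALL_THREE),
            ((False, False, False), EstCategory.NONE),
            ((True, False, False), EstCategory.PIG_ONLY),
            ((False, True, False), EstCategory.MOUSE_ONLY),
            ((False, False, True), EstCategory.HUMAN_ONLY),
            ((True, True, False), EstCategory.PIG_MOUSE),
            ((True, False, True), EstCategory.PIG_HUMAN),
            ((False, True, True), EstCategory.MOUSE_HUMAN),
        ],
    )
    def test_eight_way_mapping(self, flags, category):
        assert categorize_est(*flags) is category

    def test_counts_conserve(self, rng):
        n = 200
        est = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "pig": rng.random(n) < 0.5,
                "mouse": rng.random(n) < 0.3,
                "human": rng.random(n) < 0.3,
            }
        )
        counts = est_category_counts(est)
        assert sum(counts.values()) == n
        assert set(counts) == {c.value for c in EstCategory}


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_worked_example_against_closed_form(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        t, df = naive_pooled_t([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == df == 4
        assert res.pvalue == pytest.approx(0.0214, abs=1e-3)

    def test_zero_variance_equal_means(self):
        res = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(EnrichmentValidationError):
            compare_groups([1.0], [1.0, 2.0])

    def test_pooled_df_and_welch_flag(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0, 3, 15)
        pooled = compare_groups(a, b)
        assert pooled.df == 21
        t, _ = naive_pooled_t(list(a), list(b))
        assert pooled.statistic == pytest.approx(t, rel=1e-12)
        welch = compare_groups(a, b, welch=True)
        assert welch.df != pooled.df  # unequal variances shrink the df
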