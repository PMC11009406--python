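import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from mescore import mes
from mescore.mes import (
    ContingencyTable,
    MesConfig,
    build_table,
    classify,
    conditional_mle_odds_ratio,
    fisher_two_sided,
    odds_ratio,
    sample_odds_ratio,
    score_domain,
)
from mescore.variant_map import ColumnVariantCounts

from .oracles import conditional_mle_maximisation, fisher_p_enumeration

cells = st.integers(min_value=0, max_value=30)


class TestBuildTable:
    def test_subtraction_against_domain_totals(self):
        counts = ColumnVariantCounts(column=1, n_missense=2, n_human_residues=5)
        t = build_table(counts, (12, 30))
        assert t.as_tuple() == (2, 10, 5, 25)

    def test_synonymous_kind_selects_other_tally(self):
        counts = ColumnVariantCounts(column=1, n_missense=9, n_synonymous=2,
                                     n_human_residues=5)
        t = build_table(counts, (12, 30), variant_kind="synonymous")
        assert t.a == 2

    def test_column_exceeding_totals_rejected(self):
        counts = ColumnVariantCounts(column=1, n_missense=20, n_human_residues=5)
        with pytest.raises(ValueError):
            build_table(counts, (12, 30))

    def test_whole_domain_column_is_degenerate_but_flagged(self):
        counts = ColumnVariantCounts(column=1, n_missense=12, n_human_residues=30)
        t = build_table(counts, (12, 30))
        assert (t.b, t.d) == (0, 0)
        assert fisher_two_sided(t) == 1.0

    def test_no_human_residue_column_is_unscorable(self):
        counts = ColumnVariantCounts(column=1, n_missense=0, n_human_residues=0)
        assert not build_table(counts, (12, 30)).scorable


class TestFisherTwoSided:
    def test_symmetric_table_is_one(self):
        assert fisher_two_sided(ContingencyTable(2, 2, 2, 2)) == 1.0

    def test_empty_column_table_against_enumeration(self):
        t = ContingencyTable(0, 10, 5, 15)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_p_enumeration(0, 10, 5, 15), abs=1e-14
        )

    def test_textbook_cross_check(self):
        # scipy's fisher_exact is an independent implementation of the same
        # min-likelihood convention
        from scipy.stats import fisher_exact

        t = ContingencyTable(1, 9, 1, 9)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_exact([[1, 9], [1, 9]]).pvalue, abs=1e-12
        )

    @given(cells, cells, cells, cells)
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_p_enumeration(a, b, c, d), abs=1e-12
        )

    @given(cells, cells, cells, cells)
    @settings(max_examples=200, deadline=None)
    def test_p_bounds_and_point_probability(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        p = fisher_two_sided(t)
        assert 0.0 < p <= 1.0
        r1, c1, n = a + b, a + c, a + b + c + d
        if n > 0 and 0 < r1 < n and 0 < c1 < n:
            point = hypergeom(n, r1, c1).pmf(a)
            assert p >= point - 1e-12

    def test_one_sided_consistency_on_symmetric_margins(self):
        # with equal residue margins (c == d) the null is symmetric: the
        # two-sided p < 0.1 depleted region matches the one-sided (less)
        # p < 0.05 region
        for a in range(0, 8):
            t = ContingencyTable(a, 40 - a, 50, 50)
            two_sided_depleted = (
                fisher_two_sided(t) < 0.1 and sample_odds_ratio(t) < 1
            )
            r1, c1, n = a + (40 - a), a + 50, 140
            one_sided = hypergeom(n, 40, 90).cdf(a)
            assert two_sided_depleted == (one_sided < 0.05 and sample_odds_ratio(t) < 1)


class TestOddsRatioEstimators:
    def test_sample_symmetry(self):
        assert sample_odds_ratio(ContingencyTable(2, 2, 2, 2)) == 1.0

    def test_no_variants_gives_zero_for_both_estimators(self):
        t = ContingencyTable(0, 12, 5, 25)
        assert odds_ratio(t, "sample") == 0.0
        assert odds_ratio(t, "conditional_mle") == 0.0

    def test_zero_denominator_gives_infinity(self):
        assert sample_odds_ratio(ContingencyTable(3, 0, 2, 5)) == math.inf

    def test_conditional_mle_against_maximisation_oracle(self):
        t = ContingencyTable(3, 7, 4, 16)
        expected = conditional_mle_maximisation(3, 7, 4, 16)
        assert conditional_mle_odds_ratio(t) == pytest.approx(expected, abs=1e-6)

    def test_unscorable_table_rejected(self):
        with pytest.raises(mes.UnscorableColumn):
            odds_ratio(ContingencyTable(1, 5, 0, 10))

    @given(cells, cells, cells, cells)
    @settings(max_examples=60, deadline=None)
    def test_conditional_mle_matches_oracle_randomised(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        lo = max(0, (a + c) - (c + d))
        hi = min(a + b, a + c)
        if lo == hi:
            return
        ours = conditional_mle_odds_ratio(t)
        ref = conditional_mle_maximisation(a, b, c, d)
        if math.isinf(ref):
            assert math.isinf(ours)
        else:
            assert ours == pytest.approx(ref, abs=1e-6, rel=1e-6)


class TestClassify:
    def test_depleted_call(self):
        assert classify(0.2, 0.03) == "depleted"

    def test_neutral_above_threshold(self):
        assert classify(3.0, 0.5) == "neutral"

    def test_enriched_just_below_threshold(self):
        assert classify(3.0, 0.0999) == "enriched"

    def test_boundary_p_equal_threshold_is_neutral(self):
        assert classify(3.0, 0.1) == "neutral"


class TestScoreDomain:
    @staticmethod
    def _counts(missense, humans):
        return [
            ColumnVariantCounts(column=i + 1, n_missense=m, n_human_residues=h)
            for i, (m, h) in enumerate(zip(missense, humans))
        ]

    def test_two_site_reciprocity(self):
        results, _ = score_domain(
            self._counts([3, 9], [10, 10]), MesConfig(estimator="sample")
        )
        or1, or2 = results[0].mes, results[1].mes
        assert or1 * or2 == pytest.approx(1.0, rel=1e-12)
        assert results[0].p_value == results[1].p_value  # bit-identical

    def test_uniform_rates_give_unit_sample_or(self):
        results, _ = score_domain(
            self._counts([4, 8, 12], [5, 10, 15]), MesConfig(estimator="sample")
        )
        assert all(r.mes == pytest.approx(1.0) for r in results)

    def test_starved_deep_column_called_depleted(self):
        # 0 variants on 200 human residues vs ~2/residue elsewhere
        missense = [0] + [40] * 10
        humans = [200] + [20] * 10
        results, _ = score_domain(self._counts(missense, humans))
        assert results[0].call == "depleted"
        assert results[0].mes == 0.0

    def test_unscorable_columns_reported(self):
        counts = self._counts([1, 2, 0], [5, 5, 0])
        results, unscorable = score_domain(counts)
        assert len(results) == 2
        assert unscorable == [3]

    def test_fewer_than_two_scorable_columns_is_error(self):
        with pytest.raises(ValueError):
            score_domain(self._counts([1, 0], [5, 0]))

    def test_no_hidden_multiple_testing_adjustment(self):
        # column p-values are the raw per-table Fisher p-values
        counts = self._counts([0, 5, 9, 2], [20, 10, 10, 10])
        results, _ = score_domain(counts)
        total_m = sum(c.n_missense for c in counts)
        total_h = sum(c.n_human_residues for c in counts)
        for r, cnt in zip(results, counts):
            t = build_table(cnt, (total_m, total_h))
            assert r.p_value == fisher_two_sided(t)
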