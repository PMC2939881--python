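import math

import numpy as np
import pytest

from textdup.census import (
    CensusResult,
    ContingencyTable,
    article_pairs,
    census,
    compare_proportions,
    conditional_probability,
    contingency,
    duplicate_set_section_frequencies,
    log10_odds_ratio,
    ordered_pair_space,
    prediction_metrics,
    ratio_distribution,
    review_census,
    similarity_correlation,
)
from textdup.corpus_model import Article, Granularity, PubType, SectionClass
from textdup.similarity import SimilarPair


def pair(a, b, shared=True, ratio=0.8, cls=SectionClass.NONE, unit_suffix="u"):
    return SimilarPair(
        f"{a}:{unit_suffix}", f"{b}:{unit_suffix}", a, b, ratio, ratio, ratio,
        shared, Granularity.SECTION, cls, cls,
    )


class TestCensus:
    def test_frequency_from_counts(self):
        # 318 similar introduction pairs over 61,149 sections -> 0.0052
        r = CensusResult.from_counts(sa=222, da=96, n_dataset=61149)
        assert r.pairs_total == 318
        assert r.frequency == pytest.approx(0.0052, abs=5e-5)

    def test_zero_pairs_odds_undefined(self):
        r = census([], 100)
        assert r.frequency == 0.0
        assert math.isnan(r.odds_shared_author)

    def test_sa_da_odds(self):
        r = CensusResult.from_counts(sa=222, da=96, n_dataset=61149)
        assert round(r.odds_shared_author, 2) == 2.31

    def test_census_splits_and_conserves(self):
        pairs = [pair("A", "B", True), pair("C", "D", False), pair("E", "F", None)]
        r = census(pairs, 10)
        assert (r.pairs_sa, r.pairs_da, r.pairs_unknown) == (1, 1, 1)
        assert r.pairs_total == r.pairs_sa + r.pairs_da + r.pairs_unknown

    def test_zero_dataset_rejected(self):
        with pytest.raises(ValueError):
            census([], 0)


class TestContingency:
    def test_empty_conditions_fill_d(self):
        t = contingency(set(), set(), 72011)
        assert (t.a, t.b, t.c) == (0, 0, 0)
        assert t.d == 5_185_512_110

    def test_one_shared_pair(self):
        p = {("A", "B")}
        t = contingency(p, p, 10)
        assert (t.a, t.b, t.c) == (1, 0, 0)
        assert t.total == ordered_pair_space(10)

    def test_cells_sum_to_pair_space(self):
        c1 = {("A", "B"), ("C", "D")}
        c2 = {("A", "B"), ("E", "F")}
        t = contingency(c1, c2, 100)
        assert (t.a, t.b, t.c) == (1, 1, 1)
        assert t.a + t.b + t.c + t.d == ordered_pair_space(100)


class TestLogOddsRatio:
    def test_balanced_table_is_zero(self):
        t = ContingencyTable(7, 7, 7, 7)
        assert log10_odds_ratio(t).log10_or == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # log10((10*1)/(5*2)) = 0
        assert log10_odds_ratio(ContingencyTable(10, 5, 2, 1)).log10_or == pytest.approx(0.0)

    def test_symmetric_under_condition_exchange(self):
        # exchanging the two conditions maps b<->c and leaves ad/bc unchanged
        t = ContingencyTable(20, 5, 2, 40)
        exchanged = ContingencyTable(20, 2, 5, 40)
        assert log10_odds_ratio(t).log10_or == pytest.approx(
            log10_odds_ratio(exchanged).log10_or
        )

    def test_sign_flips_when_one_condition_negated(self):
        # negating condition 2 maps a<->b, c<->d and inverts the odds ratio
        t = ContingencyTable(20, 5, 2, 40)
        negated = ContingencyTable(5, 20, 40, 2)
        assert log10_odds_ratio(t).log10_or == pytest.approx(
            -log10_odds_ratio(negated).log10_or
        )

    def test_zero_cell_requires_haldane(self):
        t = ContingencyTable(0, 5, 5, 5)
        with pytest.raises(ValueError):
            log10_odds_ratio(t)
        est = log10_odds_ratio(t, haldane=True)
        assert est.haldane_corrected

    def test_zero_on_proportional_table(self):
        # a*d == b*c -> OR = 1 -> log10 = 0
        t = ContingencyTable(6, 3, 4, 2)
        assert log10_odds_ratio(t).log10_or == pytest.approx(0.0)


class TestPredictionMetrics:
    def test_ppv_zero_and_half(self):
        assert prediction_metrics(ContingencyTable(0, 10, 1, 1)).ppv == 0.0
        assert prediction_metrics(ContingencyTable(10, 10, 1, 1)).ppv == 0.5

    def test_ppv_invariant_to_cell_scaling(self):
        t1 = ContingencyTable(3, 9, 2, 6)
        t2 = ContingencyTable(30, 90, 20, 60)
        assert prediction_metrics(t1).ppv == pytest.approx(prediction_metrics(t2).ppv)

    def test_undefined_when_no_predictions(self):
        with pytest.raises(ValueError):
            prediction_metrics(ContingencyTable(0, 0, 1, 1))


class TestConditionalProbability:
    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            conditional_probability(set(), {("A", "B")})

    def test_all_section_pairs_abstract_similar(self):
        sect = {("A", "B"), ("C", "D")}
        assert conditional_probability(sect, sect).fraction == 1.0

    def test_planted_quarter(self):
        # 10 of 40 methods-similar article pairs also abstract-similar -> 25%
        sect = {(f"A{i}", f"B{i}") for i in range(40)}
        abst = {(f"A{i}", f"B{i}") for i in range(10)}
        cp = conditional_probability(sect, abst)
        assert cp.fraction == pytest.approx(0.25)
        assert cp.denominator == 40

    def test_unit_pairs_collapse_to_article_pairs(self):
        pairs = [
            pair("A", "B", unit_suffix="s1"),
            pair("A", "B", unit_suffix="s2"),  # same article pair, second unit pair
        ]
        cp = conditional_probability(pairs, {("A", "B")})
        assert cp.denominator == 1 and cp.fraction == 1.0

    def test_two_proportion_comparison(self):
        p1 = conditional_probability({(f"A{i}", f"B{i}") for i in range(100)},
                                     {(f"A{i}", f"B{i}") for i in range(50)})
        p2 = conditional_probability({(f"C{i}", f"D{i}") for i in range(100)},
                                     {(f"C{i}", f"D{i}") for i in range(10)})
        z, pval = compare_proportions(p1, p2)
        assert pval < 0.001 and z > 0


class TestRatioDistribution:
    def test_one_empty_class_flagged(self):
        h = ratio_distribution([0.2, 0.4], [True, True])
        assert h.empty_false and not h.empty_true

    def test_histograms_normalized(self):
        rng = np.random.default_rng(0)
        r = rng.random(500)
        cond = rng.random(500) < 0.5
        h = ratio_distribution(r, cond)
        assert h.hist_true.sum() == pytest.approx(1.0)
        assert h.hist_false.sum() == pytest.approx(1.0)

    def test_planted_bimodal_modes_recovered(self):
        rng = np.random.default_rng(1)
        dup = np.clip(rng.normal(0.9, 0.02, 300), 0, 0.999)
        bkg = np.clip(rng.normal(0.2, 0.02, 300), 0, 0.999)
        ratios = np.concatenate([dup, bkg])
        cond = np.array([True] * 300 + [False] * 300)
        h = ratio_distribution(ratios, cond, bin_width=0.05)
        assert h.bin_edges[np.argmax(h.hist_true)] == pytest.approx(0.85, abs=0.051)
        assert h.bin_edges[np.argmax(h.hist_false)] == pytest.approx(0.15, abs=0.051)

    def test_uniform_ratios_flat_within_sampling_error(self):
        from scipy import stats as ss

        rng = np.random.default_rng(2)
        r = rng.random(4000)
        cond = np.ones(4000, dtype=bool)
        h = ratio_distribution(r, cond, bin_width=0.05)
        chi2 = 4000 * np.sum((h.hist_true - 0.05) ** 2 / 0.05)
        assert ss.chi2.sf(chi2, df=19) > 0.001


class TestCorrelation:
    def test_exact_line(self):
        pts = [(0.5 + 0.01 * i, 0.5 + 0.01 * i) for i in range(10)]
        rep = similarity_correlation(pts)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)

    def test_anti_line(self):
        pts = [(0.41 + 0.01 * i, 1 - (0.41 + 0.01 * i)) for i in range(10)]
        rep = similarity_correlation(pts)
        assert rep.pearson_r == pytest.approx(-1.0)

    def test_floor_filters_pairs(self):
        pts = [(0.1, 0.9)] * 50 + [(0.5, 0.5), (0.6, 0.6), (0.7, 0.7)]
        rep = similarity_correlation(pts, floor=0.4)
        assert rep.n_pairs == 3

    def test_independent_ratios_near_zero(self):
        rng = np.random.default_rng(3)
        n = 2000
        pts = list(zip(0.4 + 0.6 * rng.random(n), 0.4 + 0.6 * rng.random(n)))
        rep = similarity_correlation(pts, floor=0.4)
        assert abs(rep.pearson_r) < 2 / math.sqrt(rep.n_pairs)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            similarity_correlation([(0.5, 0.5), (0.6, 0.6)])


class TestReviewCensus:
    def _corpus(self):
        arts = []
        for i in range(6):
            arts.append(
                Article(
                    article_id=f"R{i}" if i < 3 else f"N{i}",
                    authors=[f"Auth{i}, A."],
                    journal="J0" if i % 2 == 0 else "J1",
                    year=2005,
                    pub_type=PubType.REVIEW if i < 3 else PubType.RESEARCH,
                )
            )
        return arts

    def test_strata_frequencies_and_sa_fractions(self):
        corpus = self._corpus()
        corpus[1].authors = corpus[0].authors  # shared-author review pair
        pairs = [pair("R0", "R1", shared=True), pair("R2", "N3", shared=False)]
        rep = review_census(corpus, pairs)
        assert rep.n_reviews == 3
        assert rep.pairs_review_review == 1
        assert rep.pairs_review_research == 1
        assert rep.freq_review_review == pytest.approx(1 / 3)
        assert rep.sa_review_pairs == 1
        assert rep.sa_same_journal_fraction == pytest.approx(0.0)  # J0 vs J1
        assert rep.sa_same_year_fraction == pytest.approx(1.0)

    def test_no_reviews_flagged_empty(self):
        arts = [Article(article_id=f"N{i}", pub_type=PubType.RESEARCH) for i in range(3)]
        assert review_census(arts, []).empty


class TestDuplicateSetFrequencies:
    def test_all_results_above(self):
        recs = [{"intro_ratio": 0.1, "methods_ratio": 0.1, "results_ratio": 1.0}] * 5
        out = duplicate_set_section_frequencies(recs)
        assert out[SectionClass.RESULTS_DISCUSSION] == 1.0
        assert out[SectionClass.INTRODUCTION] == 0.0

    def test_missing_ratio_skipped(self):
        recs = [
            {"intro_ratio": 0.9, "methods_ratio": None, "results_ratio": 0.9},
            {"intro_ratio": 0.1, "methods_ratio": 0.9, "results_ratio": 0.9},
        ]
        out = duplicate_set_section_frequencies(recs)
        assert out[SectionClass.METHODS] == 1.0  # one pair counted
        assert out[SectionClass.INTRODUCTION] == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            duplicate_set_section_frequencies([])


def test_article_pairs_deduplicate():
    pairs = [pair("A", "B", unit_suffix="x"), pair("B", "A", unit_suffix="y")]
    assert article_pairs(pairs) == {("A", "B")}
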