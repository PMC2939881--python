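"""Census statistics over sets of similar pairs.

Implements the duplicate-publication census: frequencies of similar pairs
(count normalized by the query-dataset size), shared-author (SA) versus
different-author (DA) odds, the abstract-vs-full-text 2x2 contingency
analysis with a log10 odds ratio and its large-sample confidence interval,
positive-predictive metrics with Wilson intervals, conditional probabilities
of abstract similarity given section similarity, conditional ratio
histograms, correlation of two similarity ratios above a floor, and the
review-article analysis.

Two pair levels are kept explicit throughout: *unit pairs* (sections or
paragraphs) and *article pairs* (unit pairs collapsed by unordered article
id pair). Contingency and conditional statistics operate at the article
level; section/paragraph censuses count unit pairs.

Whole-pair-space denominators use the ordered-pair convention n*(n-1),
matching how corpus-scale surveys of this kind count "all possible pairs";
detected pairs themselves are always stored unordered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .corpus_model import Article, PubType, SectionClass
from .similarity import SimilarPair

ArticlePair = tuple[str, str]


def article_pairs(pairs: Iterable[SimilarPair]) -> set[ArticlePair]:
    """Collapse unit pairs to unordered article-id pairs (deduplicated)."""
    return {p.article_pair for p in pairs}


def ordered_pair_space(n: int) -> int:
    """Number of ordered pairs n*(n-1) — the whole-pair-space denominator."""
    return n * (n - 1)


# ---------------------------------------------------------------------------
# frequency of similar pairs, SA/DA split

@dataclass
class CensusResult:
    """Frequency-of-similar-pairs census for one stratum.

    frequency = total detected pairs / N (the query-dataset size);
    odds = SA count / DA count, where SA pairs share at least one author.
    Pairs with unknown authorship are excluded from the odds and reported.
    """

    n_dataset: int
    pairs_total: int
    pairs_sa: int
    pairs_da: int
    pairs_unknown: int = 0

    @property
    def frequency(self) -> float:
        return self.pairs_total / self.n_dataset

    @property
    def odds_shared_author(self) -> float:
        """SA/DA odds; nan when DA = 0 (undefined)."""
        if self.pairs_da == 0:
            return math.nan
        return self.pairs_sa / self.pairs_da

    @classmethod
    def from_counts(
        cls, sa: int, da: int, n_dataset: int, unknown: int = 0
    ) -> "CensusResult":
        return cls(n_dataset, sa + da + unknown, sa, da, unknown)


def census(pairs: Iterable[SimilarPair], n_dataset: int) -> CensusResult:
    """Count similar pairs and split by shared authorship."""
    if n_dataset <= 0:
        raise ValueError("dataset size must be positive")
    pairs = list(pairs)
    sa = sum(1 for p in pairs if p.shared_author is True)
    da = sum(1 for p in pairs if p.shared_author is False)
    unknown = sum(1 for p in pairs if p.shared_author is None)
    return CensusResult(n_dataset, len(pairs), sa, da, unknown)


# ---------------------------------------------------------------------------
# 2x2 contingency analysis

@dataclass
class ContingencyTable:
    """2x2 cross-classification of article pairs by two binary conditions.

    a: both conditions; b: condition 1 only; c: condition 2 only; d: neither.
    The cell total a+b+c+d equals the declared pair-space size.
    """

    a: int
    b: int
    c: int
    d: int
    label1: str = "condition1"
    label2: str = "condition2"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(
    pairs_cond1: set[ArticlePair],
    pairs_cond2: set[ArticlePair],
    n_articles: int,
    label1: str = "condition1",
    label2: str = "condition2",
) -> ContingencyTable:
    """Cross-classify two article-pair sets over an n-article universe.

    The d cell is the remainder of the ordered pair space n*(n-1); the
    detected cells a, b, c count unordered pairs. This mixed convention is
    the one corpus-scale similarity surveys print, and it is declared here
    once so all downstream arithmetic is reproducible.
    """
    a = len(pairs_cond1 & pairs_cond2)
    b = len(pairs_cond1 - pairs_cond2)
    c = len(pairs_cond2 - pairs_cond1)
    space = ordered_pair_space(n_articles)
    d = space - a - b - c
    if d < 0:
        raise ValueError(
            f"pair universe mismatch: {a + b + c} detected pairs exceed the "
            f"pair space {space} of {n_articles} articles"
        )
    return ContingencyTable(a, b, c, d, label1, label2)


@dataclass
class OddsRatioEstimate:
    """Log10 odds ratio with a symmetric large-sample interval half-width."""

    log10_or: float
    half_width: float
    confidence: float
    haldane_corrected: bool = False


def log10_odds_ratio(
    table: ContingencyTable,
    confidence: float = 0.99,
    haldane: bool = False,
) -> OddsRatioEstimate:
    """log10((a*d)/(b*c)) with the standard large-sample interval.

    half_width = z * sqrt(1/a + 1/b + 1/c + 1/d) / ln(10), z the two-sided
    normal quantile at ``confidence``. Zero cells require ``haldane=True``
    (adds 0.5 to every cell, flagged in the result).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "contingency table has a zero cell; enable the Haldane "
                "correction to compute the odds ratio"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    log10_or = math.log10((a * d) / (b * c))
    half_width = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d) / math.log(10)
    return OddsRatioEstimate(log10_or, half_width, confidence, corrected)


@dataclass
class PredictionMetrics:
    """Metrics for using condition 1 to predict condition 2 on a 2x2 table.

    ``ppv`` = a/(a+b): among condition-1-positive pairs, the fraction also
    condition-2-positive (historically reported as "specificity" in the
    duplicate-detection literature; labelled PPV here). ``fnr`` is computed
    under the convention fnr = c/(c+d): the fraction of condition-1-negative
    pairs that are nonetheless condition-2-positive, i.e. the miss rate of
    the predictor over the negative pair space. ``sensitivity_like`` = 1-fnr.
    """

    ppv: float
    ppv_ci: tuple[float, float]
    fnr: float
    sensitivity_like: float
    n_predicted: int


def prediction_metrics(
    table: ContingencyTable, ci_level: float = 0.95
) -> PredictionMetrics:
    n_pred = table.a + table.b
    if n_pred == 0:
        raise ValueError("no condition-1-positive pairs: PPV undefined")
    ppv = table.a / n_pred
    lo, hi = proportion_confint(table.a, n_pred, alpha=1 - ci_level, method="wilson")
    neg = table.c + table.d
    fnr = table.c / neg if neg > 0 else math.nan
    return PredictionMetrics(ppv, (float(lo), float(hi)), fnr, 1 - fnr, n_pred)


# ---------------------------------------------------------------------------
# conditional probabilities between granularities

@dataclass
class ConditionalProbability:
    fraction: float
    numerator: int
    denominator: int


def conditional_probability(
    section_pairs: Iterable[SimilarPair] | set[ArticlePair],
    abstract_pairs: set[ArticlePair],
) -> ConditionalProbability:
    """P(similar abstracts | similar sections), at the article-pair level.

    Section unit pairs are collapsed to article pairs first; the denominator
    is the number of distinct article pairs with a similar section.
    """
    if isinstance(section_pairs, set):
        apairs = section_pairs
    else:
        apairs = article_pairs(section_pairs)
    denom = len(apairs)
    if denom == 0:
        raise ValueError("no section-similar article pairs: conditional undefined")
    num = len(apairs & abstract_pairs)
    return ConditionalProbability(num / denom, num, denom)


def compare_proportions(
    p1: ConditionalProbability, p2: ConditionalProbability
) -> tuple[float, float]:
    """Two-proportion z-test (uncorrected) between two conditionals.

    Returns (z statistic, two-sided P value).
    """
    stat, pval = proportions_ztest(
        [p1.numerator, p2.numerator], [p1.denominator, p2.denominator]
    )
    return float(stat), float(pval)


# ---------------------------------------------------------------------------
# conditional ratio distributions

@dataclass
class ConditionalHistogram:
    bin_edges: np.ndarray
    hist_true: np.ndarray  # normalized frequencies, condition == True
    hist_false: np.ndarray
    empty_true: bool
    empty_false: bool
    crossing_bins: list[tuple[float, float]]


def ratio_distribution(
    ratios: Sequence[float],
    condition: Sequence[bool],
    bin_width: float = 0.05,
) -> ConditionalHistogram:
    """Normalized histograms of a similarity ratio, conditioned on a binary
    label, plus the bins where the two conditional curves cross.

    An empty condition class yields an all-zero histogram flagged empty.
    """
    if len(ratios) != len(condition):
        raise ValueError("ratios and condition must align")
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    r = np.asarray(ratios, dtype=float)
    c = np.asarray(condition, dtype=bool)

    def _norm_hist(vals: np.ndarray) -> tuple[np.ndarray, bool]:
        if vals.size == 0:
            return np.zeros(len(edges) - 1), True
        h, _ = np.histogram(vals, bins=edges)
        return h / h.sum(), False

    ht, empty_t = _norm_hist(r[c])
    hf, empty_f = _norm_hist(r[~c])
    crossings: list[tuple[float, float]] = []
    if not empty_t and not empty_f:
        diff = ht - hf
        sign = np.sign(diff)
        for i in range(1, len(sign)):
            if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
                crossings.append((float(edges[i]), float(edges[i + 1])))
    return ConditionalHistogram(edges, ht, hf, empty_t, empty_f, crossings)


# ---------------------------------------------------------------------------
# correlation between two similarity ratios

@dataclass
class CorrelationReport:
    pearson_r: float
    slope: float
    intercept: float
    n_pairs: int
    floor: float


def similarity_correlation(
    ratio_pairs: Iterable[tuple[float, float]], floor: float = 0.4
) -> CorrelationReport:
    """Pearson correlation and least-squares line between two similarity
    ratios (e.g. abstract vs full text), restricted to pairs where both
    ratios exceed ``floor``."""
    xs, ys = [], []
    for x, y in ratio_pairs:
        if x > floor and y > floor:
            xs.append(x)
            ys.append(y)
    if len(xs) < 3:
        raise ValueError(
            f"need at least 3 pairs above the floor {floor}, got {len(xs)}"
        )
    r, _ = stats.pearsonr(xs, ys)
    fit = stats.linregress(xs, ys)
    return CorrelationReport(float(r), float(fit.slope), float(fit.intercept), len(xs), floor)


# ---------------------------------------------------------------------------
# review-article analysis

@dataclass
class ReviewCensus:
    n_reviews: int
    n_research: int
    freq_review_review: float
    freq_review_research: float
    pairs_review_review: int
    pairs_review_research: int
    odds_sa_review_review: float
    odds_sa_review_research: float
    odds_sa_any_review: float
    sa_review_pairs: int
    sa_same_journal_fraction: float
    sa_same_year_fraction: float
    empty: bool = False


def review_census(
    corpus: Sequence[Article], pairs: Iterable[SimilarPair]
) -> ReviewCensus:
    """Similarity census stratified by publication type.

    Frequencies are normalized by the number of review articles (the query
    dataset for review-centric scans). Among shared-author pairs involving
    at least one review, the fractions published in the same journal and in
    the same year are reported.
    """
    arts: Mapping[str, Article] = {a.article_id: a for a in corpus}
    n_rev = sum(1 for a in arts.values() if a.pub_type is PubType.REVIEW)
    n_res = len(arts) - n_rev
    if n_rev == 0:
        return ReviewCensus(
            0, n_res, math.nan, math.nan, 0, 0, math.nan, math.nan, math.nan,
            0, math.nan, math.nan, empty=True,
        )

    rr: list[SimilarPair] = []
    rn: list[SimilarPair] = []
    for p in pairs:
        ta = arts[p.article_a].pub_type
        tb = arts[p.article_b].pub_type
        if ta is PubType.REVIEW and tb is PubType.REVIEW:
            rr.append(p)
        elif PubType.REVIEW in (ta, tb):
            rn.append(p)

    def _odds(ps: list[SimilarPair]) -> float:
        sa = sum(1 for p in ps if p.shared_author is True)
        da = sum(1 for p in ps if p.shared_author is False)
        return sa / da if da else math.nan

    sa_rev = [p for p in rr + rn if p.shared_author is True]
    sa_apairs = {p.article_pair for p in sa_rev}
    same_j = sum(
        1 for x, y in sa_apairs if arts[x].journal == arts[y].journal
    )
    same_y = sum(1 for x, y in sa_apairs if arts[x].year == arts[y].year)
    n_sa = len(sa_apairs)

    return ReviewCensus(
        n_reviews=n_rev,
        n_research=n_res,
        freq_review_review=len(rr) / n_rev,
        freq_review_research=len(rn) / n_rev,
        pairs_review_review=len(rr),
        pairs_review_research=len(rn),
        odds_sa_review_review=_odds(rr),
        odds_sa_review_research=_odds(rn),
        odds_sa_any_review=_odds(rr + rn),
        sa_review_pairs=n_sa,
        sa_same_journal_fraction=same_j / n_sa if n_sa else math.nan,
        sa_same_year_fraction=same_y / n_sa if n_sa else math.nan,
    )


# ---------------------------------------------------------------------------
# labeled duplicate-pair fixture analysis

SECTION_RATIO_FIELDS = {
    SectionClass.INTRODUCTION: "intro_ratio",
    SectionClass.METHODS: "methods_ratio",
    SectionClass.RESULTS_DISCUSSION: "results_ratio",
}


def duplicate_set_section_frequencies(
    labeled_pairs: Sequence[Mapping[str, object]],
    threshold: float = 0.5,
) -> dict[SectionClass, float]:
    """Per-section frequency of high similarity in a labeled duplicate set.

    ``labeled_pairs`` carry per-pair section similarity ratios (fields
    intro_ratio / methods_ratio / results_ratio). For each section class the
    returned frequency is the fraction of pairs whose ratio exceeds
    ``threshold``; pairs missing a ratio are skipped for that class (and
    counted out of its denominator).
    """
    if not labeled_pairs:
        raise ValueError("empty duplicate-pair set")
    out: dict[SectionClass, float] = {}
    for cls, fieldname in SECTION_RATIO_FIELDS.items():
        vals = [
            float(p[fieldname])  # type: ignore[arg-type]
            for p in labeled_pairs
            if p.get(fieldname) is not None and p.get(fieldname) != ""
        ]
        out[cls] = (
            sum(1 for v in vals if v > threshold) / len(vals) if vals else math.nan
        )
    return out


# ---------------------------------------------------------------------------
# report I/O

def write_census_tsv(
    rows: Mapping[str, CensusResult], path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("stratum\tN\tpairs_total\tpairs_SA\tpairs_DA\tpairs_unknown\tfrequency\todds_SA_DA\n")
        for name in sorted(rows):
            r = rows[name]
            odds = "" if math.isnan(r.odds_shared_author) else f"{r.odds_shared_author:.6f}"
            fh.write(
                f"{name}\t{r.n_dataset}\t{r.pairs_total}\t{r.pairs_sa}\t{r.pairs_da}\t"
                f"{r.pairs_unknown}\t{r.frequency:.6f}\t{odds}\n"
            )


def write_contingency_json(
    table: ContingencyTable,
    estimate: OddsRatioEstimate,
    metrics: PredictionMetrics,
    path: str | Path,
) -> None:
    payload = {
        "a": table.a,
        "b": table.b,
        "c": table.c,
        "d": table.d,
        "label1": table.label1,
        "label2": table.label2,
        "log10_odds_ratio": estimate.log10_or,
        "half_width": estimate.half_width,
        "confidence": estimate.confidence,
        "ppv": metrics.ppv,
        "ppv_ci": list(metrics.ppv_ci),
        "fnr": metrics.fnr,
        "sensitivity_like": metrics.sensitivity_like,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
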