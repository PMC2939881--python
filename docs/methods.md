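# Methods

## The similarity model

`textdup` detects near-duplicate text among structured scientific articles
with an order-free, term-weighted overlap score. For a query token multiset
*q* and subject multiset *s*,

    score(q, s) = Σ_t w(t) · min(count_q(t), count_s(t))

where the sum runs over distinct terms and the weights are smoothed inverse
document frequencies built on the target dataset,

    w(t) = ln((N + 1) / (df(t) + 1)) + 1,

with *N* the number of units and *df(t)* the number of units containing *t*.
The *identity score* of a subject is `score(s, s)`, and the pair statistic is
the **similarity ratio**

    ratio(q, s) = score(q, s) / score(s, s) ∈ [0, 1],

which equals 1 exactly when the two token multisets are identical. Because
`min` caps every term's contribution by the subject's own count, the ratio is
bounded by construction, and because the raw score is symmetric, one indexed
pass yields both directed ratios of a pair. A pair is reported as *similar*
when its ratio reaches a threshold in at least one direction (the
`either_direction` pairing rule; `both_directions` is available and stricter).
Ties at the threshold count as similar (closed threshold).

Rationale for this scorer: it is order-free like a keyword retrieval engine,
its ratio has the right normalization and range, and it admits an exact
brute-force oracle, so the accelerated scan can be verified pair-for-pair.
The scorer sits behind a small interface (`TermWeights`,
`similarity_score`) so alternatives can be plugged in.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.5 | similarity-ratio cut-off for calling a pair similar; 0.5 balances sensitivity and specificity for abstract-sized text |
| `pairing` | `either_direction` | pair ratio = max (or min, for `both_directions`) of the two directed ratios |
| `top_k` | 400 | candidates retained per query before thresholding; set ≥ dataset size for exhaustive scans (the index is exact; `top_k` only caps output work) |
| `min_words` | 30 (paragraphs), 0 otherwise | units shorter than this are flagged excluded: the ratio of very short texts is unstable, and the engine is calibrated for abstract-sized inputs |
| histogram bin width | 0.05 | conditional ratio distributions |
| correlation floor | 0.4 | both ratios must exceed it before Pearson/least-squares fitting |

## Corpus model

Articles are parsed from JATS/NLM XML (`lxml`) or the package's JSON-Lines
corpus format. Body sections are classified into the IMRaD scheme by
case-folded keyword matching on section titles — INTRODUCTION:
{introduction, background}; METHODS: {method, methods, materials,
experimental procedure}; RESULTS_DISCUSSION: {result, discussion,
conclusion}; anything else is OTHER — with precedence INTRODUCTION > METHODS
> RESULTS_DISCUSSION when several keywords match. The table is
config-overridable; the default reproduces the three-way split on standard
IMRaD titles. Articles without a body are retained as citation-only records
(counted as retrieved, never scanned). Publication type is read from the
JATS `article-type` attribute ("review" substring → review; default
research).

Author identity uses the loosest rule that avoids trivial string-mismatch
misses: case-folded, diacritic-stripped surname plus first initial. A pair
*shares authors* (SA) when the two key sets intersect; articles with no
usable authors are excluded from SA/DA statistics and reported separately.

## Census statistics

- **Frequency of similar pairs** = detected pairs / query-dataset size.
- **SA/DA odds** = SA pairs / DA pairs (undefined flag when DA = 0).
- **Contingency analysis**: article pairs are cross-classified by two binary
  similarity conditions (e.g. abstract vs full text at threshold 0.5). The
  a, b, c cells count detected *unordered* pairs; the d cell fills the
  *ordered* pair space n(n−1). This mixed convention matches how
  corpus-scale surveys print "all possible pairs"; both conventions are
  exposed (`ordered_pair_space`).
- **Log odds ratio**: log10(ad/bc) with the large-sample interval
  z·sqrt(1/a+1/b+1/c+1/d)/ln 10 (z at the two-sided confidence level;
  Haldane 0.5 correction optional and flagged for zero cells).
- **Prediction metrics**: the fraction a/(a+b) is a positive-predictive
  value (the older duplicate-detection literature calls it "specificity");
  it carries a 95% Wilson interval (`statsmodels`). The false-negative rate
  is reported under the explicit convention fnr = c/(c+d) — the published
  denominator for this quantity is not derivable from printed cells, so no
  external value is asserted for it.
- **Conditional probabilities** (abstract similarity given section
  similarity) collapse unit pairs to article pairs first; classes are
  compared with an uncorrected two-proportion z-test (correction available).
- **Correlation** between two ratios is Pearson + least squares on pairs
  with both ratios > 0.4 (below the floor the mass of near-zero background
  pairs swamps any signal).
- **Review analysis**: frequencies for review–review and review–research
  strata (normalized by the review count), SA/DA odds per stratum, and the
  same-journal / same-year fractions among SA review pairs.

Unit-pair versus article-pair level is explicit in every operation:
section/paragraph censuses count unit pairs; contingency and conditional
statistics always work at the article level.

## Synthetic corpus generator

The generator emulates the statistical structure the census assumes, not
natural language (the engine is order-free, so only token multiset
statistics matter):

- **Background**: each topic owns a disjoint vocabulary of 5,000 synthetic
  types with mild power-law frequencies (Zipf exponent 0.5). Articles draw
  their abstract (100 words) and three IMRaD sections (Poisson(3)
  paragraphs of Poisson(60) words) i.i.d. from their topic. With these
  defaults the expected ratio between two unrelated same-topic sections is
  ≲ 0.1 and cross-topic ratios are exactly 0, so the background false-positive
  rate at threshold 0.5 is effectively zero — mirroring the regime of a real
  archive where a random article pair is almost never similar.
- **Plants**: a duplication plan places pairs whose target (abstract only,
  one section class, full text, review pairs) is copied as a token-level
  prefix fraction *f* of each targeted unit, with the remainder resampled
  from the duplicate's own (distinct) topic. Prefix copying makes the
  achieved overlap equal *f* up to rounding, so calibration is analytic:
  f = 1 gives ratio exactly 1, f = 0 gives 0. Author overlap (shared pairs
  share exactly one author), journal and year flags are controlled per plant.
- **Ledger**: every generated corpus ships a ground-truth ledger (planted
  pairs with f and flags; per-article unit counts) validated against the
  emitted corpus on every generation.
- The default plan plants 57 pairs in a 1,000-article corpus with
  methods-biased section reuse (17 methods / 7 introduction / 8 results
  section plants), 10 full-text plants, 8 abstract-only plants and 7
  review-involving plants, at copy fraction 0.9 — a caricature of the
  section-reuse patterns the census is designed to measure.

What the generator does **not** emulate: real token burstiness and topical
drift within articles, length/section correlations, citation-driven phrase
reuse, boilerplate (journal headers, funding statements), or borderline
paraphrase. Passing recovery tests therefore demonstrate the pipeline's
correctness and calibration on well-separated duplicates, not its
operating characteristics on real archives.

The labeled duplicate-pair fixture (`make_duplicate_fixture`) is a synthetic
stand-in for a manually curated duplicate set: it reproduces target
per-section exceedance fractions exactly (counts are the nearest integers at
the requested n) and carries no other claim about real duplicates.

## Numerical and design choices

- Determinism everywhere: one `numpy` Generator per corpus; JSONL with
  sorted keys; scans ordered by unit ids; all artifacts carry their config
  header. Identical (config, seed) are byte-identical.
- Unseen query terms weigh 0; a subject whose tokens all weigh 0 has an
  undefined ratio and raises rather than returning a silent 0/0.
- Problem sizes in the test and acceptance runs — 1,000-article corpora
  across 20 seeds for recovery, ≤ 240-unit corpora for oracle equivalence,
  two-article corpora for calibration replicates — were chosen as the
  smallest sizes at which the binomial recovery bounds and oracle
  comparisons are meaningful.
- Known limitations: no sentence-level alignment or reuse highlighting; no
  semantic/cross-language similarity; English-style tokenization only; the
  inverted index is in-memory and aimed at desk-scale corpora (10^3–10^5
  units), not archive-scale batch scanning.
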