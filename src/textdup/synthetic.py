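"""Synthetic article corpora with planted near-duplicates and ground truth.

The generator emulates the statistical structure the census assumes: a
corpus of IMRaD-structured articles (title, abstract, authors, journal,
year, research/review type, Introduction / Methods / Results-Discussion
sections of paragraphs), with background text drawn from topic-specific
token distributions and a *duplication plan* of planted pairs whose
location (abstract, one section class, full text), copy fraction and author
overlap are controlled and recorded in a :class:`GroundTruthLedger`.

Background model: each topic owns a disjoint synthetic vocabulary; token
frequencies follow a mild power law (Zipf exponent 0.5 over 5,000 types),
so unrelated articles — even within a topic — have pair ratios far below
the 0.5 detection threshold, while planted pairs copy a token-level prefix
fraction f of each targeted unit and therefore achieve ratios close to f.
No natural-language realism is attempted: the similarity engine is
order-free, so only the token multiset statistics matter.

Identical (config, seed) produce byte-identical corpora and ledgers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_model import (
    Article,
    PubType,
    Section,
    SectionClass,
)

PLANT_TARGETS = (
    "abstract_only",
    "fulltext",
    "intro_section",
    "methods_section",
    "results_section",
    "review_pair",
    "review_vs_research",
)

_TARGET_SECTION = {
    "intro_section": SectionClass.INTRODUCTION,
    "methods_section": SectionClass.METHODS,
    "results_section": SectionClass.RESULTS_DISCUSSION,
}

_SECTION_TEMPLATE = (
    ("Introduction", SectionClass.INTRODUCTION),
    ("Methods", SectionClass.METHODS),
    ("Results and Discussion", SectionClass.RESULTS_DISCUSSION),
)


@dataclass
class PlantSpec:
    """A batch of planted duplicate pairs with one configuration."""

    n_pairs: int
    target: str
    copy_fraction: float = 0.9
    author_overlap: str = "shared"  # or "disjoint"
    same_journal: bool = False
    same_year: bool = False

    def __post_init__(self) -> None:
        if self.target not in PLANT_TARGETS:
            raise ValueError(f"unknown plant target {self.target!r}")
        if not (0.0 <= self.copy_fraction <= 1.0):
            raise ValueError("copy_fraction must be in [0, 1]")
        if self.author_overlap not in ("shared", "disjoint"):
            raise ValueError("author_overlap must be 'shared' or 'disjoint'")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")


def default_plan() -> list[PlantSpec]:
    """The standard duplication plan: section-biased reuse with methods
    sections the most duplicated, shared-author excess strongest for
    introduction/methods, plus full-text, abstract-only and review plants."""
    return [
        PlantSpec(5, "intro_section", author_overlap="shared"),
        PlantSpec(2, "intro_section", author_overlap="disjoint"),
        PlantSpec(11, "methods_section", author_overlap="shared"),
        PlantSpec(6, "methods_section", author_overlap="disjoint"),
        PlantSpec(4, "results_section", author_overlap="shared"),
        PlantSpec(4, "results_section", author_overlap="disjoint"),
        PlantSpec(6, "fulltext", author_overlap="shared"),
        PlantSpec(4, "fulltext", author_overlap="disjoint"),
        PlantSpec(6, "abstract_only", author_overlap="shared"),
        PlantSpec(2, "abstract_only", author_overlap="disjoint"),
        PlantSpec(1, "review_pair", author_overlap="shared", same_journal=True, same_year=True),
        PlantSpec(2, "review_pair", author_overlap="disjoint"),
        PlantSpec(4, "review_vs_research", author_overlap="disjoint"),
    ]


@dataclass
class GeneratorConfig:
    n_articles: int = 1000
    n_topics: int = 25
    vocab_size: int = 5000
    zipf_exponent: float = 0.5
    paragraphs_per_section: int = 3  # Poisson mean, min 1
    words_per_paragraph: int = 60  # Poisson mean, min 10
    abstract_words: int = 100
    authors_per_article: int = 4
    author_pool: int = 0  # 0 -> 3 * n_articles
    n_journals: int = 20
    year_range: tuple[int, int] = (2000, 2009)
    review_fraction: float = 0.075
    plants: list[PlantSpec] = field(default_factory=default_plan)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_articles, self.n_topics, self.vocab_size,
            self.paragraphs_per_section, self.words_per_paragraph,
            self.abstract_words, self.authors_per_article, self.n_journals,
        ) <= 0:
            raise ValueError("all generator counts must be positive")
        if not (0.0 <= self.review_fraction <= 1.0):
            raise ValueError("review_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedPair:
    article_a: str  # source
    article_b: str  # duplicate
    target: str
    copy_fraction: float
    author_overlap: str
    same_journal: bool
    same_year: bool


@dataclass
class GroundTruthLedger:
    """Ground truth emitted with every synthetic corpus: the planted pairs
    and per-article unit counts (sections, paragraphs)."""

    planted: list[PlantedPair]
    unit_counts: dict[str, dict[str, int]]

    def pairs_by_target(self, target: str) -> list[PlantedPair]:
        return [p for p in self.planted if p.target == target]

    def article_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((p.article_a, p.article_b))) for p in self.planted}


class _TopicModel:
    def __init__(self, config: GeneratorConfig) -> None:
        ranks = np.arange(1, config.vocab_size + 1, dtype=float)
        p = ranks ** (-config.zipf_exponent)
        self.probs = p / p.sum()
        self.vocab_size = config.vocab_size
        self._vocab: dict[int, list[str]] = {}

    def vocab(self, topic: int) -> list[str]:
        if topic not in self._vocab:
            self._vocab[topic] = [f"t{topic}w{i}" for i in range(self.vocab_size)]
        return self._vocab[topic]

    def draw(self, rng: np.random.Generator, topic: int, n: int) -> list[str]:
        idx = rng.choice(self.vocab_size, size=n, p=self.probs)
        vocab = self.vocab(topic)
        return [vocab[i] for i in idx]


def _copy_prefix(
    src: list[str], f: float, rng: np.random.Generator, tm: _TopicModel, topic: int
) -> list[str]:
    """Prefix-copy a fraction f of ``src`` tokens; resample the rest from the
    duplicate's own topic. f=1 reproduces src exactly."""
    k = round(f * len(src))
    if k >= len(src):
        return list(src)
    return list(src[:k]) + tm.draw(rng, topic, len(src) - k)


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[Article], GroundTruthLedger]:
    """Generate a synthetic corpus and its ground-truth ledger.

    Raises ``ValueError`` when the duplication plan needs more articles than
    ``n_articles`` (planted pairs use disjoint article sets).
    """
    rng = np.random.default_rng(config.seed)
    tm = _TopicModel(config)

    n_planted_articles = 2 * sum(p.n_pairs for p in config.plants)
    if n_planted_articles > config.n_articles:
        raise ValueError(
            f"duplication plan needs {n_planted_articles} articles but "
            f"n_articles={config.n_articles}"
        )

    pool = config.author_pool or max(3 * config.n_articles, 8 * config.authors_per_article)
    # letter-only surnames: author normalization keeps alphabetic chars only
    def _surname(i: int) -> str:
        s = ""
        i += 1
        while i:
            i, r = divmod(i - 1, 26)
            s = chr(ord("a") + r) + s
        return s.capitalize()

    author_names = [f"Auth{_surname(i)}, A." for i in range(pool)]

    def sample_authors(exclude: set[int] | None = None) -> list[int]:
        size = min(pool, config.authors_per_article * 3)
        cand = rng.choice(pool, size=size, replace=False)
        picked: list[int] = []
        for c in cand:
            if exclude and int(c) in exclude:
                continue
            picked.append(int(c))
            if len(picked) == config.authors_per_article:
                break
        if len(picked) < config.authors_per_article:
            raise ValueError("author pool too small for the requested overlap plan")
        return picked

    # --- structural draws, one article at a time, in a fixed order --------
    articles: list[Article] = []
    topics: list[int] = []
    author_ids: list[list[int]] = []

    def make_background(aid: str, topic: int, pub_type: PubType) -> Article:
        authors = sample_authors()
        author_ids.append(authors)
        sections: list[Section] = []
        for sec_title, sec_class in _SECTION_TEMPLATE:
            n_par = max(1, int(rng.poisson(config.paragraphs_per_section)))
            paragraphs = []
            for _ in range(n_par):
                n_words = max(10, int(rng.poisson(config.words_per_paragraph)))
                paragraphs.append(" ".join(tm.draw(rng, topic, n_words)))
            sections.append(Section(sec_class, sec_title, paragraphs))
        abstract = " ".join(tm.draw(rng, topic, config.abstract_words))
        title_toks = tm.draw(rng, topic, 4)
        return Article(
            article_id=aid,
            title=f"Synthetic study {' '.join(title_toks)}",
            abstract=abstract,
            authors=[author_names[i] for i in authors],
            journal=f"J{int(rng.integers(config.n_journals))}",
            year=int(rng.integers(config.year_range[0], config.year_range[1] + 1)),
            pub_type=pub_type,
            sections=sections,
        )

    n = config.n_articles
    for i in range(n):
        topic = int(rng.integers(config.n_topics))
        topics.append(topic)
        is_review = rng.random() < config.review_fraction
        articles.append(
            make_background(
                f"A{i:05d}", topic, PubType.REVIEW if is_review else PubType.RESEARCH
            )
        )

    # --- planting ----------------------------------------------------------
    order = rng.permutation(n)
    planted: list[PlantedPair] = []
    cursor = 0
    for spec in config.plants:
        for _ in range(spec.n_pairs):
            ia, ib = int(order[cursor]), int(order[cursor + 1])
            cursor += 2
            src, dup = articles[ia], articles[ib]
            topic_b = topics[ib]
            if topic_b == topics[ia]:  # force distinct topics for the pair
                topic_b = (topics[ia] + 1) % config.n_topics
                topics[ib] = topic_b
            f = spec.copy_fraction

            # pub types
            if spec.target == "review_pair":
                src.pub_type = PubType.REVIEW
                dup.pub_type = PubType.REVIEW
            elif spec.target == "review_vs_research":
                src.pub_type = PubType.RESEARCH
                dup.pub_type = PubType.REVIEW

            # text
            if spec.target == "abstract_only":
                src_abs = src.abstract.split()
                dup.abstract = " ".join(_copy_prefix(src_abs, f, rng, tm, topic_b))
            else:
                target_class = _TARGET_SECTION.get(spec.target)
                new_sections: list[Section] = []
                for sec in src.sections:
                    if target_class is None or sec.section_class == target_class:
                        paragraphs = [
                            " ".join(_copy_prefix(p.split(), f, rng, tm, topic_b))
                            for p in sec.paragraphs
                        ]
                        new_sections.append(Section(sec.section_class, sec.title, paragraphs))
                    else:
                        # keep the duplicate's own background section
                        match = [
                            s for s in dup.sections if s.section_class == sec.section_class
                        ]
                        new_sections.append(match[0] if match else dup.sections[0])
                dup.sections = new_sections

            # authors
            src_set = set(author_ids[ia])
            if spec.author_overlap == "shared":
                shared = int(rng.choice(sorted(src_set)))
                others = [x for x in sample_authors(exclude=src_set)][
                    : config.authors_per_article - 1
                ]
                new_ids = [shared] + others
            else:
                new_ids = sample_authors(exclude=src_set)
            author_ids[ib] = new_ids
            dup.authors = [author_names[i] for i in new_ids]

            # journal / year
            if spec.same_journal:
                dup.journal = src.journal
            elif dup.journal == src.journal:
                dup.journal = f"J{(int(src.journal[1:]) + 1) % config.n_journals}"
            if spec.same_year:
                dup.year = src.year
            elif dup.year == src.year:
                dup.year = src.year + 1 if src.year < config.year_range[1] else src.year - 1

            planted.append(
                PlantedPair(
                    article_a=src.article_id,
                    article_b=dup.article_id,
                    target=spec.target,
                    copy_fraction=f,
                    author_overlap=spec.author_overlap,
                    same_journal=spec.same_journal,
                    same_year=spec.same_year,
                )
            )

    unit_counts = {
        a.article_id: {
            "sections": len(a.sections),
            "paragraphs": sum(len(s.paragraphs) for s in a.sections),
        }
        for a in articles
    }
    ledger = GroundTruthLedger(planted=planted, unit_counts=unit_counts)
    _validate_ledger(articles, ledger)
    return articles, ledger


def _validate_ledger(corpus: Sequence[Article], ledger: GroundTruthLedger) -> None:
    """Ledger fidelity check run on every generation: planted pairs exist and
    each targeted unit achieves its recorded token-overlap fraction."""
    arts = {a.article_id: a for a in corpus}
    for p in ledger.planted:
        if p.article_a not in arts or p.article_b not in arts:
            raise AssertionError("ledger references a missing article")
        if p.target == "abstract_only":
            achieved = _overlap_fraction(
                arts[p.article_a].abstract.split(), arts[p.article_b].abstract.split()
            )
        else:
            cls = _TARGET_SECTION.get(p.target)
            src_tokens, dup_tokens = [], []
            for s in arts[p.article_a].sections:
                if cls is None or s.section_class == cls:
                    src_tokens += " ".join(s.paragraphs).split()
            for s in arts[p.article_b].sections:
                if cls is None or s.section_class == cls:
                    dup_tokens += " ".join(s.paragraphs).split()
            achieved = _overlap_fraction(src_tokens, dup_tokens)
        # prefix copying guarantees achieved overlap ~= f up to per-paragraph rounding
        if abs(achieved - p.copy_fraction) > 0.05 + 2.0 / 60:
            raise AssertionError(
                f"planted pair {p.article_a}/{p.article_b} achieved overlap "
                f"{achieved:.3f}, recorded f={p.copy_fraction}"
            )


def _overlap_fraction(src: list[str], dup: list[str]) -> float:
    from collections import Counter

    cs, cd = Counter(src), Counter(dup)
    inter = sum(min(c, cd[t]) for t, c in cs.items() if t in cd)
    return inter / max(len(src), 1)


# ---------------------------------------------------------------------------
# calibration

def calibration_curve(
    f_grid: Sequence[float],
    n_reps: int = 10,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> list[dict[str, float]]:
    """Mean detected pair ratio as a function of the copy fraction f.

    For each f and replicate, a minimal two-article corpus with one
    full-text plant at that f is generated (disjoint background topics) and
    the full-text pair ratio is measured. Monotone non-decreasing in f in
    expectation; f=1 yields ratio 1 exactly, f=0 yields 0.
    """
    from .corpus_model import Granularity, extract_units
    from .similarity import build_weights, similarity_ratio

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = config or GeneratorConfig(
        n_articles=2, n_topics=2, plants=[], review_fraction=0.0
    )
    rows: list[dict[str, float]] = []
    for f in f_grid:
        if not (0.0 <= f <= 1.0):
            raise ValueError("f_grid values must lie in [0, 1]")
        ratios = []
        for rep in range(n_reps):
            cfg = GeneratorConfig(
                n_articles=base.n_articles,
                n_topics=base.n_topics,
                vocab_size=base.vocab_size,
                zipf_exponent=base.zipf_exponent,
                paragraphs_per_section=base.paragraphs_per_section,
                words_per_paragraph=base.words_per_paragraph,
                abstract_words=base.abstract_words,
                review_fraction=0.0,
                plants=[PlantSpec(1, "fulltext", copy_fraction=f)],
                seed=(seed * 1000003 + rep * 101 + int(f * 1000)) % (2**31 - 1),
            )
            corpus, ledger = generate_corpus(cfg)
            ds = extract_units(corpus, Granularity.FULLTEXT)
            weights = build_weights(ds)
            units = {u.article_id: u for u in ds.included()}
            pp = ledger.planted[0]
            fwd = similarity_ratio(units[pp.article_b], units[pp.article_a], weights).ratio
            rev = similarity_ratio(units[pp.article_a], units[pp.article_b], weights).ratio
            ratios.append(max(fwd, rev))
        arr = np.asarray(ratios)
        rows.append(
            {"f": float(f), "mean_ratio": float(arr.mean()), "sd_ratio": float(arr.std())}
        )
    return rows


# ---------------------------------------------------------------------------
# labeled duplicate-pair fixture (synthetic stand-in for a manually curated
# duplicate set; reproduces only target per-section exceedance fractions)

def make_duplicate_fixture(
    n_pairs: int = 193,
    targets: dict[str, float] | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> list[dict[str, object]]:
    """Emit labeled duplicate pairs whose per-section fraction of ratios
    above ``threshold`` equals round(target * n)/n for each section.

    ``targets`` maps intro/methods/results to fractions in [0, 1]. The
    achieved fraction is the nearest one representable at ``n_pairs``; a
    target outside [0, 1] is rejected.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    targets = targets or {"intro": 0.82, "methods": 0.89, "results": 0.94}
    rng = np.random.default_rng(seed)
    records: list[dict[str, object]] = [
        {"pair_id": f"D{i:04d}", "shared_author": bool(rng.random() < 0.5)}
        for i in range(n_pairs)
    ]
    for key in ("intro", "methods", "results"):
        t = targets[key]
        if not (0.0 <= t <= 1.0):
            k = min(max(round(t * n_pairs), 0), n_pairs)
            raise ValueError(
                f"target {t} for {key} not achievable; nearest achievable "
                f"fraction is {k / n_pairs:.4f}"
            )
        k = round(t * n_pairs)
        above = set(rng.permutation(n_pairs)[:k].tolist())
        for i, rec in enumerate(records):
            if i in above:
                val = threshold + 0.05 + (1.0 - threshold - 0.05) * rng.random()
            else:
                val = (threshold - 0.05) * rng.random()
            rec[f"{key}_ratio"] = round(float(val), 4)
    return records


def write_fixture_tsv(records: Sequence[dict[str, object]], path: str | Path) -> None:
    cols = ("pair_id", "intro_ratio", "methods_ratio", "results_ratio", "shared_author")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                f"{r['pair_id']}\t{r['intro_ratio']}\t{r['methods_ratio']}\t"
                f"{r['results_ratio']}\t{int(bool(r['shared_author']))}\n"
            )


def read_fixture_tsv(path: str | Path) -> list[dict[str, object]]:
    out: list[dict[str, object]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            rec: dict[str, object] = dict(zip(header, vals))
            for k in ("intro_ratio", "methods_ratio", "results_ratio"):
                if rec.get(k) not in (None, ""):
                    rec[k] = float(rec[k])  # type: ignore[arg-type]
            rec["shared_author"] = bool(int(rec["shared_author"]))  # type: ignore[arg-type]
            out.append(rec)
    return out


def write_ledger_tsv(ledger: GroundTruthLedger, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "article_a\tarticle_b\ttarget\tcopy_fraction\tauthor_overlap\t"
            "same_journal\tsame_year\n"
        )
        for p in ledger.planted:
            fh.write(
                f"{p.article_a}\t{p.article_b}\t{p.target}\t{p.copy_fraction}\t"
                f"{p.author_overlap}\t{int(p.same_journal)}\t{int(p.same_year)}\n"
            )
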