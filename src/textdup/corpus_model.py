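"""Structured article corpus: JATS parsing, IMRaD section classification,
paragraph segmentation and extraction of comparison datasets.

An :class:`Article` is the unit of the census — title, abstract, author list,
journal, year, publication type (research vs review) and an ordered list of
classified body sections, each a list of paragraphs. Articles without a body
are retained as citation-only records: they count as retrieved citations but
contribute no full-text units to similarity scans.

The on-disk corpus format is JSON Lines, one article per line, with the
schema ``{id, title, abstract, authors, journal, year, pub_type,
sections: [{class, title, paragraphs}]}``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

from .text import AuthorKey, author_key, tokenize


class SectionClass(str, Enum):
    INTRODUCTION = "INTRODUCTION"
    METHODS = "METHODS"
    RESULTS_DISCUSSION = "RESULTS_DISCUSSION"
    OTHER = "OTHER"
    NONE = "NONE"


class Granularity(str, Enum):
    FULLTEXT = "FULLTEXT"
    ABSTRACT = "ABSTRACT"
    SECTION = "SECTION"
    PARAGRAPH = "PARAGRAPH"


class PubType(str, Enum):
    RESEARCH = "research"
    REVIEW = "review"


# Keyword table for classifying section titles (case-folded substring match).
# Precedence on multiple matches: INTRODUCTION > METHODS > RESULTS_DISCUSSION.
SECTION_KEYWORDS: dict[SectionClass, tuple[str, ...]] = {
    SectionClass.INTRODUCTION: ("introduction", "background"),
    SectionClass.METHODS: ("method", "methods", "materials", "experimental procedure"),
    SectionClass.RESULTS_DISCUSSION: ("result", "discussion", "conclusion"),
}

_CLASS_ORDER = (
    SectionClass.INTRODUCTION,
    SectionClass.METHODS,
    SectionClass.RESULTS_DISCUSSION,
)


def classify_section(
    title: str, keywords: dict[SectionClass, tuple[str, ...]] | None = None
) -> SectionClass:
    """Classify a section title into the IMRaD scheme by keyword matching.

    Total and deterministic: any string (including empty) maps to a class;
    titles matching no keyword map to ``OTHER``.
    """
    table = keywords if keywords is not None else SECTION_KEYWORDS
    folded = title.casefold()
    for cls in _CLASS_ORDER:
        if any(kw in folded for kw in table.get(cls, ())):
            return cls
    return SectionClass.OTHER


@dataclass
class Section:
    section_class: SectionClass
    title: str
    paragraphs: list[str]


@dataclass
class Article:
    article_id: str
    title: str = ""
    abstract: str = ""
    authors: list[str] = field(default_factory=list)
    journal: str = ""
    year: int = 0
    pub_type: PubType = PubType.RESEARCH
    sections: list[Section] = field(default_factory=list)

    def author_keys(self) -> frozenset[AuthorKey]:
        """Normalized author identity keys; empty when authors are unknown
        (such articles are excluded from shared-author statistics)."""
        keys = (author_key(a) for a in self.authors)
        return frozenset(k for k in keys if k is not None)

    @property
    def has_body(self) -> bool:
        return any(s.paragraphs for s in self.sections)

    def to_record(self) -> dict:
        return {
            "id": self.article_id,
            "title": self.title,
            "abstract": self.abstract,
            "authors": list(self.authors),
            "journal": self.journal,
            "year": self.year,
            "pub_type": self.pub_type.value,
            "sections": [
                {
                    "class": s.section_class.value,
                    "title": s.title,
                    "paragraphs": list(s.paragraphs),
                }
                for s in self.sections
            ],
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Article":
        return cls(
            article_id=rec["id"],
            title=rec.get("title", ""),
            abstract=rec.get("abstract", ""),
            authors=list(rec.get("authors", [])),
            journal=rec.get("journal", ""),
            year=int(rec.get("year", 0)),
            pub_type=PubType(rec.get("pub_type", "research")),
            sections=[
                Section(
                    section_class=SectionClass(s["class"]),
                    title=s.get("title", ""),
                    paragraphs=list(s["paragraphs"]),
                )
                for s in rec.get("sections", [])
            ],
        )


class JatsParseError(ValueError):
    """Raised for malformed JATS input or records missing an article id."""


_WS_RE = re.compile(r"\s+")


def _collapse_ws(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


def _element_text(el: etree._Element) -> str:
    return _collapse_ws(" ".join(el.itertext()))


def parse_jats(source: str | bytes | Path) -> Article:
    """Parse one JATS/NLM XML article into an :class:`Article`.

    ``source`` may be a path or an XML string/bytes. Text content is
    whitespace-normalized; body ``<sec>`` elements become classified
    sections in document order with their ``<p>`` descendants as paragraphs.
    Articles lacking a ``<body>`` yield no sections (the citation-only case).

    Raises :class:`JatsParseError` on malformed XML or a missing article-id.
    """
    try:
        if isinstance(source, Path):
            tree = etree.parse(str(source))
            root = tree.getroot()
        else:
            data = source.encode() if isinstance(source, str) else source
            root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise JatsParseError(f"malformed JATS XML: {exc}") from exc

    if root.tag != "article":
        art = root.find(".//article")
        if art is None:
            raise JatsParseError(f"no <article> element (root is <{root.tag}>)")
        root = art

    id_el = root.find(".//front/article-meta/article-id")
    if id_el is None or not (id_el.text or "").strip():
        raise JatsParseError("missing <article-id> in article-meta")
    article_id = id_el.text.strip()

    title_el = root.find(".//front/article-meta/title-group/article-title")
    title = _element_text(title_el) if title_el is not None else ""

    abstract_el = root.find(".//front/article-meta/abstract")
    abstract = _element_text(abstract_el) if abstract_el is not None else ""

    authors: list[str] = []
    for contrib in root.findall(".//front/article-meta/contrib-group/contrib"):
        if contrib.get("contrib-type", "author") != "author":
            continue
        name = contrib.find("name")
        if name is None:
            continue
        surname = _element_text(name.find("surname")) if name.find("surname") is not None else ""
        given = (
            _element_text(name.find("given-names"))
            if name.find("given-names") is not None
            else ""
        )
        if surname:
            authors.append(f"{surname}, {given}" if given else surname)

    journal_el = root.find(".//front/journal-meta//journal-title")
    journal = _element_text(journal_el) if journal_el is not None else ""

    year = 0
    year_el = root.find(".//front/article-meta/pub-date/year")
    if year_el is not None and (year_el.text or "").strip().isdigit():
        year = int(year_el.text.strip())

    atype = (root.get("article-type") or "").casefold()
    pub_type = PubType.REVIEW if "review" in atype else PubType.RESEARCH

    sections: list[Section] = []
    body = root.find("body")
    if body is not None:
        for sec in body.findall("sec"):
            sec_title_el = sec.find("title")
            sec_title = _element_text(sec_title_el) if sec_title_el is not None else ""
            paragraphs = [
                _element_text(p) for p in sec.iter("p") if _element_text(p)
            ]
            sections.append(
                Section(
                    section_class=classify_section(sec_title),
                    title=sec_title,
                    paragraphs=paragraphs,
                )
            )

    return Article(
        article_id=article_id,
        title=title,
        abstract=abstract,
        authors=authors,
        journal=journal,
        year=year,
        pub_type=pub_type,
        sections=sections,
    )


@dataclass
class TextUnit:
    """One comparable text span at a chosen granularity, tokenized."""

    unit_id: str
    article_id: str
    granularity: Granularity
    section_class: SectionClass
    tokens: list[str]
    excluded: bool = False

    @property
    def word_count(self) -> int:
        return len(self.tokens)


@dataclass
class UnitDataset:
    """A comparison dataset: units plus its own size (the normalization
    denominator used by the census — the count of non-excluded units)."""

    granularity: Granularity
    units: list[TextUnit]

    @property
    def size(self) -> int:
        return sum(1 for u in self.units if not u.excluded)

    def included(self) -> list[TextUnit]:
        return [u for u in self.units if not u.excluded]

    def __iter__(self) -> Iterator[TextUnit]:
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)


#: units shorter than this many tokens are flagged excluded, per granularity.
DEFAULT_MIN_WORDS: dict[Granularity, int] = {
    Granularity.FULLTEXT: 0,
    Granularity.ABSTRACT: 0,
    Granularity.SECTION: 0,
    Granularity.PARAGRAPH: 30,
}


def extract_units(
    corpus: Sequence[Article],
    granularity: Granularity | str,
    section_filter: SectionClass | str | None = None,
    min_words: int | None = None,
) -> UnitDataset:
    """Extract all text units of one granularity from a parsed corpus.

    ``section_filter`` restricts SECTION/PARAGRAPH units to one section
    class. Units below ``min_words`` tokens (default per-granularity, see
    :data:`DEFAULT_MIN_WORDS`) are flagged ``excluded`` but retained for
    audit; they do not count toward the dataset size.
    """
    granularity = Granularity(granularity)
    if section_filter is not None:
        section_filter = SectionClass(section_filter)
    if min_words is None:
        min_words = DEFAULT_MIN_WORDS[granularity]
    if min_words < 0:
        raise ValueError("min_words must be >= 0")

    units: list[TextUnit] = []
    for art in corpus:
        if granularity is Granularity.FULLTEXT:
            if not art.has_body:
                continue
            text = " ".join(p for s in art.sections for p in s.paragraphs)
            units.append(
                TextUnit(
                    f"{art.article_id}:full",
                    art.article_id,
                    granularity,
                    SectionClass.NONE,
                    tokenize(text),
                )
            )
        elif granularity is Granularity.ABSTRACT:
            if not art.abstract:
                continue
            units.append(
                TextUnit(
                    f"{art.article_id}:abs",
                    art.article_id,
                    granularity,
                    SectionClass.NONE,
                    tokenize(art.abstract),
                )
            )
        else:
            for i, sec in enumerate(art.sections):
                if section_filter is not None and sec.section_class != section_filter:
                    continue
                if granularity is Granularity.SECTION:
                    units.append(
                        TextUnit(
                            f"{art.article_id}:sec{i}",
                            art.article_id,
                            granularity,
                            sec.section_class,
                            tokenize(" ".join(sec.paragraphs)),
                        )
                    )
                else:
                    for j, para in enumerate(sec.paragraphs):
                        units.append(
                            TextUnit(
                                f"{art.article_id}:sec{i}:p{j}",
                                art.article_id,
                                granularity,
                                sec.section_class,
                                tokenize(para),
                            )
                        )
    for u in units:
        if u.word_count < min_words:
            u.excluded = True
    return UnitDataset(granularity=granularity, units=units)


# ---------------------------------------------------------------------------
# corpus I/O (JSON Lines) and unit manifest

def write_corpus(corpus: Iterable[Article], path: str | Path) -> None:
    """Write a corpus in the package JSONL format (one article per line,
    keys sorted — byte-deterministic for a given corpus)."""
    with open(path, "w", encoding="utf-8") as fh:
        for art in corpus:
            fh.write(json.dumps(art.to_record(), sort_keys=True) + "\n")


def read_corpus(path: str | Path) -> list[Article]:
    with open(path, encoding="utf-8") as fh:
        return [Article.from_record(json.loads(line)) for line in fh if line.strip()]


def write_unit_manifest(dataset: UnitDataset, path: str | Path) -> None:
    """TSV audit manifest: unit_id, article_id, granularity, section_class,
    word_count, excluded."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("unit_id\tarticle_id\tgranularity\tsection_class\tword_count\texcluded\n")
        for u in dataset.units:
            fh.write(
                f"{u.unit_id}\t{u.article_id}\t{u.granularity.value}\t"
                f"{u.section_class.value}\t{u.word_count}\t{int(u.excluded)}\n"
            )
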