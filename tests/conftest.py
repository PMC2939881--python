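from __future__ import annotations

from pathlib import Path

import pytest

from textdup.corpus_model import Article, Section, SectionClass
from textdup.pipeline import RunConfig
from textdup.synthetic import GeneratorConfig, PlantSpec

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def small_corpus() -> list[Article]:
    """2 articles x 3 sections x 2 paragraphs, with authors."""

    def art(i: int) -> Article:
        return Article(
            article_id=f"X{i}",
            title=f"Article {i}",
            abstract=f"abstract text of article {i} about topic{i}",
            authors=[f"Smith{i}, John", f"Jones{i}, Mary"],
            journal=f"J{i}",
            year=2000 + i,
            sections=[
                Section(cls, title, [f"para one of {title} in X{i} alpha{i}",
                                     f"para two of {title} in X{i} beta{i}"])
                for title, cls in (
                    ("Introduction", SectionClass.INTRODUCTION),
                    ("Methods", SectionClass.METHODS),
                    ("Results", SectionClass.RESULTS_DISCUSSION),
                )
            ],
        )

    return [art(1), art(2)]


def golden_run_config(out_dir: Path) -> RunConfig:
    """The fixed pipeline configuration behind the committed golden files."""
    gen = GeneratorConfig(
        n_articles=30,
        n_topics=4,
        vocab_size=1500,
        plants=[
            PlantSpec(2, "methods_section", 0.9, "shared"),
            PlantSpec(1, "intro_section", 0.9, "disjoint"),
            PlantSpec(1, "fulltext", 1.0, "shared"),
        ],
        seed=42,
    )
    return RunConfig(
        out_dir=str(out_dir),
        generator=gen,
        granularity="SECTION",
        threshold=0.5,
        seed=42,
    )
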