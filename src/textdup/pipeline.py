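"""End-to-end orchestration: simulate/parse -> extract -> scan -> census.

Every artifact written by a run carries a header comment with the serialized
run configuration, and identical (config, inputs) produce byte-identical
outputs, so pipeline runs are reproducible and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .corpus_model import (
    Article,
    Granularity,
    SectionClass,
    extract_units,
    read_corpus,
    write_corpus,
    write_unit_manifest,
)
from .census import (
    article_pairs,
    census,
    contingency,
    log10_odds_ratio,
    prediction_metrics,
    write_census_tsv,
    write_contingency_json,
)
from .similarity import ScanConfig, all_vs_all, build_weights, write_pairs
from .synthetic import GeneratorConfig, generate_corpus, write_ledger_tsv


@dataclass
class RunConfig:
    """Configuration of one pipeline run (fully serialized into outputs)."""

    out_dir: str
    corpus_path: str | None = None  # read an existing corpus instead of simulating
    generator: GeneratorConfig | None = None
    granularity: str = "SECTION"
    section_filter: str | None = None
    threshold: float = 0.5
    pairing: str = "either_direction"
    min_words: int | None = None
    seed: int = 0

    def header(self) -> str:
        """Logical run configuration (paths excluded so outputs are
        byte-identical across working directories)."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("corpus_path", None)
        if self.generator is not None:
            d["generator"]["plants"] = [asdict(p) for p in self.generator.plants]
        return "config " + json.dumps(d, sort_keys=True, default=str)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    corpus: list[Article]
    pairs_path: Path
    census_path: Path
    contingency_path: Path | None
    counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """simulate (or load) -> extract units -> scan -> census -> reports.

    Emits corpus.jsonl (when simulating), ledger.tsv, units.tsv, pairs.tsv,
    census.tsv and, when the corpus carries abstracts and bodies,
    contingency.json (abstract vs full-text similarity at the article level).
    On stage failure, partial outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, int] = {}
    try:
        # --- corpus stage ------------------------------------------------
        if config.corpus_path is not None:
            try:
                corpus = read_corpus(config.corpus_path)
            except Exception as exc:
                raise PipelineError(f"corpus stage: cannot read corpus: {exc}") from exc
        else:
            gen = config.generator or GeneratorConfig(seed=config.seed)
            corpus, ledger = generate_corpus(gen)
            p = out / "corpus.jsonl"
            write_corpus(corpus, p)
            written.append(p)
            p = out / "ledger.tsv"
            write_ledger_tsv(ledger, p)
            written.append(p)
        counts["articles_retrieved"] = len(corpus)
        counts["articles_with_body"] = sum(1 for a in corpus if a.has_body)

        # --- extraction stage ---------------------------------------------
        try:
            dataset = extract_units(
                corpus,
                Granularity(config.granularity.upper()),
                SectionClass(config.section_filter.upper())
                if config.section_filter
                else None,
                config.min_words,
            )
        except Exception as exc:
            raise PipelineError(f"extract stage: {exc}") from exc
        counts["units"] = len(dataset)
        counts["units_excluded"] = len(dataset) - dataset.size
        p = out / "units.tsv"
        write_unit_manifest(dataset, p)
        written.append(p)

        # --- scan stage ----------------------------------------------------
        try:
            scan_cfg = ScanConfig(
                threshold=config.threshold,
                pairing=config.pairing,
                top_k=max(400, len(dataset)),
                seed=config.seed,
            )
            author_index = {a.article_id: a.author_keys() for a in corpus}
            pairs = all_vs_all(dataset, scan_cfg, author_index=author_index)
        except Exception as exc:
            raise PipelineError(f"scan stage: {exc}") from exc
        counts["similar_pairs"] = len(pairs)
        pairs_path = out / "pairs.tsv"
        write_pairs(pairs, pairs_path, header_comment=config.header())
        written.append(pairs_path)

        # --- census stage ----------------------------------------------
        try:
            rows = {"all": census(pairs, dataset.size)}
            for cls in (
                SectionClass.INTRODUCTION,
                SectionClass.METHODS,
                SectionClass.RESULTS_DISCUSSION,
            ):
                sub = [
                    pr
                    for pr in pairs
                    if pr.section_class_a == cls and pr.section_class_b == cls
                ]
                n_cls = sum(1 for u in dataset.included() if u.section_class == cls)
                if n_cls:
                    rows[cls.value] = census(sub, n_cls)
        except Exception as exc:
            raise PipelineError(f"census stage: {exc}") from exc
        census_path = out / "census.tsv"
        write_census_tsv(rows, census_path, header_comment=config.header())
        written.append(census_path)

        # --- contingency stage (abstract vs fulltext) -----------------------
        contingency_path: Path | None = None
        abstracts = extract_units(corpus, Granularity.ABSTRACT)
        fulltexts = extract_units(corpus, Granularity.FULLTEXT)
        if abstracts.size >= 2 and fulltexts.size >= 2:
            author_index = {a.article_id: a.author_keys() for a in corpus}
            abs_pairs = article_pairs(
                all_vs_all(
                    abstracts,
                    ScanConfig(threshold=config.threshold, top_k=max(400, abstracts.size)),
                    author_index=author_index,
                )
            )
            ft_pairs = article_pairs(
                all_vs_all(
                    fulltexts,
                    ScanConfig(threshold=config.threshold, top_k=max(400, fulltexts.size)),
                    author_index=author_index,
                )
            )
            table = contingency(
                abs_pairs, ft_pairs, len(corpus), "abstract_similar", "fulltext_similar"
            )
            if table.a + table.b > 0:
                est = log10_odds_ratio(table, haldane=True)
                met = prediction_metrics(table)
                contingency_path = out / "contingency.json"
                write_contingency_json(table, est, met, contingency_path)
                written.append(contingency_path)

        return PipelineResult(corpus, pairs_path, census_path, contingency_path, counts)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
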