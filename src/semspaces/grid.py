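"""Experiment orchestration: the standard single-corpus RI/RP grid.

Runs the ten RI/RP pairings of :func:`semspaces.ensemble.standard_grid`
(identical windows 1+1/2+2/4+4 with both RP stop-word variants, plus the
wide 10+10 RI space with narrow RP spaces) against each requested task,
evaluating the three single-corpus combination strategies — pool-filtered
re-ranking in both directions and summed cosines — per pairing.  Trained
spaces are cached on disk keyed by corpus content, model, window,
stop-word variant and seed, so re-runs and overlapping pairings are
cheap.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from semspaces import corpus_io
from semspaces.corpus_io import Corpus, StopwordList
from semspaces.ensemble import combine_scores, combine_subset, standard_grid
from semspaces.evaluation import evaluate, filter_by_frequency, load_reference_standard
from semspaces.retrieval import OOVError, score_map
from semspaces.spaces import (
    IndexVectorConfig,
    SemanticSpace,
    WindowSpec,
    load_space,
    save_space,
    train_ri,
    train_rp,
)


class ConfigError(ValueError):
    """Invalid experiment configuration; the message lists all violations."""


@dataclass
class ExperimentConfig:
    corpora: dict[str, str]  # name -> corpus path (preprocessed, one segment/line)
    stopwords: str
    references: dict[str, str]  # task -> reference TSV path
    outdir: str
    seed: int = 0
    d: int = 1000
    n_nonzero: int = 8
    out_k: int = 10
    pool_k: int = 30
    min_frequency: int = 50
    tasks: list[str] = field(default_factory=lambda: ["abbr2exp", "exp2abbr", "syn"])
    strategies: list[str] = field(default_factory=lambda: ["RIinRP30", "RPinRI30", "RI+RP"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        for name, path in self.corpora.items():
            if not Path(path).is_file():
                problems.append(f"corpus {name!r}: missing file {path}")
        if not Path(self.stopwords).is_file():
            problems.append(f"missing stop-word file {self.stopwords}")
        for task, path in self.references.items():
            if task not in ("abbr2exp", "exp2abbr", "syn"):
                problems.append(f"unknown task {task!r}")
            if not Path(path).is_file():
                problems.append(f"reference for {task!r}: missing file {path}")
        for task in self.tasks:
            base = "abbr2exp" if task in ("abbr2exp", "exp2abbr") else task
            if base not in self.references and task not in self.references:
                problems.append(f"task {task!r} has no reference standard")
        if problems:
            raise ConfigError("; ".join(problems))


def _corpus_digest(corpus: Corpus) -> str:
    h = hashlib.blake2b(digest_size=8)
    for seg in corpus.segments:
        h.update(" ".join(seg.tokens).encode("utf-8"))
        h.update(b"\n")
    return h.hexdigest()


class SpaceCache:
    """Disk cache of trained spaces keyed by everything that determines them."""

    def __init__(self, cache_dir: str | Path):
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)

    def get(self, corpus: Corpus, model: str, window: WindowSpec,
            cfg: IndexVectorConfig) -> SemanticSpace:
        key = (f"{_corpus_digest(corpus)}_{model}_{window.left}-{window.right}"
               f"_sw{int(not corpus.stopwords_removed)}_d{cfg.d}_n{cfg.n_nonzero}"
               f"_s{cfg.seed}")
        path = self.cache_dir / f"{key}.npz"
        if path.exists():
            return load_space(path)
        train = train_ri if model == "RI" else train_rp
        space = train(corpus, window, cfg)
        save_space(space, path)
        return space


def query_outputs(
    spaces: list[SemanticSpace],
    queries: list[str],
    strategy: str,
    out_k: int = 10,
    pool_k: int = 30,
):
    """Per-query candidate lists under one combination strategy.

    ``spaces`` is [RI, RP] for the single-corpus strategies.  Out-of-
    vocabulary queries yield empty lists (counted as misses downstream).
    """
    outputs = {}
    for query in queries:
        try:
            if strategy == "RIinRP30":
                outputs[query] = combine_subset(spaces[0], spaces[1], query,
                                                out_k=out_k, pool_k=pool_k)
            elif strategy == "RPinRI30":
                outputs[query] = combine_subset(spaces[1], spaces[0], query,
                                                out_k=out_k, pool_k=pool_k)
            elif strategy == "RI+RP":
                maps = [score_map(s, query) for s in spaces]
                outputs[query] = combine_scores(maps, mode="SUM", out_k=out_k,
                                                query=query)
            else:
                raise ConfigError(f"unknown strategy {strategy!r}")
        except OOVError:
            outputs[query] = []
    return outputs


def run_standard_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Train the grid, run every (corpus, pairing, strategy, task) cell and
    write a P/R summary plus per-query detail under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = SpaceCache(outdir / "spaces")
    stopwords = corpus_io.load_stopwords(config.stopwords)
    rows = []
    for corpus_name, corpus_path in config.corpora.items():
        raw = corpus_io.read_corpus(corpus_path)
        with_sw = corpus_io.preprocess_segments(raw, name=corpus_name)
        without_sw = corpus_io.remove_stopwords(with_sw, stopwords)
        freq = corpus_io.term_frequencies(with_sw)
        icfg = IndexVectorConfig(d=config.d, n_nonzero=config.n_nonzero,
                                 seed=config.seed)
        for task in config.tasks:
            base_task = task if task in config.references else "abbr2exp"
            if base_task not in config.references:
                continue
            ref = load_reference_standard(config.references[base_task], task=task)
            ref = filter_by_frequency(ref, freq, min_count=config.min_frequency)
            if not ref.tuples:
                continue
            queries = sorted(ref.queries())
            for combo in standard_grid():
                rp_corpus = with_sw if combo["rp_stopwords_retained"] else without_sw
                ri = cache.get(without_sw, "RI", combo["ri_window"], icfg)
                rp = cache.get(rp_corpus, "RP", combo["rp_window"], icfg)
                for strategy in config.strategies:
                    outputs = query_outputs([ri, rp], queries, strategy,
                                            out_k=config.out_k, pool_k=config.pool_k)
                    report = evaluate(outputs, ref, k=config.out_k)
                    label = (f"RI_{combo['ri_window']}+RP_{combo['rp_window']}"
                             f"{'_sw' if combo['rp_stopwords_retained'] else ''}")
                    row = report.summary_row(strategy=strategy)
                    row.update({"corpus": corpus_name, "combination": label})
                    rows.append(row)
                    report.to_json(outdir / f"{corpus_name}_{label}_{strategy}_{task}.json")
    summary = pd.DataFrame(rows, columns=["corpus", "combination", "strategy",
                                          "task", "P", "R", "n_queries"])
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return summary
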