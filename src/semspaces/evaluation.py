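"""Reference standards and the terminology-extraction evaluation harness.

A reference standard is a set of gold tuples for one task: synonym groups
(``syn``, every term queried for every other term in its group, i.e. both
directions of a pair) or abbreviation–expansion tuples (first column the
abbreviation, remaining columns its expansions; queried in the task's
direction only: ``abbr2exp`` or ``exp2abbr``).  Multiword terms are
removed because the spaces model unigrams only, and tuples are filtered
by a minimum corpus frequency (default 50 in every supplied corpus)
because distributional representations of rare terms are unreliable.

Performance is measured as recall@k (micro-averaged over (query, gold)
pairs) and rank-weighted precision: a true positive at 0-based rank ``i``
within the first ``j`` suggestions scores ``j - i``, and the per-query
score is normalised by the maximum attainable ``sum_{i<j} (j - i)``.
Paired systems are compared with the exact binomial sign test over
per-query successes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom

from semspaces.corpus_io import FrequencyTable

TASKS = ("abbr2exp", "exp2abbr", "syn")


class ReferenceStandardError(ValueError):
    """Raised for malformed reference-standard files."""


@dataclass(frozen=True)
class ReferenceStandard:
    task: str
    tuples: tuple[tuple[str, ...], ...]
    split_label: str = "all"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        for tup in self.tuples:
            if len(tup) < 2:
                raise ValueError(f"reference tuple needs >= 2 terms: {tup}")

    def __len__(self) -> int:
        return len(self.tuples)

    def queries(self) -> dict[str, set[str]]:
        """Query term -> gold terms, per the task's querying direction."""
        out: dict[str, set[str]] = {}
        for tup in self.tuples:
            if self.task == "syn":
                for q in tup:
                    out.setdefault(q, set()).update(t for t in tup if t != q)
            elif self.task == "abbr2exp":
                out.setdefault(tup[0], set()).update(tup[1:])
            else:  # exp2abbr
                for exp in tup[1:]:
                    out.setdefault(exp, set()).add(tup[0])
        return out

    def terms(self) -> set[str]:
        return {t for tup in self.tuples for t in tup}

    def retask(self, task: str) -> "ReferenceStandard":
        """Same tuples queried in another direction (abbreviation tasks)."""
        return replace(self, task=task)


def load_reference_standard(path: str | Path, task: str,
                            lowercase: bool = True) -> ReferenceStandard:
    """Read a TSV reference standard (one tuple per line, >= 2 columns).

    Whitespace-containing (multiword) terms are dropped, and a tuple is
    dropped entirely if fewer than two terms remain.
    """
    tuples: list[tuple[str, ...]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            terms = line.split("\t")
            if len(terms) < 2:
                raise ReferenceStandardError(
                    f"{path}:{lineno}: expected >= 2 tab-separated terms")
            cleaned = []
            for term in terms:
                term = term.strip()
                if lowercase:
                    term = term.lower()
                if term and " " not in term:
                    cleaned.append(term)
            if len(cleaned) >= 2:
                tuples.append(tuple(cleaned))
    return ReferenceStandard(task=task, tuples=tuple(tuples))


def save_reference_standard(ref: ReferenceStandard, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tup in ref.tuples:
            fh.write("\t".join(tup) + "\n")


def split_dev_eval(ref: ReferenceStandard, seed: int) -> tuple[ReferenceStandard, ReferenceStandard]:
    """Random tuple-level split into development and evaluation halves of
    roughly equal size (difference at most one tuple), deterministic per seed."""
    if len(ref) < 2:
        raise ValueError("need at least two tuples to split")
    order = list(ref.tuples)
    random.Random(seed).shuffle(order)
    half = (len(order) + 1) // 2
    dev = replace(ref, tuples=tuple(order[:half]), split_label="dev")
    ev = replace(ref, tuples=tuple(order[half:]), split_label="eval")
    return dev, ev


def filter_by_frequency(
    ref: ReferenceStandard,
    freq_tables: FrequencyTable | Sequence[FrequencyTable],
    min_count: int = 50,
) -> ReferenceStandard:
    """Keep a tuple iff every term occurs at least ``min_count`` times in
    every supplied frequency table."""
    if isinstance(freq_tables, FrequencyTable):
        freq_tables = [freq_tables]
    if not freq_tables:
        raise ValueError("need at least one frequency table")
    kept = tuple(
        tup for tup in ref.tuples
        if all(table[t] >= min_count for t in tup for table in freq_tables)
    )
    return replace(ref, tuples=kept)


def _terms_of(output) -> list[str]:
    """Ordered candidate terms of a CandidateList/FilteredList or plain list."""
    if hasattr(output, "terms"):
        return output.terms()
    return [getattr(c, "term", c) for c in output]


def recall_at_k(outputs: Mapping[str, object], ref: ReferenceStandard, k: int = 10) -> float:
    """Micro-averaged recall: the share of (query, gold) pairs whose gold
    term appears among the query's first ``k`` suggestions.  Queries with
    no output (e.g. out-of-vocabulary) count as misses."""
    queries = ref.queries()
    hits = 0
    total = 0
    for query, gold in queries.items():
        suggested = set(_terms_of(outputs.get(query, []))[:k])
        total += len(gold)
        hits += len(gold & suggested)
    return hits / total if total else 0.0


def weighted_precision(candidates, gold: Iterable[str], j: int | None = None) -> float:
    """Rank-weighted precision over the first ``j`` suggestions.

    ``j`` defaults to 10 in fixed mode; under a dynamic cut-off pass the
    returned list length instead.
    """
    terms = _terms_of(candidates)
    if j is None:
        j = 10
    if j < 1:
        raise ValueError("j must be >= 1")
    gold = set(gold)
    score = sum(j - i for i, t in enumerate(terms[:j]) if t in gold)
    max_score = sum(j - i for i in range(j))
    return score / max_score


def sign_test_exact(hits_a: Sequence[bool], hits_b: Sequence[bool]) -> float:
    """Two-sided exact binomial sign test on paired per-query successes.

    Discordant pairs are modelled as Binomial(n, 1/2); the p-value is
    ``min(1, 2 * min(P(X <= k), P(X >= k)))`` where ``k`` counts wins for
    the first system.  With no discordant pairs the p-value is 1.
    """
    if len(hits_a) != len(hits_b):
        raise ValueError("paired samples must have equal length")
    k = sum(1 for a, b in zip(hits_a, hits_b) if a and not b)
    n = k + sum(1 for a, b in zip(hits_a, hits_b) if b and not a)
    if n == 0:
        return 1.0
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class EvalReport:
    task: str
    n_queries: int
    recall_at_k: float
    mean_weighted_precision: float
    k: int
    per_query: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "task": self.task,
            "n_queries": self.n_queries,
            "k": self.k,
            "recall_at_k": self.recall_at_k,
            "mean_weighted_precision": self.mean_weighted_precision,
            "per_query": self.per_query,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    def summary_row(self, strategy: str = "") -> dict:
        return {
            "strategy": strategy,
            "task": self.task,
            "P": round(self.mean_weighted_precision, 4),
            "R": round(self.recall_at_k, 4),
            "n_queries": self.n_queries,
        }


def evaluate(
    outputs: Mapping[str, object],
    ref: ReferenceStandard,
    k: int = 10,
    dynamic: bool = False,
) -> EvalReport:
    """Full evaluation of per-query outputs against a reference standard.

    Recall is micro-averaged over (query, gold) pairs; precision is the
    mean per-query weighted precision with ``j = k`` (or the returned list
    length when ``dynamic`` is set).
    """
    queries = ref.queries()
    per_query: list[dict] = []
    precisions: list[float] = []
    for query in sorted(queries):
        gold = queries[query]
        output = outputs.get(query, [])
        terms = _terms_of(output)
        j = max(1, len(terms)) if dynamic else k
        wp = weighted_precision(terms, gold, j=j) if terms else 0.0
        precisions.append(wp)
        per_query.append({
            "query": query,
            "gold": sorted(gold),
            "suggested": terms[:k],
            "hits": sorted(gold & set(terms[:k])),
            "weighted_precision": wp,
        })
    return EvalReport(
        task=ref.task,
        n_queries=len(queries),
        recall_at_k=recall_at_k(outputs, ref, k=k),
        mean_weighted_precision=(sum(precisions) / len(precisions)) if precisions else 0.0,
        k=k,
        per_query=per_query,
    )


def frequency_threshold_sweep(
    outputs: Mapping[str, object],
    ref: ReferenceStandard,
    freq_tables: FrequencyTable | Sequence[FrequencyTable],
    thresholds: Iterable[int] = range(1, 101),
    k: int = 10,
) -> pd.DataFrame:
    """Recall and query count as the minimum-frequency threshold varies.

    Re-filters the reference standard at each threshold and re-scores the
    same per-query outputs, mirroring the usual threshold-sweep protocol
    (thresholds 1..100 by default).
    """
    rows = []
    for threshold in thresholds:
        filtered = filter_by_frequency(ref, freq_tables, min_count=threshold)
        queries = filtered.queries()
        rows.append({
            "threshold": threshold,
            "n_queries": len(queries),
            "recall": recall_at_k(outputs, filtered, k=k) if queries else float("nan"),
        })
    return pd.DataFrame(rows)
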