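"""Cosine similarity and top-k nearest-neighbour queries against a space."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from semspaces.spaces import SemanticSpace


class OOVError(KeyError):
    """Query term not in the space's vocabulary."""


@dataclass(frozen=True)
class Candidate:
    term: str
    score: float
    rank: int


@dataclass
class CandidateList:
    """Ranked candidates for one query.

    ``score_kind`` records what the score means (plain/summed/averaged
    cosine, or a rank sum/average, where for rank-based kinds the list is
    sorted ascending — zero is the best score).
    """

    query: str
    candidates: list[Candidate]
    score_kind: str = "cosine"
    source: str = ""

    def terms(self) -> list[str]:
        return [c.term for c in self.candidates]

    def score_map(self) -> dict[str, float]:
        return {c.term: c.score for c in self.candidates}

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for c in self.candidates:
                fh.write(f"{c.rank}\t{c.term}\t{c.score:.6g}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "query": self.query,
            "score_kind": self.score_kind,
            "source": self.source,
            "candidates": [
                {"rank": c.rank, "term": c.term, "score": c.score} for c in self.candidates
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors; an all-zero vector is treated
    as maximally dissimilar (similarity 0)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _all_cosines(space: SemanticSpace, query: str) -> np.ndarray:
    qv = space.vector(query)
    qnorm = np.linalg.norm(qv)
    norms = np.linalg.norm(space.matrix, axis=1)
    scores = np.zeros(space.vocab_size)
    if qnorm > 0.0:
        nonzero = norms > 0.0
        scores[nonzero] = (space.matrix[nonzero] @ qv) / (norms[nonzero] * qnorm)
    return scores


def top_k_neighbors(
    space: SemanticSpace,
    query: str,
    k: int = 10,
    exclude: set[str] | None = None,
) -> CandidateList:
    """The ``k`` highest-cosine terms for ``query`` (ties broken
    lexicographically), never including the query itself."""
    if query not in space:
        raise OOVError(query)
    if exclude is None:
        exclude = {query}
    else:
        exclude = set(exclude) | {query}
    scores = _all_cosines(space, query)
    # stable order: descending score, then lexicographic on the term
    vocab_order = np.lexsort((np.array(space.vocab), -scores))
    candidates: list[Candidate] = []
    for idx in vocab_order:
        term = space.vocab[idx]
        if term in exclude:
            continue
        candidates.append(Candidate(term=term, score=float(scores[idx]), rank=len(candidates)))
        if len(candidates) == k:
            break
    return CandidateList(
        query=query,
        candidates=candidates,
        score_kind="cosine",
        source=f"{space.model}_{space.window}@{space.corpus_name}",
    )


def score_map(space: SemanticSpace, query: str) -> dict[str, float]:
    """Cosine of the query against every other vocabulary term (the full-depth
    per-space output that the ensemble strategies combine)."""
    if query not in space:
        raise OOVError(query)
    scores = _all_cosines(space, query)
    return {t: float(scores[i]) for i, t in enumerate(space.vocab) if t != query}
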