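"""Combination strategies for ensembles of semantic spaces.

Single-corpus strategies combine one RI space with one RP space:

* ``combine_subset`` — membership filter from one space's top-30 pool,
  ordering from the other space (RI⊂RP₃₀ and RP⊂RI₃₀ by argument order);
* ``combine_scores`` with two maps — RI+RP, summed cosines.

Multi-corpora strategies combine the four spaces (RI and RP from each of
two corpora) either in a single step (SUM / AVG, optionally rank-
normalised) or in two steps (per-corpus combination, rank normalisation,
then a cross-corpus SUM or AVG over ranks).  Rank normalisation replaces
cosines by the 0-based position in the candidate list, so combined lists
sort ascending — zero is the best score; a term absent from a list
receives a penalty rank equal to the normalisation horizon, so absence is
never an advantage.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from semspaces.retrieval import (
    Candidate,
    CandidateList,
    OOVError,
    cosine_similarity,
    score_map,
    top_k_neighbors,
)
from semspaces.spaces import SemanticSpace, WindowSpec

SUM = "SUM"
AVG = "AVG"


def _ranked_terms(scores: Mapping[str, float]) -> list[str]:
    """Terms sorted by descending score, ties lexicographic."""
    return sorted(scores, key=lambda t: (-scores[t], t))


def rank_normalize(ranked: CandidateList | Sequence[str] | Mapping[str, float],
                   horizon: int | None = None) -> dict[str, int]:
    """Map each term to its 0-based rank; positions at or beyond ``horizon``
    are clamped to the penalty rank ``horizon`` (ascending = better)."""
    if isinstance(ranked, CandidateList):
        terms = ranked.terms()
    elif isinstance(ranked, Mapping):
        terms = _ranked_terms(ranked)
    else:
        terms = list(ranked)
    if horizon is None:
        horizon = len(terms)
    return {t: min(i, horizon) for i, t in enumerate(terms)}


def combine_subset(
    rank_space: SemanticSpace,
    pool_space: SemanticSpace,
    query: str,
    out_k: int = 10,
    pool_k: int = 30,
) -> CandidateList:
    """Top ``out_k`` terms of ``rank_space`` among ``pool_space``'s top
    ``pool_k`` terms (e.g. RI⊂RP₃₀ = combine_subset(ri, rp))."""
    if pool_k < out_k:
        raise ValueError("pool_k must be >= out_k")
    if query not in rank_space:
        raise OOVError(query)
    pool = top_k_neighbors(pool_space, query, k=pool_k).terms()
    qv = rank_space.vector(query)
    scores = {
        t: cosine_similarity(qv, rank_space.vector(t)) for t in pool if t in rank_space
    }
    order = _ranked_terms(scores)[:out_k]
    candidates = [Candidate(term=t, score=scores[t], rank=i) for i, t in enumerate(order)]
    return CandidateList(
        query=query,
        candidates=candidates,
        score_kind="cosine",
        source=f"{rank_space.model}_in_{pool_space.model}{pool_k}",
    )


def combine_scores(
    score_maps: Sequence[Mapping[str, float]],
    mode: str = SUM,
    normalize: bool = False,
    out_k: int = 10,
    horizon: int | None = None,
    query: str = "",
    source: str = "",
) -> CandidateList:
    """Single-step combination of per-space score maps.

    SUM adds each term's cosine across the maps (absent terms contribute
    0); AVG divides the sum by the number of maps in which the term
    exists.  With ``normalize`` the cosines are first replaced by ranks
    (penalty ``horizon`` for absent terms) and the combined list sorts
    ascending.
    """
    if len(score_maps) < 2:
        raise ValueError("need at least two score maps to combine")
    if mode not in (SUM, AVG):
        raise ValueError(f"unknown combination mode {mode!r}")
    union: set[str] = set()
    for m in score_maps:
        union.update(m)
    if normalize:
        if horizon is None:
            horizon = len(union)
        rank_maps = [rank_normalize(m, horizon=horizon) for m in score_maps]
        combined = {t: float(sum(rm.get(t, horizon) for rm in rank_maps)) for t in union}
        kind = "rank_sum"
    else:
        combined = {t: float(sum(m.get(t, 0.0) for m in score_maps)) for t in union}
        kind = "summed_cosine"
    if mode == AVG:
        count = {t: sum(1 for m in score_maps if t in m) for t in union}
        combined = {t: combined[t] / count[t] for t in union}
        kind = "rank_avg" if normalize else "averaged_cosine"
    if normalize:
        order = sorted(union, key=lambda t: (combined[t], t))
    else:
        order = _ranked_terms(combined)
    order = order[:out_k]
    candidates = [Candidate(term=t, score=combined[t], rank=i) for i, t in enumerate(order)]
    return CandidateList(query=query, candidates=candidates, score_kind=kind, source=source)


def combine_two_step(
    pair_a: Sequence[Mapping[str, float]],
    pair_b: Sequence[Mapping[str, float]],
    step1: str = SUM,
    step2: str = SUM,
    out_k: int = 10,
    horizon: int | None = None,
    query: str = "",
    source: str = "",
) -> CandidateList:
    """Two-step multi-corpora combination.

    Each per-corpus pair of score maps is first combined with the
    ``step1`` mode (AVG divides by the number of spaces *within the pair*
    containing the term); the two combined lists are rank-normalised; the
    normalised ranks are then combined with ``step2`` (AVG divides by the
    number of source spaces — across both pairs — containing the term).
    The final list sorts ascending on the combined rank score.
    """
    if step1 not in (SUM, AVG) or step2 not in (SUM, AVG):
        raise ValueError("step modes must be SUM or AVG")
    if len(pair_a) < 2 or len(pair_b) < 2:
        raise ValueError("each corpus pair needs at least two score maps")

    def step1_scores(pair: Sequence[Mapping[str, float]]) -> dict[str, float]:
        terms: set[str] = set()
        for m in pair:
            terms.update(m)
        scores = {t: sum(m.get(t, 0.0) for m in pair) for t in terms}
        if step1 == AVG:
            scores = {t: s / sum(1 for m in pair if t in m) for t, s in scores.items()}
        return scores

    scores_a = step1_scores(pair_a)
    scores_b = step1_scores(pair_b)
    union = set(scores_a) | set(scores_b)
    if horizon is None:
        horizon = len(union)
    ranks_a = rank_normalize(scores_a, horizon=horizon)
    ranks_b = rank_normalize(scores_b, horizon=horizon)
    combined = {
        t: float(ranks_a.get(t, horizon) + ranks_b.get(t, horizon)) for t in union
    }
    kind = "rank_sum"
    if step2 == AVG:
        all_maps = list(pair_a) + list(pair_b)
        count = {t: sum(1 for m in all_maps if t in m) for t in union}
        combined = {t: combined[t] / count[t] for t in union}
        kind = "rank_avg"
    order = sorted(union, key=lambda t: (combined[t], t))[:out_k]
    candidates = [Candidate(term=t, score=combined[t], rank=i) for i, t in enumerate(order)]
    return CandidateList(query=query, candidates=candidates, score_kind=kind, source=source)


def ensemble_query(
    spaces: Sequence[SemanticSpace],
    query: str,
    mode: str = SUM,
    normalize: bool = False,
    out_k: int = 10,
    horizon: int | None = None,
) -> CandidateList:
    """Convenience wrapper: single-step combination of whole spaces."""
    maps = [score_map(s, query) for s in spaces]
    source = "+".join(f"{s.model}_{s.window}@{s.corpus_name}" for s in spaces)
    return combine_scores(
        maps, mode=mode, normalize=normalize, out_k=out_k, horizon=horizon,
        query=query, source=source,
    )


def standard_grid() -> list[dict]:
    """The standard single-corpus experiment grid: ten RI/RP pairings.

    Identical windows 1+1 / 2+2 / 4+4 (RP with stop words removed and
    retained) plus the wide 10+10 RI space paired with narrow 1+1 / 2+2 RP
    spaces (again in both stop-word variants).
    """
    grid: list[dict] = []
    for w in (1, 2, 4):
        for sw in (False, True):
            grid.append({
                "ri_window": WindowSpec(w, w),
                "rp_window": WindowSpec(w, w),
                "rp_stopwords_retained": sw,
            })
    for w in (1, 2):
        for sw in (False, True):
            grid.append({
                "ri_window": WindowSpec(10, 10),
                "rp_window": WindowSpec(w, w),
                "rp_stopwords_retained": sw,
            })
    return grid
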