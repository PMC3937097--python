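"""Rule-based post-filtering of candidate lists.

Abbreviation tasks use structural rules: a valid abbreviation has at most
four letters, its expansion more than four, the abbreviation's letters
occur in the expansion in the same order, and both share the initial
letter.  The synonym task instead uses cosine/rank cut-off profiles tuned
per corpus setting (``clinical``, ``medical``, ``combined`` — the last on
summed cosines, which range up to four over a four-space ensemble).

Two filtering modes are provided.  The fixed mode (``refill_top10``)
scans candidates in rank order until ten are accepted or one hundred have
been classified, then backfills any remaining slots with the highest-
ranked rejected candidates, so it always suggests a full list.  The
dynamic cut-off mode returns only the accepted candidates (between one
and ten); when nothing is accepted, the single highest-ranked candidate
is suggested.
"""

from __future__ import annotations

import math
import unicodedata
from dataclasses import dataclass
from typing import Callable, Sequence

from semspaces.retrieval import Candidate, CandidateList


@dataclass(frozen=True)
class AbbrevRule:
    max_abbrev_len: int = 4
    min_expansion_len: int = 5

    def __post_init__(self) -> None:
        if self.max_abbrev_len >= self.min_expansion_len:
            raise ValueError("max_abbrev_len must be < min_expansion_len")


@dataclass(frozen=True)
class SynonymRule:
    """Disjunction of (cosine threshold, exclusive max rank) clauses."""

    profile: str
    clauses: tuple[tuple[float, float], ...]

    def __call__(self, cos: float, rank: int) -> bool:
        return accept_synonym(cos, rank, self)


SYNONYM_PROFILES: dict[str, SynonymRule] = {
    "clinical": SynonymRule("clinical", ((0.60, math.inf), (0.40, 9))),
    "medical": SynonymRule("medical", ((0.50, math.inf),)),
    "combined": SynonymRule("combined", ((1.9, math.inf), (1.8, 6), (1.75, 3))),
}


def synonym_rule(profile: str) -> SynonymRule:
    try:
        return SYNONYM_PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown synonym profile {profile!r}; choose from {sorted(SYNONYM_PROFILES)}"
        ) from None


def _letters(s: str) -> str:
    return "".join(c for c in s.lower() if unicodedata.category(c).startswith("L"))


def letter_length(s: str) -> int:
    """Length in letters only (punctuation/digits are already stripped upstream,
    but counting letters keeps the rule robust to raw input)."""
    return len(_letters(s))


def ordered_subsequence_same_initial(short: str, long: str) -> bool:
    """True iff both strings start with the same letter and every letter of
    ``short`` occurs in ``long`` in the same order (greedy subsequence test,
    case-insensitive, non-letters ignored)."""
    if not short or not long:
        raise ValueError("terms must be non-empty")
    s = _letters(short)
    l = _letters(long)
    if not s or not l or s[0] != l[0]:
        return False
    pos = 0
    for ch in s:
        pos = l.find(ch, pos)
        if pos < 0:
            return False
        pos += 1
    return True


def accept_exp_to_abbr(query_expansion: str, candidate: str,
                       rule: AbbrevRule = AbbrevRule()) -> bool:
    """Expansion query -> abbreviation candidate: candidate has fewer than
    five letters and is an ordered same-initial subsequence of the query."""
    return (
        letter_length(candidate) < rule.min_expansion_len
        and ordered_subsequence_same_initial(candidate, query_expansion)
    )


def accept_abbr_to_exp(query_abbr: str, candidate: str,
                       rule: AbbrevRule = AbbrevRule()) -> bool:
    """Abbreviation query -> expansion candidate: candidate has more than
    four letters and contains the query as an ordered same-initial
    subsequence."""
    return (
        letter_length(candidate) > rule.max_abbrev_len
        and ordered_subsequence_same_initial(query_abbr, candidate)
    )


def accept_synonym(cos: float, rank: int, rule: SynonymRule) -> bool:
    """True iff any profile clause is satisfied: cosine at or above the
    clause threshold and 0-based rank strictly below the clause's max."""
    if rank < 0:
        raise ValueError("rank must be >= 0")
    return any(cos >= threshold and rank < max_rank for threshold, max_rank in rule.clauses)


def task_predicate(task: str, query: str,
                   rule: AbbrevRule | SynonymRule | None = None) -> Callable[[Candidate], bool]:
    """Candidate-level acceptance predicate for one query of a given task."""
    if task == "abbr2exp":
        abbrev = rule if isinstance(rule, AbbrevRule) else AbbrevRule()
        return lambda c: accept_abbr_to_exp(query, c.term, abbrev)
    if task == "exp2abbr":
        abbrev = rule if isinstance(rule, AbbrevRule) else AbbrevRule()
        return lambda c: accept_exp_to_abbr(query, c.term, abbrev)
    if task == "syn":
        if not isinstance(rule, SynonymRule):
            raise ValueError("the synonym task needs a SynonymRule profile")
        return lambda c: accept_synonym(c.score, c.rank, rule)
    raise ValueError(f"unknown task {task!r}")


@dataclass
class FilteredList:
    """Post-filtered candidates with per-candidate accepted/padded flags."""

    query: str
    candidates: list[Candidate]
    accepted: list[bool]
    mode: str = "refill"
    source: str = ""

    def terms(self) -> list[str]:
        return [c.term for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)


def _rerank(query: str, chosen: Sequence[Candidate], flags: Sequence[bool],
            mode: str, source: str) -> FilteredList:
    reranked = [
        Candidate(term=c.term, score=c.score, rank=i) for i, c in enumerate(chosen)
    ]
    return FilteredList(query=query, candidates=reranked, accepted=list(flags),
                        mode=mode, source=source)


def refill_top10(
    candidates: CandidateList | Sequence[Candidate],
    accept: Callable[[Candidate], bool],
    out_k: int = 10,
    scan_limit: int = 100,
) -> FilteredList:
    """Fixed-size filtering: accepted candidates first (original relative
    order), backfilled with the highest-ranked rejected candidates."""
    query = candidates.query if isinstance(candidates, CandidateList) else ""
    source = candidates.source if isinstance(candidates, CandidateList) else ""
    stream = list(candidates)[:scan_limit]
    kept: list[Candidate] = []
    rejected: list[Candidate] = []
    for cand in stream:
        if accept(cand):
            kept.append(cand)
            if len(kept) == out_k:
                break
        else:
            rejected.append(cand)
    flags = [True] * len(kept)
    pads = rejected[: out_k - len(kept)]
    flags.extend([False] * len(pads))
    return _rerank(query, kept + pads, flags, "refill", source)


def dynamic_cutoff(
    candidates: CandidateList | Sequence[Candidate],
    accept: Callable[[Candidate], bool],
    max_k: int = 10,
    scan_limit: int = 100,
) -> FilteredList:
    """Dynamic-size filtering: only accepted candidates (at most ``max_k``);
    when none are accepted, the single highest-ranked candidate."""
    query = candidates.query if isinstance(candidates, CandidateList) else ""
    source = candidates.source if isinstance(candidates, CandidateList) else ""
    stream = list(candidates)[:scan_limit]
    kept = [c for c in stream if accept(c)][:max_k]
    if kept:
        return _rerank(query, kept, [True] * len(kept), "dynamic", source)
    if not stream:
        return FilteredList(query=query, candidates=[], accepted=[], mode="dynamic",
                            source=source)
    return _rerank(query, stream[:1], [False], "dynamic", source)
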