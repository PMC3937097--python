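"""Corpus reading, normalisation and frequency tables.

A corpus is an ordered sequence of *segments* (sentences or short clinical
notes); a segment is the hard context boundary — sliding windows used
during space induction never cross it.  Preprocessing strips punctuation
and digits from tokens, lowercases by default, and optionally removes
stop words (closing up the positions, as in the stop-word-filtered corpus
versions used for Random Indexing spaces).
"""

from __future__ import annotations

import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator


class CorpusError(ValueError):
    """Raised for empty corpora or invalid preprocessing configuration."""


@dataclass(frozen=True)
class Segment:
    """One context unit: an id and its ordered tokens."""

    id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    name: str
    segments: list[Segment]
    stopwords_removed: bool = False

    @property
    def token_count(self) -> int:
        return sum(len(s) for s in self.segments)

    @property
    def type_count(self) -> int:
        return len({t for s in self.segments for t in s.tokens})

    def iter_tokens(self) -> Iterator[str]:
        for seg in self.segments:
            yield from seg.tokens

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class StopwordList:
    """A set of stop-word terms (roughly 150 high-frequency terms in practice)."""

    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise CorpusError("stop-word list must be non-empty when supplied")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "StopwordList":
        return cls(frozenset(terms))


@dataclass
class FrequencyTable:
    """Exact per-term token counts for one corpus."""

    counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, term: str) -> int:
        return self.counts.get(term, 0)

    def __contains__(self, term: str) -> bool:
        return term in self.counts

    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in sorted(self.counts):
                fh.write(f"{term}\t{self.counts[term]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        counts: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                term, count = line.split("\t")
                counts[term] = int(count)
        return cls(counts)


def read_corpus(path: str | Path, dialect: str = "line", name: str | None = None) -> list[Segment]:
    """Read raw segments from a UTF-8 text file.

    ``dialect='line'``: one segment per line, empty lines skipped.
    ``dialect='blank'``: segments are blank-line-separated blocks.
    """
    if dialect not in ("line", "blank"):
        raise ValueError(f"unknown corpus dialect: {dialect!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    segments: list[Segment] = []
    if dialect == "line":
        for line in text.splitlines():
            tokens = tuple(line.split())
            if tokens:
                segments.append(Segment(id=f"s{len(segments)}", tokens=tokens))
    else:
        block: list[str] = []
        for line in text.splitlines() + [""]:
            if line.strip():
                block.extend(line.split())
            elif block:
                segments.append(Segment(id=f"s{len(segments)}", tokens=tuple(block)))
                block = []
    if not segments:
        raise CorpusError(f"no non-empty segments in {path}")
    return segments


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write one segment per line (the default dialect); round-trips exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for seg in corpus.segments:
            fh.write(" ".join(seg.tokens) + "\n")


def load_stopwords(path: str | Path) -> StopwordList:
    """One term per line; ``#`` starts a comment."""
    terms = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                terms.add(line)
    return StopwordList(frozenset(terms))


def _strip_token(token: str) -> str:
    # Unicode punctuation (category P*) and decimal digits (Nd) are removed;
    # letters such as å/ä/ö are kept like any other letter.
    return "".join(
        c for c in token
        if not unicodedata.category(c).startswith("P") and unicodedata.category(c) != "Nd"
    )


def preprocess_segments(
    raw: Iterable[Segment],
    stopwords: StopwordList | None = None,
    remove_stopwords: bool = False,
    lowercase: bool = True,
    lemmatizer: Callable[[str], str] | None = None,
    name: str = "corpus",
) -> Corpus:
    """Normalise raw segments into a trainable :class:`Corpus`.

    Punctuation and digits are stripped from every token; tokens emptied by
    stripping are dropped, and segments emptied entirely are dropped.  When
    ``remove_stopwords`` is set the stop-word tokens are deleted from the
    stream and the surrounding positions close up.  ``lemmatizer`` is an
    optional per-token hook applied after lowercasing (no lemmatizer is
    shipped; lemmatisation is an external pre-step).
    """
    if remove_stopwords and stopwords is None:
        raise CorpusError("remove_stopwords=True requires a stop-word list")
    segments: list[Segment] = []
    for seg in raw:
        tokens: list[str] = []
        for token in seg.tokens:
            token = _strip_token(token)
            if not token:
                continue
            if lowercase:
                token = token.lower()
            if lemmatizer is not None:
                token = lemmatizer(token)
                if not token:
                    continue
            if remove_stopwords and token in stopwords:  # type: ignore[operator]
                continue
            tokens.append(token)
        if tokens:
            segments.append(Segment(id=seg.id, tokens=tuple(tokens)))
    return Corpus(name=name, segments=segments, stopwords_removed=remove_stopwords)


def remove_stopwords(corpus: Corpus, stopwords: StopwordList) -> Corpus:
    """Stop-word-filtered copy of an already preprocessed corpus."""
    segments = []
    for seg in corpus.segments:
        tokens = tuple(t for t in seg.tokens if t not in stopwords)
        if tokens:
            segments.append(Segment(id=seg.id, tokens=tokens))
    return Corpus(name=corpus.name, segments=segments, stopwords_removed=True)


def term_frequencies(corpus: Corpus) -> FrequencyTable:
    """Exact token counts per term; the total equals the corpus token count."""
    if not corpus.segments:
        raise CorpusError("cannot count frequencies of an empty corpus")
    counts: Counter[str] = Counter()
    for seg in corpus.segments:
        counts.update(seg.tokens)
    return FrequencyTable(dict(counts))
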