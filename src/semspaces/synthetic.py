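"""Synthetic corpora with planted synonym and abbreviation-expansion pairs.

The generator emulates the statistical structure that distributional
synonym extraction relies on, in two genre-distinct corpora:

* a Zipf-distributed background vocabulary partitioned round-robin over a
  set of topics; each segment is assigned a topic and its tokens are drawn
  from a mixture of the topic's own words and the global distribution;
* planted *lexemes*, each with two surface forms — either a synonym pair
  or an abbreviation and its expansion (the abbreviation is an ordered
  letter-subsequence of the expansion sharing its initial letter, at most
  four letters against at least five);
* each lexeme owns a small set of shared *signature* collocates from its
  home topic, and each surface form additionally owns a few *private*
  collocates; every placed occurrence of a form overwrites some of its
  window neighbours with collocates drawn from the shared set, the form's
  private set or (as noise) the topic at large.  The two forms therefore
  share neighbours — a paradigmatic relation — without ever co-occurring,
  but their context distributions overlap only partially, as real
  near-synonyms' do;
* *genre skew*: each corpus prefers one surface form of every lexeme, the
  minority form still meeting the configured frequency floor, so the two
  corpora contribute complementary evidence.

Per-form occurrence counts are planned deterministically (majority/
minority split from the skew, spread log-uniformly above the floor) and
validated against the available topic slots before generation, so the
frequency floor holds by construction.  Everything is reproducible from
the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from semspaces.corpus_io import Corpus, Segment, StopwordList, term_frequencies, write_corpus
from semspaces.evaluation import ReferenceStandard, save_reference_standard
from semspaces.postfilter import ordered_subsequence_same_initial

_LETTERS = "abcdefghijklmnopqrstuvwxyzåäö"


class SynthConfigError(ValueError):
    """Raised when a configuration cannot satisfy its own frequency floors."""


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    vocab_size: int = 2000
    n_topics: int = 20
    n_synonym_pairs: int = 20
    n_abbrev_pairs: int = 10
    segments_per_corpus: int = 30000
    segment_length: int = 10
    min_pair_frequency: int = 60
    genre_skew: float = 0.8  # probability mass of the corpus-preferred form
    zipf_exponent: float = 1.1
    topic_mix: float = 0.6  # share of background tokens drawn from the segment's topic
    n_signature_terms: int = 6  # shared collocates per lexeme
    n_private_terms: int = 3  # form-specific collocates per surface form
    sig_per_occurrence: int = 2  # neighbours overwritten per planted occurrence
    p_shared: float = 0.5  # collocate draw: shared vs form-private set
    sig_noise: float = 0.25  # collocate draw: replaced by a topic word at large
    freq_spread: float = 4.0  # lexeme floors spread log-uniformly in [1.15, spread] x floor

    def __post_init__(self) -> None:
        n_lexemes = self.n_synonym_pairs + self.n_abbrev_pairs
        if self.vocab_size <= 2 * n_lexemes:
            raise SynthConfigError("vocab_size must exceed twice the planted pair count")
        if not 0.5 <= self.genre_skew <= 1.0:
            raise SynthConfigError("genre_skew must lie in [0.5, 1]")
        if self.genre_skew >= 1.0:
            raise SynthConfigError(
                "genre_skew = 1 leaves the minority surface form with zero "
                "occurrences, so the frequency floor cannot be met")
        if self.min_pair_frequency < 1:
            raise SynthConfigError("min_pair_frequency must be >= 1")
        if self.freq_spread < 1.0:
            raise SynthConfigError("freq_spread must be >= 1")


@dataclass
class SynthBundle:
    corpus_a: Corpus
    corpus_b: Corpus
    ref_syn: ReferenceStandard
    ref_abbr: ReferenceStandard
    stopwords: StopwordList
    truth: dict
    config: SynthConfig


def _unique_words(rng: np.random.Generator, n: int, min_len: int, max_len: int,
                  taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < n:
        length = int(rng.integers(min_len, max_len + 1))
        word = "".join(_LETTERS[i] for i in rng.integers(0, len(_LETTERS), size=length))
        if word not in taken:
            taken.add(word)
            words.append(word)
    return words


def _make_abbreviation(rng: np.random.Generator, expansion: str, taken: set[str]) -> str:
    """Ordered letter-subsequence of the expansion keeping the initial letter."""
    for _ in range(200):
        n_extra = int(rng.integers(1, 4))  # total length 2..4
        positions = sorted(rng.choice(np.arange(1, len(expansion)), size=n_extra,
                                      replace=False))
        abbr = expansion[0] + "".join(expansion[p] for p in positions)
        if abbr not in taken:
            taken.add(abbr)
            return abbr
    raise SynthConfigError(f"could not derive a fresh abbreviation from {expansion!r}")


def _plan_counts(cfg: SynthConfig, rng: np.random.Generator,
                 n_lexemes: int) -> list[tuple[int, int]]:
    """(majority, minority) occurrence counts per lexeme and corpus.

    The minority form's count sits a safety margin above the configured
    floor, spread log-uniformly so planted pairs span a range of corpus
    frequencies; the majority count follows from the genre skew.
    """
    plans = []
    lo, hi = math.log(1.15), math.log(max(cfg.freq_spread, 1.16))
    for _ in range(n_lexemes):
        u = math.exp(rng.uniform(lo, hi))
        minority = math.ceil(cfg.min_pair_frequency * u)
        majority = math.ceil(minority * cfg.genre_skew / (1.0 - cfg.genre_skew))
        plans.append((majority, minority))
    return plans


def _validate_capacity(cfg: SynthConfig, plans: list[tuple[int, int]],
                       home_topics: list[int]) -> None:
    per_topic_needed = [0] * cfg.n_topics
    for (majority, minority), topic in zip(plans, home_topics):
        per_topic_needed[topic] += majority + minority
    available = (cfg.segments_per_corpus // cfg.n_topics) * cfg.segment_length
    for topic, needed in enumerate(per_topic_needed):
        # form slots plus their signature overwrites must fit comfortably
        if needed * (1 + cfg.sig_per_occurrence) > 0.8 * available:
            raise SynthConfigError(
                f"frequency floor unachievable: topic {topic} needs {needed} "
                f"planted occurrences but only ~{available} token slots exist; "
                "increase segments_per_corpus or lower min_pair_frequency")


def _generate_corpus(
    cfg: SynthConfig,
    rng: np.random.Generator,
    name: str,
    background: list[str],
    topic_members: list[np.ndarray],
    global_weights: np.ndarray,
    lexemes: list[dict],
    preferred_form: int,
) -> Corpus:
    n_seg, seg_len = cfg.segments_per_corpus, cfg.segment_length
    vocab = background + [form for lex in lexemes for form in lex["forms"]]
    bg_index = {w: i for i, w in enumerate(background)}
    form_id = {form: len(background) + i
               for i, form in enumerate(f for lex in lexemes for f in lex["forms"])}
    tokens = np.empty((n_seg, seg_len), dtype=np.int64)
    seg_topics = np.arange(n_seg) % cfg.n_topics

    # background fill: mixture of topic-specific and global Zipf draws
    for topic in range(cfg.n_topics):
        rows = np.where(seg_topics == topic)[0]
        n_tok = rows.size * seg_len
        members = topic_members[topic]
        w = global_weights[members]
        w = w / w.sum()
        from_topic = rng.random(n_tok) < cfg.topic_mix
        draw = np.empty(n_tok, dtype=np.int64)
        n_topic_draws = int(from_topic.sum())
        draw[from_topic] = rng.choice(members, size=n_topic_draws, p=w)
        draw[~from_topic] = rng.choice(len(background), size=n_tok - n_topic_draws,
                                       p=global_weights)
        tokens[rows] = draw.reshape(rows.size, seg_len)

    # phase 1: place every surface-form token on its own slot
    is_form = np.zeros((n_seg, seg_len), dtype=bool)
    occurrences: list[tuple[int, int, np.ndarray, np.ndarray, np.ndarray]] = []
    for topic in range(cfg.n_topics):
        topic_lexemes = [lex for lex in lexemes if lex["topic"] == topic]
        if not topic_lexemes:
            continue
        rows = np.where(seg_topics == topic)[0]
        slots = [(int(r), p) for r in rows for p in range(seg_len)]
        order = rng.permutation(len(slots))
        cursor = 0
        topic_ids = topic_members[topic]
        for lex in topic_lexemes:
            majority, minority = lex["plan"]
            counts = (majority, minority) if preferred_form == 0 else (minority, majority)
            shared_ids = np.array([bg_index[s] for s in lex["signatures"]], dtype=np.int64)
            for form, count in zip(lex["forms"], counts):
                fid = form_id[form]
                private_ids = np.array([bg_index[s] for s in lex["private"][form]],
                                       dtype=np.int64)
                for _ in range(count):
                    r, p = slots[order[cursor]]
                    cursor += 1
                    tokens[r, p] = fid
                    is_form[r, p] = True
                    occurrences.append((r, p, shared_ids, private_ids, topic_ids))

    # phase 2: overwrite window neighbours with collocates — shared signature
    # words, form-private words, or topic noise — in a globally shuffled order
    # so no form systematically clobbers another form's collocates
    for occ_idx in rng.permutation(len(occurrences)):
        r, p, shared_ids, private_ids, topic_ids = occurrences[occ_idx]
        neigh = [q for q in (p - 2, p - 1, p + 1, p + 2)
                 if 0 <= q < seg_len and not is_form[r, q]]
        if not neigh:
            continue
        chosen = rng.permutation(len(neigh))[: cfg.sig_per_occurrence]
        for ci in chosen:
            u = rng.random()
            if u < cfg.sig_noise:
                pool = topic_ids
            elif u < cfg.sig_noise + (1 - cfg.sig_noise) * cfg.p_shared:
                pool = shared_ids
            else:
                pool = private_ids
            tokens[r, neigh[ci]] = pool[int(rng.integers(0, len(pool)))]

    vocab_arr = np.array(vocab, dtype=object)
    segments = [
        Segment(id=f"{name}-s{i}", tokens=tuple(vocab_arr[tokens[i]]))
        for i in range(n_seg)
    ]
    return Corpus(name=name, segments=segments, stopwords_removed=False)


def generate_bundle(cfg: SynthConfig) -> SynthBundle:
    """Generate two genre-skewed corpora plus matching reference standards."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EAD]))
    taken: set[str] = set()
    background = _unique_words(rng, cfg.vocab_size, 4, 9, taken)

    ranks = np.arange(1, cfg.vocab_size + 1, dtype=float)
    global_weights = ranks ** (-cfg.zipf_exponent)
    global_weights /= global_weights.sum()
    topic_members = [np.arange(t, cfg.vocab_size, cfg.n_topics)
                     for t in range(cfg.n_topics)]

    n_lexemes = cfg.n_synonym_pairs + cfg.n_abbrev_pairs
    home_topics = [i % cfg.n_topics for i in range(n_lexemes)]
    plans = _plan_counts(cfg, rng, n_lexemes)
    _validate_capacity(cfg, plans, home_topics)

    # collocate sets: mid-frequency topic words, exclusive per lexeme/form
    sig_pool_used: dict[int, int] = {t: 0 for t in range(cfg.n_topics)}
    per_lexeme_words = cfg.n_signature_terms + 2 * cfg.n_private_terms
    lexemes: list[dict] = []
    for i in range(n_lexemes):
        topic = home_topics[i]
        members = topic_members[topic]
        pool_start = len(members) // 4  # skip the most stopword-like ranks
        start = pool_start + sig_pool_used[topic]
        if start + per_lexeme_words > len(members):
            raise SynthConfigError(
                f"topic {topic} has too few words for exclusive collocate sets; "
                "increase vocab_size or n_topics")
        block = [background[j] for j in members[start:start + per_lexeme_words]]
        sig_pool_used[topic] += per_lexeme_words
        signatures = block[: cfg.n_signature_terms]
        # interleave so both forms get frequency-matched private collocates
        rest = block[cfg.n_signature_terms:]
        private_blocks = (rest[0::2], rest[1::2])
        if i < cfg.n_synonym_pairs:
            forms = tuple(_unique_words(rng, 2, 5, 9, taken))
            kind = "syn"
        else:
            expansion = _unique_words(rng, 1, 8, 12, taken)[0]
            abbr = _make_abbreviation(rng, expansion, taken)
            forms = (abbr, expansion)
            kind = "abbr"
        lexemes.append({
            "id": f"lex{i}",
            "kind": kind,
            "topic": topic,
            "forms": forms,
            "signatures": signatures,
            "private": {form: block for form, block in zip(forms, private_blocks)},
            "plan": plans[i],
        })

    rng_a = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA]))
    rng_b = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB]))
    corpus_a = _generate_corpus(cfg, rng_a, "genre_a", background, topic_members,
                                global_weights, lexemes, preferred_form=0)
    corpus_b = _generate_corpus(cfg, rng_b, "genre_b", background, topic_members,
                                global_weights, lexemes, preferred_form=1)

    ref_syn = ReferenceStandard(
        task="syn",
        tuples=tuple(lex["forms"] for lex in lexemes if lex["kind"] == "syn"),
    )
    ref_abbr = ReferenceStandard(
        task="abbr2exp",
        tuples=tuple(lex["forms"] for lex in lexemes if lex["kind"] == "abbr"),
    )
    stop_terms = [background[i] for i in np.argsort(-global_weights)[:20]]
    bundle = SynthBundle(
        corpus_a=corpus_a,
        corpus_b=corpus_b,
        ref_syn=ref_syn,
        ref_abbr=ref_abbr,
        stopwords=StopwordList(frozenset(stop_terms)),
        truth={lex["id"]: {k: v for k, v in lex.items() if k != "id"} for lex in lexemes},
        config=cfg,
    )
    _check_bundle(bundle)
    return bundle


def _check_bundle(bundle: SynthBundle) -> None:
    cfg = bundle.config
    freq_a = term_frequencies(bundle.corpus_a)
    freq_b = term_frequencies(bundle.corpus_b)
    for ref in (bundle.ref_syn, bundle.ref_abbr):
        for tup in ref.tuples:
            for term in tup:
                if freq_a[term] < cfg.min_pair_frequency or freq_b[term] < cfg.min_pair_frequency:
                    raise AssertionError(
                        f"planted term {term!r} misses the frequency floor "
                        f"({freq_a[term]}/{freq_b[term]} < {cfg.min_pair_frequency})")
    for abbr, expansion in bundle.ref_abbr.tuples:
        if not ordered_subsequence_same_initial(abbr, expansion):
            raise AssertionError(f"planted pair {abbr!r}/{expansion!r} violates the "
                                 "subsequence constraint")


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> None:
    """Write corpora, reference TSVs, stop words and truth metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus(bundle.corpus_a, outdir / "corpus_a.txt")
    write_corpus(bundle.corpus_b, outdir / "corpus_b.txt")
    save_reference_standard(bundle.ref_syn, outdir / "ref_syn.tsv")
    save_reference_standard(bundle.ref_abbr, outdir / "ref_abbr.tsv")
    (outdir / "stopwords.txt").write_text(
        "\n".join(sorted(bundle.stopwords.terms)) + "\n", encoding="utf-8")
    truth = {
        lex_id: {**meta, "plan": list(meta["plan"])}
        for lex_id, meta in bundle.truth.items()
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1), encoding="utf-8")
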