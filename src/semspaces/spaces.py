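"""Random Indexing and Random Permutation semantic-space induction.

Each term-as-context gets a static sparse ternary *index vector*: a
``d``-dimensional vector (default d=1000) with ``n_nonzero`` randomly
placed nonzeros (default 8: four +1 and four -1), so index vectors are
near-orthogonal.  A term's *context vector* is accumulated by sliding a
window over every segment and adding the index vectors of the in-window
neighbours of each occurrence:

* Random Indexing (RI): neighbour index vectors are added with a distance
  weight ``2^(1 - dist)``, where ``dist`` is the number of token positions
  between neighbour and target (the immediate neighbour has weight 1).
* Random Permutation (RP): neighbour index vectors are added unweighted,
  but circularly rotated by the neighbour's signed offset — a neighbour
  two positions to the left is shifted two positions toward lower indices,
  one position to the right one step toward higher indices — so word order
  is encoded in the vector.

Windows never cross segment boundaries.  Index vectors are derived
deterministically from a stable hash of ``(seed, term)``, so RI and RP
spaces over the same corpus and seed share index vectors and retraining is
exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from semspaces.corpus_io import Corpus

_FORMAT_VERSION = 1


class SpaceFormatError(ValueError):
    """Raised when a persisted space file cannot be read back."""


@dataclass(frozen=True)
class IndexVectorConfig:
    d: int = 1000
    n_nonzero: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonzero % 2 != 0:
            raise ValueError("n_nonzero must be even (balanced +1/-1)")
        if not 0 < self.n_nonzero <= self.d:
            raise ValueError("need 0 < n_nonzero <= d")


@dataclass(frozen=True)
class IndexVector:
    """Sparse ternary random vector: distinct positions with balanced signs."""

    d: int
    positions: tuple[int, ...]
    signs: tuple[int, ...]

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.d)
        v[list(self.positions)] = self.signs
        return v


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window extent: ``left + right`` surrounding terms."""

    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0 or self.left + self.right == 0:
            raise ValueError("window sides must be >= 0 and not both zero")

    @property
    def size(self) -> int:
        return self.left + self.right

    def __str__(self) -> str:  # "2+2"
        return f"{self.left}+{self.right}"


def _term_rng(term: str, seed: int) -> np.random.Generator:
    digest = hashlib.blake2b(f"{seed}\x00{term}".encode("utf-8"), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))


def make_index_vector(term: str, cfg: IndexVectorConfig) -> IndexVector:
    """Deterministic ternary index vector for ``(term, cfg.seed)``.

    Positions are drawn without replacement from a pseudo-random stream
    keyed by a stable hash, the first half getting +1 and the second -1,
    so the element sum is always zero.
    """
    rng = _term_rng(term, cfg.seed)
    positions = rng.choice(cfg.d, size=cfg.n_nonzero, replace=False)
    half = cfg.n_nonzero // 2
    signs = (1,) * half + (-1,) * half
    return IndexVector(d=cfg.d, positions=tuple(int(p) for p in positions), signs=signs)


def ri_weight(dist: int) -> float:
    """Distance weight for RI training: ``2**(1 - dist)`` for ``dist >= 1``."""
    if dist < 1:
        raise ValueError("distance to the target term must be >= 1")
    return 2.0 ** (1 - dist)


def rotate(v: np.ndarray, offset: int) -> np.ndarray:
    """Circular shift: the element at index ``i`` moves to ``(i + offset) % d``.

    For a matrix of row vectors each row is rotated independently.
    """
    return np.roll(v, offset, axis=-1)


@dataclass
class SemanticSpace:
    model: str  # "RI" | "RP"
    window: WindowSpec
    d: int
    vocab: list[str]
    matrix: np.ndarray  # |vocab| x d dense context vectors
    index_config: IndexVectorConfig
    corpus_name: str = ""
    stopwords_retained: bool = True
    term_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.term_index:
            self.term_index = {t: i for i, t in enumerate(self.vocab)}

    def __contains__(self, term: str) -> bool:
        return term in self.term_index

    def vector(self, term: str) -> np.ndarray:
        return self.matrix[self.term_index[term]]

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)


def _index_matrix(vocab: list[str], cfg: IndexVectorConfig) -> np.ndarray:
    iv = np.zeros((len(vocab), cfg.d))
    for i, term in enumerate(vocab):
        v = make_index_vector(term, cfg)
        iv[i, list(v.positions)] = v.signs
    return iv


def _offset_pairs(corpus: Corpus, term_index: dict[str, int], offset: int) -> sp.csr_matrix:
    """Sparse count matrix C where C[t, n] = # occurrences of neighbour n at
    signed ``offset`` from target t, truncated at segment boundaries."""
    n_terms = len(term_index)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for seg in corpus.segments:
        ids = np.fromiter((term_index[t] for t in seg.tokens), dtype=np.int64, count=len(seg))
        if len(ids) <= abs(offset):
            continue
        if offset > 0:
            rows.append(ids[:-offset])
            cols.append(ids[offset:])
        else:
            rows.append(ids[-offset:])
            cols.append(ids[:offset])
    if not rows:
        return sp.csr_matrix((n_terms, n_terms))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(len(r))
    return sp.coo_matrix((data, (r, c)), shape=(n_terms, n_terms)).tocsr()


def _train(corpus: Corpus, window: WindowSpec, cfg: IndexVectorConfig,
           model: str, weighted: bool, permute: bool) -> SemanticSpace:
    if not corpus.segments:
        raise ValueError("cannot train a space on an empty corpus")
    vocab = sorted({t for seg in corpus.segments for t in seg.tokens})
    if not vocab:
        raise ValueError("empty vocabulary")
    term_index = {t: i for i, t in enumerate(vocab)}
    iv = _index_matrix(vocab, cfg)
    ctx = np.zeros_like(iv)
    offsets = [-p for p in range(1, window.left + 1)] + list(range(1, window.right + 1))
    for offset in offsets:
        counts = _offset_pairs(corpus, term_index, offset)
        neighbours = rotate(iv, offset) if permute else iv
        w = ri_weight(abs(offset)) if weighted else 1.0
        # index-vector entries are +-1 and weights are powers of two, so this
        # accumulation is exact in binary floating point
        ctx += w * counts.dot(neighbours)
    return SemanticSpace(
        model=model,
        window=window,
        d=cfg.d,
        vocab=vocab,
        matrix=ctx,
        index_config=cfg,
        corpus_name=corpus.name,
        stopwords_retained=not corpus.stopwords_removed,
        term_index=term_index,
    )


def train_ri(corpus: Corpus, window: WindowSpec, cfg: IndexVectorConfig,
             weighted: bool = True) -> SemanticSpace:
    """Train a Random Indexing space (distance-weighted by default)."""
    return _train(corpus, window, cfg, model="RI", weighted=weighted, permute=False)


def train_rp(corpus: Corpus, window: WindowSpec, cfg: IndexVectorConfig,
             permute: bool = True) -> SemanticSpace:
    """Train a Random Permutation space (unweighted, order-encoding rotations).

    ``permute=False`` disables the rotations, which collapses RP onto
    unweighted RI — useful as a definitional cross-check.
    """
    return _train(corpus, window, cfg, model="RP", weighted=False, permute=permute)


def save_space(space: SemanticSpace, path: str | Path) -> None:
    """Persist a space losslessly (versioned .npz container)."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "model": space.model,
        "window": [space.window.left, space.window.right],
        "d": space.d,
        "corpus_name": space.corpus_name,
        "stopwords_retained": space.stopwords_retained,
        "index_config": {
            "d": space.index_config.d,
            "n_nonzero": space.index_config.n_nonzero,
            "seed": space.index_config.seed,
        },
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        vocab=np.array(space.vocab, dtype=object),
        matrix=space.matrix,
    )


def load_space(path: str | Path) -> SemanticSpace:
    try:
        with np.load(path, allow_pickle=True) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            vocab = [str(t) for t in data["vocab"]]
            matrix = np.asarray(data["matrix"])
    except (OSError, KeyError, ValueError, json.JSONDecodeError,
            zipfile.BadZipFile) as exc:
        raise SpaceFormatError(f"cannot read space file {path}: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise SpaceFormatError(
            f"unsupported space format version {meta.get('format_version')!r}")
    if matrix.shape != (len(vocab), meta["d"]):
        raise SpaceFormatError("space payload inconsistent with header")
    icfg = meta["index_config"]
    return SemanticSpace(
        model=meta["model"],
        window=WindowSpec(*meta["window"]),
        d=meta["d"],
        vocab=vocab,
        matrix=matrix,
        index_config=IndexVectorConfig(d=icfg["d"], n_nonzero=icfg["n_nonzero"], seed=icfg["seed"]),
        corpus_name=meta["corpus_name"],
        stopwords_retained=meta["stopwords_retained"],
    )


def export_text_embeddings(space: SemanticSpace, path: str | Path) -> None:
    """Export as the common "word v1 v2 ..." text embedding format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{space.vocab_size} {space.d}\n")
        for term in space.vocab:
            values = " ".join(f"{x:.6g}" for x in space.vector(term))
            fh.write(f"{term} {values}\n")
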