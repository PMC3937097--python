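"""Independent reference implementations used only as test oracles.

These deliberately re-derive expected behaviour with naive code paths
(double loops, regex, binomial enumeration) that share nothing with the
library's implementations.
"""

from __future__ import annotations

import math
import re

import numpy as np

from semspaces.corpus_io import Corpus, Segment
from semspaces.spaces import IndexVectorConfig, WindowSpec, make_index_vector


def brute_force_context_vectors(
    corpus: Corpus,
    window: WindowSpec,
    cfg: IndexVectorConfig,
    model: str = "RI",
    weighted: bool = True,
    permute: bool = True,
) -> dict[str, np.ndarray]:
    """Naive per-position accumulation of (weighted / rotated) index vectors."""
    vocab = sorted({t for s in corpus.segments for t in s.tokens})
    iv = {t: make_index_vector(t, cfg).to_dense() for t in vocab}
    ctx = {t: np.zeros(cfg.d) for t in vocab}
    for seg in corpus.segments:
        toks = seg.tokens
        for i, target in enumerate(toks):
            lo = max(0, i - window.left)
            hi = min(len(toks), i + window.right + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                off = j - i
                v = iv[toks[j]]
                if model == "RP" and permute:
                    v = np.roll(v, off)
                if model == "RI" and weighted:
                    v = (2.0 ** (1 - abs(off))) * v
                ctx[target] = ctx[target] + v
    return ctx


def regex_subsequence_same_initial(short: str, long: str) -> bool:
    """Regex-based ordered-subsequence check with the same-initial rule."""
    s = [c for c in short.lower() if c.isalpha()]
    l = "".join(c for c in long.lower() if c.isalpha())
    if not s or not l or s[0] != l[0]:
        return False
    pattern = ".*?".join(re.escape(c) for c in s)
    return re.search(pattern, l, flags=re.DOTALL) is not None


def sign_test_bruteforce(k: int, n: int) -> float:
    """Two-sided exact sign test by direct enumeration of Binomial(n, 1/2)."""
    if n == 0:
        return 1.0
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2.0 * min(lower, upper))


def random_toy_corpus(rng: np.random.Generator, max_tokens: int = 500) -> Corpus:
    """Random small corpus: a handful of segments over a tiny vocabulary."""
    vocab = [f"w{i}" for i in range(int(rng.integers(3, 15)))]
    segments = []
    budget = int(rng.integers(20, max_tokens + 1))
    i = 0
    while budget > 0:
        length = int(rng.integers(1, 13))
        length = min(length, budget)
        toks = tuple(vocab[j] for j in rng.integers(0, len(vocab), size=length))
        segments.append(Segment(id=f"s{i}", tokens=toks))
        budget -= length
        i += 1
    return Corpus(name="toy", segments=segments)
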