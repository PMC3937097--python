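# Methods

## Models

Both models build a *semantic space*: a map from vocabulary terms to dense
d-dimensional context vectors whose geometric proximity (cosine)
approximates distributional similarity.  Every term, in its role as a
context, is first assigned a static **index vector**: d = 1000 entries of
which eight are nonzero (four +1, four −1) at positions drawn without
replacement from a pseudo-random stream keyed by a stable 64-bit hash of
`(seed, term)`.  Index vectors of distinct terms are therefore
near-orthogonal (the expected magnitude of the cosine between two random
index vectors at d = 1000, n = 8 is about 0.03), deterministic per seed,
and shared between all spaces trained with the same seed.

Training slides a window of `left + right` surrounding terms over every
segment; segments are hard context boundaries and windows never cross
them.

* **Random Indexing (RI)** adds each in-window neighbour's index vector to
  the target's context vector with weight `2^(1 − dist)`, where `dist ≥ 1`
  is the token distance on the processed stream (the immediate neighbour
  counts 1).  Passing `weighted=False` uses weight 1 everywhere; the
  default applies the same geometric weighting to every window size,
  including the wide 10+10 spaces.
* **Random Permutation (RP)** adds each neighbour's index vector
  unweighted, after circularly rotating it by the neighbour's signed
  offset: a neighbour `p` positions to the left is rotated `p` steps
  toward lower indices, to the right toward higher indices.  Rotation is
  a bijection on coordinates, so norms are preserved; with all rotations
  forced to zero RP degenerates to unweighted RI exactly, which the test
  suite uses as a definitional cross-check.

Because index-vector entries are ±1 and the weights are powers of two,
training accumulates dyadic rationals and is exact in binary floating
point — trained spaces equal a brute-force double-loop accumulation
bit for bit, which the oracle tests assert on random toy corpora.

RI spaces are intended for stop-word-filtered corpora (high-frequency
function words carry little meaning but dominate co-occurrence counts);
RP spaces can also be trained with stop words retained, since function
words carry syntactic-order information that rotation encodes.  Distances
and offsets are always counted on the stream being trained on, i.e. after
stop-word removal when it applies.

## Combination strategies

All strategies operate on per-space query outputs, not on vectors.

* **Pool-filtered re-ranking** (`combine_subset`): candidate membership
  comes from one space's top-30 pool, ordering from the other space's
  cosines; terms missing from the ranking space's vocabulary are dropped,
  and if fewer than ten candidates survive, the shorter list is returned.
* **Score fusion** (`combine_scores`): SUM adds each candidate's cosine
  across the spaces (a term absent from a space contributes zero); AVG
  divides the sum by the number of spaces containing the term, which is
  meant to avoid penalising vocabulary present in only one corpus.  Both
  are computed over the full union vocabulary rather than a truncated
  retrieval horizon, so results are exact; a horizon is configurable for
  speed.
* **Rank normalisation**: cosines are replaced by the 0-based position in
  the candidate list, so combined lists sort ascending (zero best).  A
  term absent from a list receives the penalty rank `horizon` (the union
  vocabulary size by default) — under an ascending sort, absence must
  never be an advantage.  This penalty choice is the package's own; it is
  consistent with rank normalisation performing worse than raw-score SUM,
  which is also what the fusion literature this design follows reports.
* **Two-step fusion** (`combine_two_step`): each same-corpus pair is
  fused first (SUM or AVG within the pair), both fused lists are
  rank-normalised, and the normalised ranks are fused across corpora
  (SUM, or AVG dividing by the number of the four source spaces
  containing the term).

Ties are always broken lexicographically by term, making every strategy
deterministic and invariant to candidate insertion order.

## Post-filtering

Abbreviation tasks use structural rules on letters only (punctuation and
digits are stripped upstream): a candidate abbreviation must have at most
four letters, a candidate expansion more than four, and the short form
must be an ordered subsequence of the long form sharing its initial
letter.  Synonym candidates are filtered by cosine/rank cut-off profiles:
`clinical` accepts cosine ≥ 0.60 at any rank or ≥ 0.40 below rank 9;
`medical` accepts cosine ≥ 0.50; `combined` applies to summed cosines of
a four-space ensemble (range up to 4) and accepts ≥ 1.9 anywhere, ≥ 1.8
below rank 6, or ≥ 1.75 below rank 3.  Ranks are 0-based throughout, so
"below rank 9" admits ranks 0–8.

Two application modes: the fixed mode scans candidates in rank order
until ten are accepted or one hundred classified, then backfills the
remaining slots with the highest-ranked rejected candidates (so output
length is always min(10, available)); the dynamic cut-off returns only
the accepted candidates, between one and ten, falling back to the single
top-ranked candidate when nothing is accepted.  The 100-candidate scan is
used in both modes.

## Evaluation

Reference standards are TSV tuples; multiword terms are removed because
the spaces model unigrams.  Synonym tuples generate queries in both
directions (every member queries every other member); abbreviation tuples
are directional.  Tuples are filtered by a minimum corpus frequency
(default 50 in every corpus involved) because distributional vectors of
rare terms are statistically unreliable, and split at the tuple level
into development and evaluation halves.

Recall@10 micro-averages over (query, gold) pairs: the share of expected
terms found among ten suggestions.  Out-of-vocabulary queries yield empty
outputs and count as misses.  Weighted precision scores a true positive
at 0-based rank i within the first j suggestions as j − i, normalised by
the best attainable score; j is 10 in fixed mode and the returned length
under a dynamic cut-off.  Reported precision is the mean weighted
precision over queries.  Paired systems are compared with the two-sided
exact binomial sign test on discordant per-query successes (any-hit
counts as success for multi-gold queries; configurable), with p = 1 when
no pairs are discordant.

## Synthetic data generator

The generator emulates the statistical structure that sliding-window
distributional methods exploit, in two genre-distinct corpora:

* A background vocabulary (default 2000 words over the Swedish alphabet)
  with global Zipf weights (exponent 1.1), partitioned round-robin across
  20 topics; each segment (10 tokens) belongs to one topic and draws 60%
  of its tokens from the topic's own words, 40% from the global
  distribution.  The most frequent background words double as the
  bundle's stop-word list.
* Each planted lexeme has two surface forms — a synonym pair, or an
  abbreviation constructed as an ordered letter-subsequence of its
  expansion sharing the initial letter — a home topic, six shared
  *signature* collocates and three *private* collocates per form.  Every
  placed occurrence of a form overwrites two of its window neighbours
  with draws that are 25% topic noise, else 50/50 shared vs private.
  The two forms therefore share roughly half of their salient collocates:
  enough second-order overlap to be recoverable, enough divergence that
  recovery is not trivial, mimicking near-synonyms whose usage contexts
  overlap only partially.
* Genre skew: each corpus prefers one form of every lexeme (80% of the
  lexeme's occurrence mass); occurrence counts are planned
  deterministically so that even the minority form meets the configured
  frequency floor (default 60) in both corpora — the floor holds by
  construction rather than by rejection sampling.  Per-lexeme frequencies
  are spread log-uniformly up to 4× the floor (16× in the low-floor sweep
  configuration) so that planted pairs span a realistic frequency range.
* Placement is two-phase — all form tokens first, collocate overwrites
  second in a globally shuffled order — so no form systematically
  clobbers another form's collocates and the two corpora are
  statistically exchangeable.

What the generator does **not** emulate: morphology and spelling
variation, ambiguous abbreviations with several expansions, segments of
varying length, topic drift, and the heavy-tailed document structure of
real clinical text.  Passing the end-to-end tests therefore shows that
the pipeline recovers paradigmatic structure of the planted kind at
realistic sizes; it does not certify recall levels on real corpora,
where reported performance is substantially lower.

## Default problem sizes

The end-to-end study (also recomputed by `scripts/acceptance.py`) uses
two corpora of 30 000 ten-token segments (~300k tokens each, comparable
per-term statistics to corpora 100× larger with proportionally larger
vocabularies), 20 synonym and 10 abbreviation pairs at frequency floor
60, RI and RP windows of 2+2 at d = 1000, and five seeds for the
ensemble-vs-single-space comparison.  At these sizes a full study runs in
tens of seconds on one CPU; the sizes were chosen so the planted-pair
statistics (60+ occurrences per form) sit safely above the reliability
floor the evaluation itself imposes.

## Numerical choices and degenerate inputs

* Cosine of any vector with an all-zero vector is defined as 0 (terms
  with empty contexts are maximally dissimilar, never spuriously close).
* Equal scores are ordered lexicographically by term everywhere.
* Out-of-vocabulary queries raise a typed error at the retrieval layer;
  the evaluation layer maps them to empty outputs and counts misses.
* Dev/eval splits shuffle tuples with a dedicated `random.Random(seed)`,
  independent of the numpy streams used for generation and training.
* Space files are versioned `.npz` containers; truncated or
  version-mismatched files raise a format error rather than loading
  partially.

## Known limitations

Vector-level fusion of spaces, learned combination weights, multiword
term spaces and direction-only permutation vectors are out of scope.
Filter thresholds are fixed profiles, not learned from development data.
The CLI's grid command caches trained spaces by corpus digest, model,
window, stop-word variant and seed; cache entries are not evicted.
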