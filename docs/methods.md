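# Methods

This note records the model, the defaults and the open design choices of
traitspace, in enough detail that a maintainer can predict what the code
does without reading it.

## Semantic space

Co-occurrence is counted symmetrically in a window of `window = 3` tokens
to each side of the target, never crossing document boundaries, with every
pair at distance 1..window contributing 1 regardless of distance (counts,
not decayed weights). The diagonal is zeroed: a word is not its own
context, even when two tokens of the same type fall inside one window.
Words with corpus frequency below `min_count = 2` are dropped after
counting; the floor keeps degenerate hapax vectors out of small test
corpora while remaining configurable to 0.

Weighting is PPMI, `max(0, log2(c·T / (r_i·r_j)))`, computed on the kept
vocabulary. Raw counts are available as a weighting option and are what
make the (6, 3)-coordinate toy example exact. Optional dimensionality
reduction is a full LAPACK SVD truncated to `svd_dim`, with vectors
`U·S` — deterministic without any seed, affordable because the package
targets desk-scale vocabularies (10²–10⁴ words). Cosine similarity
returns 0 for zero-norm vectors rather than raising, so batch scoring is
total; out-of-vocabulary queries raise an error carrying the word.
Neighbor lists break similarity ties alphabetically.

PPMI is known to overweight rare co-occurrences: with thin counts,
one-off coincidences between rare words get large positive weights and
dilute cosines. The package does not smooth or shift PPMI; instead the
synthetic backgrounds are sized so that association statistics are stable
(see below). Real applications should use the largest background corpus
available — the method's premise is a reference corpus orders of
magnitude larger than the documents being scored.

## Representation and tagging

A document is represented by the `k = 10` most frequent nouns, verbs and
adjectives of its lowercased token stream; ties at the frequency cut are
broken alphabetically so representations are deterministic. Tokens are
maximal runs of letters with internal apostrophes; digits and punctuation
separate. No lemmatization is applied — scores are driven by surface
forms. A word selected under two POS categories is counted independently
per category and contributes once per category to the centroid. Tagging
is a pluggable contract (same-length, same-order token list with only
`pos` filled); the shipped tagger is a deterministic dictionary lookup
with OTHER as fallback, which is exact on synthetic corpora and lets any
external statistical tagger be wrapped in for real text.

## Trait scoring

The score of a document on a trait is, by default, the cosine between the
unweighted centroid of its in-vocabulary representation words and the
centroid of the trait's in-vocabulary seed words (`centroid` mode). The
alternative `mean_pairwise` mode averages cosines over all
representation-word x seed-word pairs; both are standard aggregations,
they coincide on single-word sides, and results should state the mode
used. A frequency-weighted centroid sits behind a flag. OOV words are
dropped and counted in an OOV report; a cell with no usable word on
either side is undefined (NaN), never silently zero, because silent zeros
would bias group comparisons. Custom lexica load from a two-column
`trait,word` CSV.

## Group comparison

The U statistic is that of the positive group (ties count 1/2), so
U near n1·n2 means the positive group scores higher. The p-value is
Monte-Carlo: labels are permuted without replacement (the exact null of
exchangeability), and p = (b + 1)/(m + 1) over m = 10,000 permutations by
default — add-one, so never exactly 0, and within binomial error of the
exhaustive permutation p (verified against full enumeration for small
groups). Two-sided p doubles the smaller tail, capped at 1. Undefined
cells are excluded pairwise per trait and the effective group sizes are
reported. No multiple-testing correction is applied across the 13 traits
by default; Benjamini–Hochberg is available behind a flag.

## Ranking and screening

Three models produce positive-class probabilities from the 13 scores:

* **BLR** — scikit-learn logistic regression (L2, lbfgs), optional
  balanced class weights (off by default).
* **TRE** — a CART decision tree whose cost-complexity pruning strength
  is selected by stratified cross-validated AUC over the tree's own alpha
  path. This is a deliberate, documented substitute for chi-square
  multiway CHAID trees, for which no maintained open implementation is
  assumed; both are pruned classification trees yielding leaf-frequency
  probabilities.
* **KNN** — k = 5 neighbors on standardized features; probability =
  neighbor class fraction.

Cross-validation folds are capped at the minority-class count (stratified
folds are otherwise undefined); with 6 positives, nominal 10-fold becomes
6-fold. Undefined score cells are imputed with the per-trait
comparison-group median before fitting — deterministic and rank-safe.

Ranking is by descending probability with ties broken by ascending
doc_id, so outputs are reproducible run to run. *Steps-to-identify-all*
is the maximum rank among positives; the random-reading baseline is the
order-statistics expectation m(N+1)/(m+1). The MEAN ensemble averages the
per-model ranks and re-ranks ascending.

In-sample fitting (fit on all labeled documents, rank the same documents)
is the default screening protocol. It is the realistic triage setting,
but its probabilities are optimistically biased — KNN in particular sees
each document as its own nearest neighbor. Performance statements about
null behavior therefore use `mode="cv"` (out-of-fold probabilities),
under which screening cost on exchangeable data sits at the random
baseline; in-sample mode on exchangeable data can sit well below it
purely through overfitting, which is leakage, not signal.

## Synthetic data

The generator emulates the two statistical features the analysis relies
on, and nothing else:

1. **Coherent trait neighborhoods in the background corpus.** Tokens are
   drawn from a unigram mixture (a small block of very frequent
   OTHER-tagged function-word stand-ins, 35% of mass; Zipf-flavored
   content fillers; and 25% of mass on the lexicon's 36 distinct seed
   words plus planted context words). After a seed word is emitted, each
   of the following `neighborhood_window = 3` positions is redrawn with
   probability `neighborhood_strength = 0.9` from that seed's context
   neighborhood. Seeds of the same planted trait share one neighborhood,
   so their PPMI vectors become similar — first-order dependence only,
   which is exactly what windowed counting measures. Background documents
   default to 2,000 tokens; the background corpus stands in for a large
   reference corpus, and at roughly 10⁵–10⁶ tokens planted-synonym
   cosines stabilize above 0.8 while random-pair cosines stay far lower.
   Much smaller backgrounds leave PPMI rare-event noise dominant and the
   planted structure only weakly recoverable — which is faithful to how
   the real method degrades on small reference corpora.
2. **Lexical enrichment of positive documents.** In the labeled
   collection (documents of 120–150 tokens), each content-word draw in a
   positive document is replaced with probability θ by a word from the
   target trait's pool (its seeds plus their context words). θ = 0 is the
   exchangeable null; θ = 1 confines all content words to the pool. Which
   documents are positive is itself randomized per seed, so at θ = 0 no
   deterministic tie-break can leak class information.

All sampling is driven by numpy `default_rng` seeded from the config;
identical configs give byte-identical corpora. Vocabularies are abstract
letter-only tokens (`filab`, `ctxrevengefula`, ...) plus the seed words;
no real violent text is embedded. `vocab_size` counts the filler block —
seed and context words are always added on top so that all 13 traits are
scoreable even in the 50-filler tiny fixture. What the generator does
*not* emulate: syntax, topical discourse structure, document-length
heterogeneity, demographic metadata, and polysemy. Passing tests
therefore demonstrate that the pipeline recovers planted distributional
structure and is calibrated under exchangeability; they do not certify
performance on natural language.

Fixture sizes: `tiny` (50 fillers, 30 background docs, 6 + 24 labeled)
for unit tests; `small` (500 fillers, 300 x 4,000-token docs) for
integration; `paper_shaped` (6 positives vs 2,000 comparisons) for
screening-metric tests — a reduced-scale version of a realistic
6-vs-several-thousand screening study, sized so the full suite runs in a
few minutes on one CPU.

## Numerical and procedural choices

* Permutation U values are sums of midranks (halves), exact in floating
  point; comparisons need no tolerance.
* Monte-Carlo subsets are drawn by argpartition of iid uniforms, chunked
  to bound memory at large N.
* Per-trait and per-stage seeds are derived from the master seed
  (affine map, SHA-256 for pipeline stages), all below 2^31.
* Scores CSV renders floats with 6 significant digits and fixed row
  order, so re-writing a table is byte-identical.
* Empty documents, empty groups, single-class labels, fully-OOV traits
  and mismatched rank sets all raise early with the offending identifier.

## Known limitations

* The 13 seed lists are short; on small spaces a trait can be dominated
  by one or two in-vocabulary seeds.
* Centroid cosines of PPMI vectors are nonnegative in practice, so the
  theoretical [-1, 1] range is effectively [0, 1] without SVD.
* The mean-of-ranks ensemble weights all models equally regardless of
  their individual quality.
* In-sample screening numbers are optimistic by construction; use cv
  mode for honest performance estimates.
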