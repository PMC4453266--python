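# traitspace

Distributional-semantic trait profiling and ranked screening of text
corpora, for researchers in computational psychiatry and forensic text
analysis who need to (a) quantify how strongly a psychological dimension is
expressed in a document and (b) prioritize a large collection of documents
so that the few concerning ones surface near the top of a reading list.

## The method

**Semantic space.** Word meaning is represented by windowed co-occurrence
counts over a background corpus: for every token, the words up to `w = 3`
positions to each side (never crossing document boundaries) are its
contexts. Counts c(i, j) are reweighted by positive pointwise mutual
information,

    PPMI(i, j) = max(0, log2( c(i,j) · T / (r(i) · r(j)) )),

with T the total count and r(·) row sums, optionally compressed by
truncated SVD. Similarity between words is the cosine of their vectors: a
word that appears with *anxious* six times and with *angry* three times
literally has raw coordinates (6, 3) on those two context dimensions.

**Document representation.** Each document is reduced to its 10 most
frequent nouns, 10 most frequent verbs and 10 most frequent adjectives
(up to 30 words), using any part-of-speech tagger that honors a simple
contract; a deterministic dictionary tagger ships with the package.

**Trait scores.** Thirteen psychological dimensions — four
personality-disorder dimensions (depressivity DEP; paranoid PPD;
narcissistic NPD; schizoid SCHYZO) and nine facets of vengeful behavior
(Hopeless, Lonely, Helpless, Pain, Revengeful, Chaotic, Unsafe, Abandoned,
Humiliated) — are each defined by a short seed-word list, e.g.
NPD = {arrogant, manipulative, egocentric, insensitive}. A document's
score on a dimension is the cosine between the centroid of its
representation words and the centroid of the seed words, so every document
gets 13 scores in [-1, 1].

**Group comparison.** Positive vs comparison score distributions are
compared per trait with the Mann–Whitney U statistic; because the positive
group may contain only a handful of documents, p-values come from
Monte-Carlo label permutation (default 10,000 resamples, add-one
estimator, never exactly zero).

**Ranked screening.** The 13 scores feed three classifiers — binary
logistic regression (BLR), a cross-validation-pruned decision tree (TRE),
and k-nearest neighbors (KNN) — whose predicted positive-class
probabilities rank the documents most-suspicious-first. The screening
metric is *steps-to-identify-all*: the number of top-ranked documents an
expert must read to encounter every positive one (against the random
baseline m(N+1)/(m+1) for m positives among N documents). A mean-of-ranks
ensemble (MEAN) averages the per-model ranks and re-ranks.

A synthetic-corpus generator with planted co-occurrence neighborhoods and
a tunable enrichment dial θ provides ground truth for every stage, so the
whole pipeline is testable without any external data.

## Worked example

Generate a small synthetic study — 6 positive documents enriched (θ = 0.4)
toward the *Revengeful* semantic neighborhood vs 24 exchangeable
comparison documents — and run the full pipeline:

```
traitspace simulate --size tiny --theta 0.4 --seed 13 --out demo
cat > demo/run.yaml <<EOF
background_dir: demo/background
labeled_dir: demo/labeled
labels_csv: demo/labels.csv
pos_dictionary_json: demo/pos_dictionary.json
out_dir: demo/run
n_permutations: 10000
seed: 13
EOF
traitspace run --config demo/run.yaml
cat demo/run/summary.txt
```

```
traitspace run (seed 13)
documents: 30 (6 positive), vocabulary: 95

group comparison (Mann-Whitney U, Monte-Carlo p):
  DEP          U=5          p_mc=0.0004 (n1=6, n2=24)
  ...
  Revengeful   U=144        p_mc=0.0002 (n1=6, n2=24)
  ...

screening (steps to identify all positives):
  BLR   steps=6      fraction=20.00% (~20%)
  TRE   steps=6      fraction=20.00% (~20%)
  KNN   steps=6      fraction=20.00% (~20%)
  MEAN  steps=6      fraction=20.00% (~20%)
  random-ranking baseline: 26.6 steps
```

Reading the output: on the planted trait the positive group scores as high
as possible (U = 144 = n1·n2, every positive above every comparison,
p ≈ 2·10⁻⁴ at the permutation resolution). Off-target traits show the
*opposite* direction (small U): documents whose content words are tilted
toward one semantic neighborhood spend correspondingly fewer words near
the other trait vocabularies, a composition effect to keep in mind when
interpreting multi-trait profiles. All four rankers find the six positives
in the first six reading steps, against 26.6 expected under random
reading.

The scored table (`scores.csv`), per-trait tests (`mwu.csv`), per-document
ranks (`ranking.csv`) and a machine-readable manifest are all written to
the run directory; rerunning the same config reproduces them byte for
byte.

## What this package does not do

Scores are distributional similarities, not diagnoses. The package makes
no claim that any score or rank identifies a dangerous individual, and it
deliberately contains no alerting, crawling or deployment machinery.
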