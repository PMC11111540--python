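# Methods

## The problem

How well can the perceived riskiness of a concept ("vaccination", "nuclear
energy", "war") be predicted from the semantics of its name?  The classic
psychometric paradigm predicts mean risk ratings from a handful of
survey-derived item means (dread, controllability, catastrophic potential,
...).  Word embeddings — trained on text corpora or on free-association
data — offer an alternative: a high-dimensional vector per word whose
dimensions implicitly encode affective and semantic properties.  This
package implements the full comparison pipeline: embedding training,
ensemble construction, cross-validated prediction, residual
interpretability, vocabulary curation, and corpus application.

## Free-association embedding

Free-association data arrive as counts n(c, r): how often cue word c
elicited response word r.  Training is a three-step procedure:

1. **Count matrix M.**  Rows are cues, columns are responses whose total
   count over the whole table is *strictly greater than* a frequency
   threshold (default 5).  The threshold is read as a per-response-token
   total, not per (cue, response) pair.
2. **PPMI.**  M' = max(0, log[(n_cr/N) / ((n_c·/N)(n_·r/N))]) with N the
   grand total.  Natural logarithm; the base is arbitrary (it rescales all
   dimensions uniformly and is absorbed by the downstream regression) but
   must be fixed for reproducibility.  Cells with zero joint count are
   exactly zero and the log is never evaluated there.  No
   context-distribution smoothing and no shifted PPMI.
3. **Truncated SVD.**  M' ≈ UΣV*; the cue embedding is the rows of UΣ and
   V* is discarded.  Sign indeterminacy is resolved by flipping each left
   singular vector so its largest-magnitude entry is positive, which makes
   output deterministic across LAPACK backends.  Exact singular-value ties
   keep the backend's ordering (a residual nondeterminism risk on contrived
   inputs).

## Ensembles and groupwise scaling

Ensembles concatenate feature blocks column-wise (two 300-dim embeddings →
600 predictors; adding the nine psychometric items → 609).  Because the
elastic net is run *without* predictor standardization (see below), blocks
with systematically larger dimension scales would absorb regularization
unevenly.  Each non-reference block is therefore multiplied by a single
scalar so that its mean column standard deviation (sample, n−1 denominator)
equals that of the reference block — conventionally the psychometric block,
which itself is never rescaled.  A single scalar per block preserves the
within-block variance profile and correlation structure exactly; the
operation is idempotent.  Scaling is computed once on the full design
matrix before cross-validation (only scale information can leak, and the
reference scale is not label-dependent); a fold-wise variant would be a
one-line change in the caller.

Bigram risk terms default to the mean of their constituent word vectors
(`mean_of_words`); `strict` reproduces pure vocabulary-intersection
behavior; `phrase_then_mean` prefers an underscore-joined phrase token.

## Prediction protocol

Elastic net over an 88-point grid: mixing ratio l1_ratio on 11 even steps
in [0, 1] and penalty magnitude α on 8 log-spaced steps in [1e-5, 100]
(10^linspace(−5, 2, 8)).  Model evaluation is nested 10-fold CV repeated 10
times: each repeat reshuffles rows with a repeat-specific seed derived
deterministically from the master seed, hyperparameters are chosen per
outer training set by inner 10-fold CV (scikit-learn `ElasticNetCV`), and
R² is computed on the held-out outer fold; all 100 fold scores are kept and
the headline number is their arithmetic mean.  The inner fold count is a
config field because only the grid and outer protocol are fixed by
convention.

Predictors are not standardized by default: standardization redistributes
variance evenly across dimensions, which specifically hurts SVD-derived
embeddings whose leading dimensions deliberately carry more variance.  A
`standardize` flag exists for sensitivity analyses (the scaler is fit per
outer training fold).

**Adjusted confidence intervals.**  When several models are scored on the
same fold partitioning, most fold-score variance is a shared fold effect.
The within-design interval removes it: center each fold's scores across
models, inflate the remaining spread by √(m/(m−1)) for m models (the
small-sample correction for the centering), and take a normal-theory 95%
interval per model.  Column means are unchanged by the centering, so
intervals stay centered on the raw mean.  With a single model the
adjustment is undefined and the unadjusted interval is returned with a
warning.

**Residuals.**  Interpretability analyses use out-of-fold residuals by
default: every term gets exactly one held-out prediction per repeat, and
the residual is observed minus the mean of those predictions.  In-sample
residuals are optimistically shrunken toward zero exactly where the model
overfits; out-of-fold residuals are not.  (`fit_final` provides the
non-nested fit used to generalize word scores beyond the rated
vocabulary.)

## Residual–norm interpretability

Sixteen word norms in three groups — affect (valence, dominance, arousal,
fear, anger, sadness, disgust, joy, trust, surprise, anticipation),
frequency (age of acquisition, familiarity, frequency), concreteness
(concreteness, imageability) — are correlated (absolute Pearson r, Fisher-z
95% CIs) with (a) the risk ratings themselves (baseline), and (b) model
residuals.  Group-level drops in mean |r| between stages quantify how much
of each group's signal a model absorbed.  The joint "shared variance" of
the norms with the ratings uses the same cross-validated elastic-net
protocol as the risk models (an in-sample multiple-R² variant is
available).  Norms constant across the shared terms are flagged and
excluded from group means.  Bigram risks receive norm values by the same
word-averaging policy as embedding lookup.

## Vocabulary curation

A candidate word joins the preliminary risk list iff it has ≥ 2 human
votes, or exactly 1 human vote and ≥ 2 of 3 machine votes (the rule is
monotone in both vote counts).  A machine vote scores each candidate by the
max (default; mean available) cosine similarity to a pooled seed list of
previously studied risks, and thresholds at the k-th largest score with
k = round(rate × n), so the machine positive rate matches the human
positive rate up to ties.  `max` is the default because a word close to
*any* known risk is risk-like.  Final filters: drop frequencies below a
required, user-supplied threshold (no universal constant exists); keep one
word per lemma (highest frequency, lexicographic tie-break; the lemma map
is an input, not a bundled lemmatizer); drop sensitive words.  Output is
sorted, hence order-independent.

## Corpus scoring

Tokenization is lowercase + punctuation-stripped + whitespace-split.
Coverage counts *distinct* in-vocabulary tokens per headline (a repeated
risk word counts once) and reports the proportion of headlines with ≥ 1, 2,
3 covered words.  Riskiness per headline is the mean predicted word score
over covered words, min-max rescaled across headlines onto [−100, 100]
(all-equal means map to 0; the scaled score is invariant to positive affine
transforms of the word scores).  The document-term matrix uses tf = raw
count and idf = log(N/df) with exact zeros (deliberately not the smoothed
sklearn variant), and the 2-D projection is a pluggable reducer interface —
any callable from the sparse matrix to (n, 2) coordinates, e.g. a UMAP
instance's `fit_transform`.

## Synthetic worlds

The generator plants a latent semantic space that every stage can recover:

* Latent vectors are standard-normal draws normalized to the unit sphere.
  Directions, not magnitudes, are the semantic content: free associations
  read cosine similarity, which is purely directional, so ratings built on
  the same directional information keep the planted ceiling attainable
  through the association channel.
* Risk means are latent·w + Gaussian noise with the noise calibrated in
  closed form to a target population R² (default 0.80): noise variance =
  signal variance × (1−R²)/R², with signal variance |w|²/k on the sphere.
  The affine map onto [−100, 100] places ±2.81 population SDs at the scale
  ends, so clipping touches ≈ 0.5% of values and the linear ceiling stays
  valid.  Psychometric items are nine independent noisy linear maps onto
  [1, 7], with noise set by the same formula from a reliability target
  (default 0.97); with the default k_latent = 9 their span generically
  contains the risk direction, mirroring how well-designed survey items
  blanket the construct.
* Affect norms load on the risk direction with alignment 0.8 and noise SD
  0.5, planting a baseline |r| ≈ 0.4; concreteness and frequency norms are
  orthogonal controls.
* Associations: per cue, 300 responses (the order of response tokens per
  cue in large citizen-science association studies) drawn from
  softmax(cosine/T) over all other words, temperature 0.15 — concentrated
  enough that top responses are informative, diffuse enough that the
  response vocabulary is covered.
* Headlines: half the documents are "risky topics" sampling words ∝
  softmax of standardized true riskiness; the rest are uniform.

What the generator does *not* emulate: participant-level response chaining
(R1→R2 dependence), word-frequency (Zipfian) structure, polysemy, and any
nonlinear rating behavior.  Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under its own modeling assumptions,
not that real ratings are this predictable.

A note on embedding rank: PPMI's clipping is nonlinear, so a k-dimensional
latent space does not produce an exactly rank-k PPMI matrix; information
leaks into higher singular components, and which latent directions a rank-k
embedding captures best varies by draw.  Truncating at k = k_latent
recovers the ceiling to within a few points of R²; ranks comfortably above
k_latent (the demonstration script uses 50) close most of that gap, which
is why practical embeddings use dimensionalities far above the effective
semantic rank.

## Problem sizes and runtimes

The test suite and the demonstration script run at desk scale by design:
worlds of 1000 words, 800 association cues, 300 responses per cue, corpora
of a few thousand headlines, and full 10×10 nested CV where the protocol is
itself under test (a few minutes end to end).  Statistical checks at these
sizes have comfortable margins (e.g. null R² bounds at n = 300–1000).

## Known limitations

* `l1_ratio = 0` (pure ridge) is solved by coordinate descent in
  scikit-learn, which is slow and occasionally non-convergent; convergence
  warnings are suppressed inside the fit wrapper and the fixed α grid keeps
  the path well-behaved.
* The adjusted-CI small-sample correction is the standard within-design
  one; other corrections in the literature differ in detail.
* Coverage and scoring match tokens exactly after normalization — no
  lemmatization or spelling normalization of headline text.
* The exact 1004-term reference vocabulary cannot be reproduced without
  the original human votes; the curation module reproduces the *algorithm*
  (votes → combination rule → filters), not the artifact.
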