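# Methods

`phenocnn` implements a patient-phenotyping stack for free-text clinical
notes: convolutional text classifiers over word- and sentence-level input,
cost-sensitive training, cross-validated evaluation, and a family of
token-statistics analyses (Zipf rank-frequency fitting, frequency filtering,
greedy category prioritization).  Real discharge-summary corpora of this
kind (MIMIC-III and its expert phenotype annotations) are access-controlled,
so the package ships a synthetic note generator that reproduces the
statistical structure these methods rely on and is used for all bundled
benchmarks.

## Models

**w-CNN (word-level input).**  A note is a padded sequence of 1-based token
indices.  An embedding layer maps it to an L x d matrix (d = 50 by
default).  For each configured filter length `l` (default 1-4), a group of
100 filters computes, at every position with stride 1 and no temporal
padding,

    c_i = ReLU(w . x_{i:i+l-1} + b),

where `x_{i:i+l-1}` is the flattened window of `l` consecutive embedding
rows.  Max-over-time pooling reduces each feature map to its maximum; the
pooled values concatenate into the feature vector V.  A single sigmoid unit
`y = sigma(w_out . V + b_out)` produces P(positive); the complementary
probability is 1 - y.  (A two-unit softmax output is an equivalent
parameterization for a binary task; the single-logit form is used because it
is unambiguous.)

**ws-CNN (combined input).**  A second branch consumes the sentence view of
the same note (S_max sentences x W_max tokens, padded in both dimensions).
Each sentence's word vectors are pooled into one d-dimensional *sentence
embedding* — sum or average over the sentence's true, pre-padding length, so
padding tokens never contribute; all-padding sentences pool to zero.  The
same conv + max-over-time machinery (filter lengths {1, 5, 7, 9}, 50 maps
each) runs over the sentence axis, and both branches' feature vectors
concatenate at the penultimate layer.  Pooling mode is a per-phenotype
hyperparameter (`sum` or `average`).

**Masking scope.**  Padding is masked only in sentence pooling.  Word-level
padding positions do enter the convolution; because the padding embedding
row is zero, an all-padding window contributes exactly `ReLU(bias)` to every
map.  The trainer exploits this: within a mini-batch, the common all-padding
suffix beyond the longest note (plus one window) is trimmed before the
convolution, which changes no pooled feature but cuts cost roughly in
proportion to the padding share.

## Training

Adadelta (rho = 0.95, eps = 1e-6, the optimizer's published defaults) with
learning rate 0.5, batch size 32, 20 epochs.  Conv and output weights are
initialized U(-0.01, 0.01); after every update each filter's weight vector
is projected back to max-norm 3.  Dropout (rate 0.5) is applied to the
penultimate feature vector V during training only.

Class imbalance is handled by per-class loss weights `w_c = 1 / n_c`.  The
batch loss is the *weighted mean* cross-entropy, `sum(w_i ce_i) / sum(w_i)`:
normalizing by the weight sum keeps the loss on the usual nats scale
regardless of class counts (the raw 1/n_c weights would otherwise shrink
every gradient by ~1/n, which stalls Adadelta, whose epsilon floors the
accumulated squared gradients).  With weighting disabled all weights are 1
and the loss is the plain batch mean.

Embeddings are trainable by default.  In the combined model the table is
shared by both branches, but only word-branch gradients update it (the
sentence branch sees a detached view); the padding row is additionally
frozen at zero so "padding contributes nothing" stays exact under
fine-tuning.  Probabilities inside the loss are clamped to
[1e-12, 1 - 1e-12].

Backpropagation uses the max-over-time structure: per feature map only the
winning window carries gradient, so the backward pass gathers one window per
map and scatter-adds into the embedding table instead of re-running the
convolution.  All model math is float32; a fixed seed plus single-threaded
execution reproduces parameters bit-for-bit.

## Word embeddings

`CBOWEmbeddings` is a compact single-threaded implementation of
continuous-bag-of-words with negative sampling: mean-pooled context, window
10 (shrunk uniformly per position), min-count 5, 10 noise samples drawn from
the unigram^0.75 distribution, 15 iterations, linearly decaying learning
rate from 0.025.  `align_to_vocabulary` re-indexes the raw token -> vector
map against a task vocabulary: missing tokens share the `unk` row
(U(-0.01, 0.01)), and `padding` is all zeros.  When no pretrained table is
supplied, classifiers fall back to a random U(-0.1, 0.1) table — wider than
the conv init so the initial feature scale resembles pretrained word2vec
vectors (whose components are typically O(0.1)); with U(-0.01, 0.01)
embeddings the initial gradients are small enough that Adadelta barely moves
in 20 epochs.

## Preprocessing

Cleansing keeps ASCII letters, digits, space, and `, ( ) ! ? ' .` (the prime
glyph is normalized to an ASCII apostrophe); everything else becomes a
space, runs collapse, and the result is stripped.  Tokenization splits on
spaces with kept punctuation emitted as standalone tokens.  Sentence
segmentation treats a period as an unconditional boundary and a comma as a
boundary only when strictly more than 5 tokens accumulated since the last
boundary (long comma-spliced spans act as sentences in clinical notes);
boundary characters are dropped from sentence token lists but retained in
the word-level stream.  Vocabulary indices are 1-based in order of first
appearance, with `unk` = 1 (out-of-vocabulary) and `padding` = 2; tables
allocate a dummy row 0 so index i addresses row i.  Sequence maxima default
to corpus maxima; longer documents at inference are tail-truncated with a
warning.  At predict time, indices beyond the fitted embedding table are
mapped to `unk`.

## Evaluation

One-vs-rest binary evaluation per phenotype with stratified 10-fold CV
(stratification keeps minority folds non-empty at the prevalences involved,
0.08-0.3).  Metrics: precision, recall, F1 at threshold 0.5, and
tie-corrected rank AUROC.  Summaries report the fold mean and SE =
sd/sqrt(k) (sd with ddof = 1).  Learning curves re-run the same folds while
uniformly subsampling each fold's training split to a fraction of its size;
test folds are fixed across fractions, and fraction 1.0 reproduces the plain
CV exactly (same seed).  Subsampling ignores class balance; a fraction that
leaves a single-class training split skips that fold with a warning.

## Token selection

`token_frequencies` counts token types with rank order descending by count,
ties broken by first appearance.  `zipf_fit` is OLS of log10 frequency on
log10 rank over a closed rank window (default 10-1500, avoiding the
flattened head and singleton tail); the exponent is alpha = -slope.
`frequency_filter` deletes every token type occurring <= theta times
(occurrences are dropped, not mapped to `unk`, since the analysis re-runs on
the remaining tokens with re-padding).  `filter_by_categories` restricts a
corpus to a kept subset of the seven semantic categories (symptoms,
descriptions, medicine, body, numbers, verbs, others); category maps for
real corpora are input data (TSV), as manual categorization is not
reconstructible.  `greedy_category_removal` removes one category at a time,
always the one whose removal yields the highest evaluator score (ties by
name order); the category removed at step s of K gets rank K + 1 - s and the
survivor gets rank 1, so rank 1 = most important.  The default evaluator in
the experiments is holdout F1 of a reduced w-CNN (two filter groups, 50
maps, 8 epochs) — lighter than full CV per candidate set but the same
pipeline; AUROC is selectable.  The information-content metric is
psi = N x p_t, and matching a reference level N' x p_t' requires
N = ceil(N' p_t'/p_t) samples.

## Synthetic corpora

The generator draws background tokens by inverse-CDF lookup over a fixed
Zipf rank table (exact exponent control, rejection-free), assigns each
phenotype label independently per note by its prevalence, plants
phenotype-specific signal tokens — each emitted per sentence with
probability `signal_rate` in positive notes only — and emits fresh
never-reused "noise" singletons (spelling-error analogues) at a small
per-token rate.  Categories are assigned round-robin over background ranks;
all of a phenotype's signal tokens share one configurable category (default
"symptoms") so category-prioritization recovery is testable.  Defaults
mirror the target benchmark's scale: 1,610 notes, 10 phenotypes with
prevalences 0.29 down to 0.08, ~48.8k background types, alpha = 0.97,
100-300 sentences/note of 5-13 words, singleton rate 0.006 (~0.6% of token
occurrences, matching a corpus where ~42% of *types* are singletons).

What the generator deliberately does not emulate: real clinical vocabulary,
negation and hedging, section structure, annotator noise, or label
correlation between phenotypes (labels are independent).  Signal tokens
never appear in negative notes, so the benchmark tasks are easier than real
phenotyping; passing benchmarks demonstrates that the pipeline's machinery
(optimization, weighting, selection, evaluation) behaves correctly, not that
the reported real-data performance levels would be attained.

## Benchmark scales

The bundled experiments (`phenocnn.experiments`) run at desk scale, chosen
so the full suite completes in minutes on one CPU core: classification
corpora of 400-500 notes with 5-9 sentences of 4-9 words (one phenotype,
prevalence 0.3 unless stated), 10-fold CV, the full 100-maps-per-group
w-CNN/ws-CNN.  The permutation null uses 5 independent corpus/permutation
seeds.  The weight-balancing comparison uses prevalence 0.1 with a weak
per-sentence signal (rate 0.1, 2 tokens), where the unweighted model
collapses to the majority class.  Zipf recovery generates ~1e6 background
draws (500 notes of 200-250 sentences) against a 48,848-rank table and fits
ranks 10-1500.  Greedy recovery uses 240-note corpora and the holdout
evaluator above.

## Numerical notes and limitations

* Adadelta from small weights has a long warm-up; tasks with only a handful
  of updates per epoch may not converge in 20 epochs even when separable.
  The benchmark scales above provide ~100+ updates, which suffices.
* Max-over-time argmax ties (exactly equal map values) route gradient to the
  first maximizing position; with continuous inputs ties essentially never
  occur.
* `zipf_fit` requires at least 3 window points and a table at least
  `rank_hi` deep; single-class AUROC is returned as NaN with a flag rather
  than raised.
* The CBOW trainer is intended for corpora up to a few hundred thousand
  tokens; it is exact to its specification but not performance-tuned beyond
  that.
* Checkpoints serialize parameters as JSON (text-only artifacts); for the
  bundled model sizes this is adequate if not compact.
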