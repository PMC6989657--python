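# phenocnn

Patient phenotyping from free-text clinical notes with word- and
sentence-level convolutional neural networks, plus the token-statistics
analyses that explain *why* such classifiers work: Zipf rank-frequency
fitting, frequency-threshold token filtering, and greedy semantic-category
prioritization.

## The problem

Discharge summaries are free-form text whose style varies wildly between
records, yet they carry enough signal to predict whether a patient has a
given disorder (advanced cancer, chronic pain, depression, ...).  The
reference setting for this package is the MIMIC-III discharge-summary
phenotyping benchmark: 1,610 expert-annotated notes, ten binary phenotypes,
one-vs-rest classification.  Those notes are access-controlled, so
`phenocnn` ships a synthetic note generator with the same statistical
skeleton — Zipf-distributed vocabulary (f(r) ~ r^-alpha), documents of many
short sentences, once-only noise tokens, category-tagged signal tokens,
uneven multi-label prevalences — and every analysis is exercised end to end
on generated corpora with known ground truth.

## The models

The **w-CNN** embeds a note's token-index sequence into an L x d matrix
(d = 50) and applies groups of temporal convolutions (filter lengths 1-4 or
2-5 per phenotype, 100 feature maps each, stride 1):

    c_i = ReLU(w · x_{i:i+l-1} + b)

Max-over-time pooling keeps one value per feature map; the pooled feature
vector V feeds a sigmoid output y = σ(w·V + b) = P(positive).  The
**ws-CNN** adds a sentence branch: each sentence's word vectors are pooled
(sum or average over the true sentence length, padding excluded) into a
sentence embedding, a second set of conv groups (lengths {1,5,7,9}, 50 maps)
runs over the sentence axis, and both branches concatenate at the
penultimate layer.

Training is cost-sensitive: per-class weights 1/n_c in the cross-entropy,
Adadelta (lr 0.5), batch 32, 20 epochs, dropout 0.5 on V, max-norm 3 on
filter weights, trainable embeddings fine-tuned by word-branch gradients
only.  CBOW word2vec embeddings (window 10, min-count 5, 10 negative
samples, 15 iterations) can be pre-trained on a larger unlabelled corpus.
Everything is pure numpy; no deep-learning framework is required.

Classifiers follow scikit-learn conventions (`fit`, `predict_proba`,
`get_params`, clone-safe), so they compose with sklearn model selection.

## Worked example

```python
from phenocnn import (
    GeneratorConfig, generate_corpus, encode_corpus,
    WordCNNClassifier, cross_validate, token_frequencies, zipf_fit,
)

cfg = GeneratorConfig(
    n_notes=500, n_phenotypes=1, vocab_size=2000, zipf_alpha=0.97,
    signal_tokens_per_phenotype=3, signal_rate=0.25,
    sentences_per_note=(5, 9), words_per_sentence=(4, 9),
    label_prevalences=(0.3,), singleton_rate=0.01, seed=1,
)
corpus = generate_corpus(cfg)
X, vocab = encode_corpus(corpus.notes)
y = corpus.labels[:, 0]

summary = cross_validate(WordCNNClassifier(random_state=1), X, y, k=10, seed=1)
print({m: round(v["mean"], 2) for m, v in summary.summary(percent=True).items()})

fit = zipf_fit(token_frequencies(corpus.notes), rank_lo=10, rank_hi=500)
print(f"alpha = {fit.alpha:.2f}")
```

Output:

```
{'precision': 100.0, 'recall': 99.38, 'f1': 99.68, 'auroc': 99.89}
alpha = 0.97
```

The classifier recovers the planted token signal almost perfectly (mean
10-fold AUROC 99.89%, F1 99.68%), and the rank-frequency fit over ranks
10-500 recovers the configured exponent alpha = 0.97.

The same pipeline is scriptable from the shell:

```bash
phenocnn generate --out-dir corpus --n-notes 500 --n-phenotypes 1 --seed 1
phenocnn evaluate --notes corpus/notes.jsonl --labels corpus/labels.csv \
    --model word --k 10 --seed 1 --out-dir results
phenocnn zipf --notes corpus/notes.jsonl --out results/zipf.json
```

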