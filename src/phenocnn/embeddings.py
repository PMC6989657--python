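"""CBOW word embeddings and vocabulary-aligned lookup tables.

The classifiers consume a dense table whose row ``i`` is the d-dimensional
vector of vocabulary index ``i``.  The table is produced in two steps:

1. :class:`CBOWEmbeddings` trains continuous-bag-of-words vectors with
   negative sampling on an (unlabelled) token corpus — typically much larger
   than the labelled task corpus.
2. :func:`align_to_vocabulary` re-indexes the raw ``token -> vector`` map
   against a task :class:`~phenocnn.preprocessing.Vocabulary`: in-map tokens
   copy their vector, absent tokens share the ``unk`` row (small random
   values), and the ``padding`` row is all zeros so padded positions pool to
   nothing.

The trainer is a small single-threaded implementation of the standard CBOW
negative-sampling updates (mean-pooled context, unigram^0.75 noise
distribution, linearly decaying learning rate) — adequate for the corpus
sizes this package works with and exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .preprocessing import PAD_INDEX, UNK_INDEX, Vocabulary

__all__ = [
    "EmbeddingConfig",
    "EmbeddingTable",
    "CBOWEmbeddings",
    "train_cbow",
    "align_to_vocabulary",
    "save_word2vec_text",
    "load_word2vec_text",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    dimension: int = 50
    window: int = 10
    min_count: int = 5
    negative_samples: int = 10
    iterations: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dimension", "window", "min_count", "negative_samples", "iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class EmbeddingTable:
    """Index-aligned embedding matrix; row ``i`` is vocabulary index ``i``.

    Row 0 is an unused placeholder so 1-based indices address rows directly.
    """

    matrix: np.ndarray  # (vocab_size + 1, d)

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    @property
    def vocab_size(self) -> int:
        return self.matrix.shape[0] - 1

    def __getitem__(self, index):
        return self.matrix[index]


def _iter_sentences(corpus):
    for doc in corpus:
        if not doc:
            continue
        if isinstance(doc[0], str):
            yield doc
        else:
            yield from (s for s in doc if s)


class CBOWEmbeddings(BaseEstimator):
    """Continuous-bag-of-words embeddings with negative sampling.

    Parameters mirror the classic word2vec CBOW configuration: *window* is
    the one-sided context size (shrunk uniformly per position as in the
    reference implementation), *negative* the number of noise samples per
    positive example, and tokens seen fewer than *min_count* times are
    dropped before training.
    """

    def __init__(
        self,
        dimension: int = 50,
        window: int = 10,
        min_count: int = 5,
        negative: int = 10,
        epochs: int = 15,
        learning_rate: float = 0.025,
        seed: int = 0,
    ):
        self.dimension = dimension
        self.window = window
        self.min_count = min_count
        self.negative = negative
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, corpus, y=None):
        """Train on an iterable of token sequences (or sentence-structured docs)."""
        sentences = [list(s) for s in _iter_sentences(corpus)]
        if not sentences:
            raise ValueError("cannot train embeddings on an empty corpus")
        counts: dict[str, int] = {}
        for sent in sentences:
            for tok in sent:
                counts[tok] = counts.get(tok, 0) + 1
        tokens = [t for t, c in counts.items() if c >= self.min_count]
        if not tokens:
            raise ValueError("no token reaches min_count; corpus too small")
        index = {t: i for i, t in enumerate(tokens)}
        V, d = len(tokens), self.dimension

        rng = np.random.default_rng(self.seed)
        W_in = (rng.random((V, d)) - 0.5) / d
        W_out = np.zeros((V, d))

        freq = np.array([counts[t] for t in tokens], dtype=float)
        noise_cdf = np.cumsum(freq**0.75)
        noise_cdf /= noise_cdf[-1]

        encoded = [
            np.array([index[t] for t in sent if t in index], dtype=np.int64)
            for sent in sentences
        ]
        encoded = [s for s in encoded if len(s) >= 2]
        total_words = sum(len(s) for s in encoded) * self.epochs
        lr0, lr_min, seen = self.learning_rate, 1e-4, 0

        for _ in range(self.epochs):
            order = rng.permutation(len(encoded))
            for si in order:
                sent = encoded[si]
                n = len(sent)
                shrink = rng.integers(1, self.window + 1, size=n)
                for t in range(n):
                    lr = max(lr_min, lr0 * (1 - seen / total_words))
                    seen += 1
                    b = int(shrink[t])
                    lo, hi = max(0, t - b), min(n, t + b + 1)
                    ctx = np.concatenate([sent[lo:t], sent[t + 1 : hi]])
                    if len(ctx) == 0:
                        continue
                    h = W_in[ctx].mean(axis=0)
                    neg = np.searchsorted(
                        noise_cdf, rng.random(self.negative), side="left"
                    )
                    targets = np.concatenate([[sent[t]], neg])
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    out = W_out[targets]
                    f = 1.0 / (1.0 + np.exp(-out @ h))
                    g = (labels - f) * lr
                    e = g @ out
                    W_out[targets] += np.outer(g, h)
                    W_in[ctx] += e / len(ctx)

        self.tokens_ = tokens
        self.index_ = index
        self.vectors_ = W_in
        return self

    def __contains__(self, token: str) -> bool:
        return token in self.index_

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors_[self.index_[token]]

    def to_map(self) -> dict:
        return {t: self.vectors_[i].copy() for t, i in self.index_.items()}


def train_cbow(corpus, config: EmbeddingConfig = EmbeddingConfig()) -> dict:
    """Functional wrapper: train CBOW vectors and return a token -> vector map."""
    est = CBOWEmbeddings(
        dimension=config.dimension,
        window=config.window,
        min_count=config.min_count,
        negative=config.negative_samples,
        epochs=config.iterations,
        seed=config.seed,
    )
    return est.fit(corpus).to_map()


def align_to_vocabulary(
    raw_map: dict, vocab: Vocabulary, seed: int = 0
) -> EmbeddingTable:
    """Build the index-aligned table for *vocab* from a raw token->vector map.

    Tokens missing from the map share the ``unk`` row, drawn uniformly from
    [-0.01, 0.01]; the ``padding`` row is zero and stays out of any pooling.
    """
    if not raw_map:
        raise ValueError("empty embedding map")
    dims = {len(v) for v in raw_map.values()}
    if len(dims) != 1:
        raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
    d = dims.pop()
    rng = np.random.default_rng(seed)
    matrix = np.zeros((len(vocab) + 1, d))
    matrix[UNK_INDEX] = rng.uniform(-0.01, 0.01, size=d)
    matrix[PAD_INDEX] = 0.0
    for i, tok in enumerate(vocab.tokens, start=1):
        if i in (UNK_INDEX, PAD_INDEX):
            continue
        vec = raw_map.get(tok)
        matrix[i] = matrix[UNK_INDEX] if vec is None else np.asarray(vec, dtype=float)
    return EmbeddingTable(matrix=matrix)


def save_word2vec_text(raw_map: dict, path) -> None:
    """Write a token->vector map in word2vec text format."""
    items = list(raw_map.items())
    if not items:
        raise ValueError("empty embedding map")
    d = len(items[0][1])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(items)} {d}\n")
        for tok, vec in items:
            fh.write(tok + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def load_word2vec_text(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        count, d = int(header[0]), int(header[1])
        raw = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < d + 1:
                continue
            raw[parts[0]] = np.array([float(v) for v in parts[1:]], dtype=float)
    if len(raw) != count:
        raise ValueError("embedding file header count does not match contents")
    return raw
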