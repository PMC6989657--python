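"""scikit-learn-style estimators wrapping the CNN models and trainer.

:class:`WordCNNClassifier` consumes a padded word-index matrix (n_samples,
L_max); :class:`WordSentenceCNNClassifier` additionally needs the
two-dimensionally padded sentence view, so both accept the
:class:`EncodedNotes` container, which carries all three arrays and supports
fancy indexing (hence composes with cross-validation splitters).

Both estimators implement ``fit`` / ``predict`` / ``predict_proba`` /
``get_params`` / ``set_params`` and expose fitted state with trailing
underscores, so they clone and grid-search like any other sklearn
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import models, training
from .embeddings import EmbeddingTable
from .preprocessing import Vocabulary, build_vocabulary, index_and_pad_sentences, index_and_pad_words

__all__ = [
    "EncodedNotes",
    "encode_corpus",
    "estimator_for_phenotype",
    "WordCNNClassifier",
    "WordSentenceCNNClassifier",
]


@dataclass
class EncodedNotes:
    """Index-encoded corpus: word view plus optional sentence view."""

    word: np.ndarray  # (n, L_max)
    sent: np.ndarray | None = None  # (n, S_max, W_max)
    sent_len: np.ndarray | None = None  # (n, S_max)

    def __len__(self) -> int:
        return self.word.shape[0]

    def __getitem__(self, idx) -> "EncodedNotes":
        return EncodedNotes(
            word=self.word[idx],
            sent=None if self.sent is None else self.sent[idx],
            sent_len=None if self.sent_len is None else self.sent_len[idx],
        )

    @property
    def shape(self):  # lets sklearn utilities report n_samples
        return (len(self), self.word.shape[1])

    def as_dict(self) -> dict:
        return {"word": self.word, "sent": self.sent, "sent_len": self.sent_len}


def encode_corpus(
    documents,
    vocab: Vocabulary | None = None,
    case_sensitive: bool = True,
    L_max: int | None = None,
    W_max: int | None = None,
    S_max: int | None = None,
    min_sentence_filter: int = 9,
    min_word_filter: int = 5,
) -> tuple[EncodedNotes, Vocabulary]:
    """Encode sentence-structured documents into an :class:`EncodedNotes`.

    *documents* is a list of documents, each a list of sentences (token
    lists).  Maxima default to the corpus maxima; ``L_max`` and ``S_max``
    are floored at *min_word_filter* / *min_sentence_filter* so the longest
    conv filters always fit even on degenerate corpora.  Documents longer
    than explicit maxima are tail-truncated.
    """
    if vocab is None:
        vocab = build_vocabulary(documents, case_sensitive=case_sensitive)
    flat = [[t for s in doc for t in s] for doc in documents]
    L = L_max or max(min_word_filter, max((len(f) for f in flat), default=1))
    W = W_max or max((len(s) for doc in documents for s in doc), default=1)
    S = S_max or max(min_sentence_filter, max((len(doc) for doc in documents), default=1))

    word = np.empty((len(documents), L), dtype=np.int64)
    sent = np.empty((len(documents), S, W), dtype=np.int64)
    sent_len = np.empty((len(documents), S), dtype=np.int64)
    for i, doc in enumerate(documents):
        note = index_and_pad_words(flat[i], vocab, L, overflow="truncate")
        snote = index_and_pad_sentences(doc, vocab, W, S, overflow="truncate")
        word[i] = note.indices
        sent[i] = snote.indices
        sent_len[i] = snote.sentence_lengths
    return EncodedNotes(word=word, sent=sent, sent_len=sent_len), vocab


def _word_matrix(X) -> np.ndarray:
    if isinstance(X, EncodedNotes):
        return X.word
    return np.asarray(X, dtype=np.int64)


def _clip_to_table(idx: np.ndarray | None, n_rows: int) -> np.ndarray | None:
    """Map indices beyond the embedding table to ``unk`` (unseen tokens)."""
    if idx is None or idx.max() < n_rows:
        return idx
    from .preprocessing import UNK_INDEX

    return np.where(idx < n_rows, idx, UNK_INDEX)


def _as_table(embedding, vocab_size_hint: int, dim: int, seed: int) -> np.ndarray:
    """Resolve the embedding init: a table, an array, or random U(-0.1, 0.1).

    The random fallback uses a wider range than the +/-0.01 conv init so the
    initial feature scale resembles that of pretrained word2vec vectors.
    """
    if embedding is None:
        rng = np.random.default_rng(seed)
        E = rng.uniform(-0.1, 0.1, size=(vocab_size_hint + 1, dim)).astype(np.float32)
        E[0] = 0.0
        E[2] = 0.0  # padding row
        return E
    if isinstance(embedding, EmbeddingTable):
        return np.array(embedding.matrix, dtype=np.float32)
    return np.array(embedding, dtype=np.float32)


class _CNNClassifierBase(BaseEstimator, ClassifierMixin):
    def _train_config(self) -> training.TrainConfig:
        return training.TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            dropout=self.dropout,
            max_norm=self.max_norm,
            init_range=self.init_range,
            class_weighting=self.class_weighting,
            trainable_embeddings=self.trainable_embeddings,
            seed=self.random_state,
        )

    def _check_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])
        return y.astype(float)

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


class WordCNNClassifier(_CNNClassifierBase):
    """Word-level-input CNN (w-CNN) binary phenotype classifier.

    One conv group per entry of *filter_lengths* (each with *n_maps* feature
    maps), max-over-time pooling, dropout on the pooled feature vector, and a
    sigmoid output unit.  ``embedding`` may be an
    :class:`~phenocnn.embeddings.EmbeddingTable`, a raw ``(vocab+1, d)``
    array, or None for a random U(-0.1, 0.1) table (``vocab_size`` then
    required or inferred from the training data).
    """

    def __init__(
        self,
        filter_lengths=(1, 2, 3, 4),
        n_maps: int = 100,
        embedding=None,
        embedding_dim: int = 50,
        vocab_size: int | None = None,
        learning_rate: float = 0.5,
        batch_size: int = 32,
        epochs: int = 20,
        dropout: float = 0.5,
        max_norm: float = 3.0,
        init_range: float = 0.01,
        class_weighting: bool = True,
        trainable_embeddings: bool = True,
        random_state: int = 0,
    ):
        self.filter_lengths = filter_lengths
        self.n_maps = n_maps
        self.embedding = embedding
        self.embedding_dim = embedding_dim
        self.vocab_size = vocab_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.max_norm = max_norm
        self.init_range = init_range
        self.class_weighting = class_weighting
        self.trainable_embeddings = trainable_embeddings
        self.random_state = random_state

    def fit(self, X, y, X_valid=None, y_valid=None):
        word = _word_matrix(X)
        y = self._check_y(y)
        vs = self.vocab_size or int(word.max())
        E = _as_table(self.embedding, vs, self.embedding_dim, self.random_state)
        self.model_ = models.init_model(
            E,
            word_filter_lengths=self.filter_lengths,
            word_n_maps=self.n_maps,
            pooling_mode="average",
            dropout=self.dropout,
            init_range=self.init_range,
            seed=self.random_state,
        )
        Xv = None
        if X_valid is not None:
            Xv = {"word": _word_matrix(X_valid), "sent": None, "sent_len": None}
        _, self.loss_trace_ = training.fit(
            self.model_,
            {"word": word, "sent": None, "sent_len": None},
            y,
            config=self._train_config(),
            X_valid=Xv,
            y_valid=y_valid,
        )
        return self

    def decision_scores(self, X) -> np.ndarray:
        """P(positive) per sample, deterministic (dropout off)."""
        word = _clip_to_table(_word_matrix(X), self.model_.embedding.shape[0])
        return training._forward_all(
            self.model_, {"word": word, "sent": None, "sent_len": None}
        )


class WordSentenceCNNClassifier(_CNNClassifierBase):
    """Combined word- and sentence-level CNN (ws-CNN).

    The word branch is identical to :class:`WordCNNClassifier`; the sentence
    branch pools each sentence's word vectors (sum or average over true
    lengths) and convolves over the sentence axis with its own filter
    groups.  Both feature vectors concatenate at the penultimate layer.  The
    shared embedding table is fine-tuned by word-branch gradients only.
    """

    def __init__(
        self,
        word_filter_lengths=(1, 2, 3, 4),
        word_n_maps: int = 100,
        sentence_filter_lengths=(1, 5, 7, 9),
        sentence_n_maps: int = 50,
        pooling_mode: str = "average",
        embedding=None,
        embedding_dim: int = 50,
        vocab_size: int | None = None,
        learning_rate: float = 0.5,
        batch_size: int = 32,
        epochs: int = 20,
        dropout: float = 0.5,
        max_norm: float = 3.0,
        init_range: float = 0.01,
        class_weighting: bool = True,
        trainable_embeddings: bool = True,
        random_state: int = 0,
    ):
        self.word_filter_lengths = word_filter_lengths
        self.word_n_maps = word_n_maps
        self.sentence_filter_lengths = sentence_filter_lengths
        self.sentence_n_maps = sentence_n_maps
        self.pooling_mode = pooling_mode
        self.embedding = embedding
        self.embedding_dim = embedding_dim
        self.vocab_size = vocab_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.max_norm = max_norm
        self.init_range = init_range
        self.class_weighting = class_weighting
        self.trainable_embeddings = trainable_embeddings
        self.random_state = random_state

    @staticmethod
    def _encoded(X) -> EncodedNotes:
        if not isinstance(X, EncodedNotes) or X.sent is None:
            raise ValueError(
                "the combined model needs EncodedNotes with a sentence view"
            )
        return X

    def fit(self, X, y, X_valid=None, y_valid=None):
        X = self._encoded(X)
        y = self._check_y(y)
        if X.sent.shape[1] < max(self.sentence_filter_lengths):
            raise ValueError(
                "S_max is shorter than the longest sentence-branch filter"
            )
        vs = self.vocab_size or int(max(X.word.max(), X.sent.max()))
        E = _as_table(self.embedding, vs, self.embedding_dim, self.random_state)
        self.model_ = models.init_model(
            E,
            word_filter_lengths=self.word_filter_lengths,
            word_n_maps=self.word_n_maps,
            sent_filter_lengths=self.sentence_filter_lengths,
            sent_n_maps=self.sentence_n_maps,
            pooling_mode=self.pooling_mode,
            dropout=self.dropout,
            init_range=self.init_range,
            seed=self.random_state,
        )
        Xv = self._encoded(X_valid).as_dict() if X_valid is not None else None
        _, self.loss_trace_ = training.fit(
            self.model_,
            X.as_dict(),
            y,
            config=self._train_config(),
            X_valid=Xv,
            y_valid=y_valid,
        )
        return self

    def decision_scores(self, X) -> np.ndarray:
        X = self._encoded(X)
        n_rows = self.model_.embedding.shape[0]
        return training._forward_all(
            self.model_,
            {
                "word": _clip_to_table(X.word, n_rows),
                "sent": _clip_to_table(X.sent, n_rows),
                "sent_len": X.sent_len,
            },
        )


def estimator_for_phenotype(phenotype: str, model: str = "word", **overrides):
    """Classifier configured with a benchmark phenotype's hyperparameters.

    Looks up the per-phenotype word-branch filter lengths and (for the
    combined model) the sentence-pooling mode; unknown phenotype names fall
    back to the defaults (filter lengths 1-4, average pooling).
    """
    lengths = models.PHENOTYPE_FILTER_LENGTHS.get(phenotype, (1, 2, 3, 4))
    if model == "word":
        kwargs = {"filter_lengths": lengths}
        kwargs.update(overrides)
        return WordCNNClassifier(**kwargs)
    if model == "ws":
        kwargs = {
            "word_filter_lengths": lengths,
            "pooling_mode": models.SENTENCE_POOLING_MODE.get(phenotype, "average"),
        }
        kwargs.update(overrides)
        return WordSentenceCNNClassifier(**kwargs)
    raise ValueError(f"unknown model {model!r} (choose 'word' or 'ws')")
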