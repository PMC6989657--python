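"""Word-level and combined word+sentence-level convolutional classifiers.

The word branch embeds a token-index sequence into an L x d matrix, runs
groups of length-``l`` temporal convolutions (stride 1, no temporal padding,
ReLU), reduces each feature map by max-over-time pooling, and concatenates
the pooled values into a feature vector V.  The combined model adds a
sentence branch: each sentence's word vectors are pooled (sum or average over
the true, pre-padding length) into one sentence embedding, and the same
conv + max-over-time machinery runs over the sentence axis.  Both branches'
features concatenate at the penultimate layer; the output is a single
sigmoid unit y = phi(w . V + b), read as P(positive).

Feature value: ``c_i = f(w . x_{i:i+l-1} + b)`` with f = ReLU, where
``x_{i:i+l-1}`` is the flattened window of ``l`` consecutive d-dimensional
rows.

Everything here is plain numpy; the batched forward/backward pair at the
bottom is what the trainer drives.  Backpropagation exploits max-over-time:
only the winning window of each feature map carries gradient, so the
backward pass gathers one window per map instead of re-running the
convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .embeddings import EmbeddingTable
from .preprocessing import PAD_INDEX

__all__ = [
    "PHENOTYPE_FILTER_LENGTHS",
    "SENTENCE_POOLING_MODE",
    "ConvFilterGroup",
    "ModelParams",
    "conv_feature_map",
    "max_over_time",
    "sentence_embed",
    "forward",
    "init_model",
]

#: per-phenotype word-branch filter lengths used on the benchmark disorders
PHENOTYPE_FILTER_LENGTHS = {
    "Adv. Cancer": (1, 2, 3, 4),
    "Chronic Neuro": (1, 2, 3, 4),
    "Depression": (1, 2, 3, 4),
    "Adv. Lung Disease": (2, 3, 4, 5),
    "Chronic Pain": (2, 3, 4, 5),
    "Alcohol Abuse": (2, 3, 4, 5),
    "Obesity": (2, 3, 4, 5),
    "Psychiatric Disorders": (2, 3, 4, 5),
    "Substance Abuse": (2, 3, 4, 5),  # unlisted in the protocol; majority group
    "Adv. Heart Disease": (1, 2, 3, 4, 5),
}

#: per-phenotype sentence-embedding pooling mode for the combined model
SENTENCE_POOLING_MODE = {
    "Adv. Cancer": "sum",
    "Adv. Heart Disease": "sum",
    "Chronic Pain": "sum",
    "Adv. Lung Disease": "average",
    "Chronic Neuro": "average",
    "Alcohol Abuse": "average",
    "Substance Abuse": "average",
    "Obesity": "average",
    "Psychiatric Disorders": "average",
    "Depression": "average",
}


@dataclass
class ConvFilterGroup:
    """All filters of one length: weights are (n_maps, l*d), one bias per map."""

    filter_length: int
    weights: np.ndarray
    bias: np.ndarray

    @property
    def n_maps(self) -> int:
        return self.weights.shape[0]


@dataclass
class ModelParams:
    embedding: np.ndarray  # (vocab_size + 1, d); row 0 unused, row PAD zero
    word_groups: list[ConvFilterGroup]
    w_out: np.ndarray  # (F,)
    b_out: float
    sent_groups: list[ConvFilterGroup] = field(default_factory=list)
    pooling_mode: str = "average"
    dropout: float = 0.5

    @property
    def dimension(self) -> int:
        return self.embedding.shape[1]

    @property
    def feature_size(self) -> int:
        return sum(g.n_maps for g in self.word_groups) + sum(
            g.n_maps for g in self.sent_groups
        )

    @property
    def has_sentence_branch(self) -> bool:
        return len(self.sent_groups) > 0

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        def group(g):
            return {
                "filter_length": g.filter_length,
                "weights": g.weights.tolist(),
                "bias": g.bias.tolist(),
            }

        payload = {
            "embedding": self.embedding.tolist(),
            "word_groups": [group(g) for g in self.word_groups],
            "sent_groups": [group(g) for g in self.sent_groups],
            "w_out": self.w_out.tolist(),
            "b_out": float(self.b_out),
            "pooling_mode": self.pooling_mode,
            "dropout": self.dropout,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)

        def group(d):
            return ConvFilterGroup(
                filter_length=d["filter_length"],
                weights=np.asarray(d["weights"], dtype=float),
                bias=np.asarray(d["bias"], dtype=float),
            )

        return cls(
            embedding=np.asarray(payload["embedding"], dtype=float),
            word_groups=[group(g) for g in payload["word_groups"]],
            sent_groups=[group(g) for g in payload["sent_groups"]],
            w_out=np.asarray(payload["w_out"], dtype=float),
            b_out=payload["b_out"],
            pooling_mode=payload["pooling_mode"],
            dropout=payload["dropout"],
        )


def init_model(
    embedding: EmbeddingTable | np.ndarray,
    word_filter_lengths,
    word_n_maps: int = 100,
    sent_filter_lengths=(),
    sent_n_maps: int = 50,
    pooling_mode: str = "average",
    dropout: float = 0.5,
    init_range: float = 0.01,
    seed: int = 0,
) -> ModelParams:
    """Fresh model with conv and output weights ~ U(-init_range, init_range)."""
    E = embedding.matrix if isinstance(embedding, EmbeddingTable) else embedding
    E = np.array(E, dtype=np.float32)
    d = E.shape[1]
    rng = np.random.default_rng(seed)

    def groups(lengths, n_maps):
        return [
            ConvFilterGroup(
                filter_length=l,
                weights=rng.uniform(
                    -init_range, init_range, size=(n_maps, l * d)
                ).astype(np.float32),
                bias=np.zeros(n_maps, dtype=np.float32),
            )
            for l in lengths
        ]

    word_groups = groups(word_filter_lengths, word_n_maps)
    sent_groups = groups(sent_filter_lengths, sent_n_maps)
    F = word_n_maps * len(word_groups) + sent_n_maps * len(sent_filter_lengths)
    return ModelParams(
        embedding=E,
        word_groups=word_groups,
        sent_groups=sent_groups,
        w_out=rng.uniform(-init_range, init_range, size=F).astype(np.float32),
        b_out=0.0,
        pooling_mode=pooling_mode,
        dropout=dropout,
    )


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def conv_feature_map(X: np.ndarray, group: ConvFilterGroup) -> np.ndarray:
    """Feature maps for one input matrix: (n_maps, L - l + 1), ReLU applied."""
    X = np.asarray(X, dtype=float)
    L = X.shape[0]
    l = group.filter_length
    if L < l:
        raise ValueError(f"input length {L} shorter than filter length {l}")
    win = sliding_window_view(X, l, axis=0)  # (T, d, l)
    win = win.transpose(0, 2, 1).reshape(L - l + 1, -1)  # (T, l*d)
    return np.maximum(win @ group.weights.T + group.bias, 0.0).T


def max_over_time(C: np.ndarray) -> np.ndarray:
    """One value per feature map: the maximum along the temporal axis."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] == 0:
        raise ValueError("feature maps must be a non-empty (n_maps, T) array")
    return C.max(axis=1)


def sentence_embed(
    E_prime: np.ndarray, lengths: np.ndarray, mode: str = "average"
) -> np.ndarray:
    """Pool an S x W x d embedded note into S sentence vectors.

    Only the first ``lengths[s]`` word vectors of sentence *s* contribute;
    all-padding sentences yield zero rows.
    """
    if mode not in ("sum", "average"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    E_prime = np.asarray(E_prime, dtype=float)
    lengths = np.asarray(lengths, dtype=np.int64)
    S, W, _ = E_prime.shape
    mask = (np.arange(W)[None, :] < lengths[:, None]).astype(float)
    pooled = (E_prime * mask[:, :, None]).sum(axis=1)
    if mode == "average":
        denom = np.maximum(lengths, 1).astype(float)
        pooled = pooled / denom[:, None]
    return pooled


def forward(
    word_indices: np.ndarray,
    params: ModelParams,
    sentence_indices: np.ndarray | None = None,
    sentence_lengths: np.ndarray | None = None,
    dropout_active: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Probability for one note. Deterministic unless ``dropout_active``."""
    E = params.embedding
    X = E[np.asarray(word_indices, dtype=np.int64)]
    feats = [max_over_time(conv_feature_map(X, g)) for g in params.word_groups]
    if params.has_sentence_branch:
        if sentence_indices is None or sentence_lengths is None:
            raise ValueError("combined model requires sentence-level input")
        E_prime = E[np.asarray(sentence_indices, dtype=np.int64)]
        pooled = sentence_embed(E_prime, sentence_lengths, params.pooling_mode)
        feats += [max_over_time(conv_feature_map(pooled, g)) for g in params.sent_groups]
    V = np.concatenate(feats)
    if dropout_active and params.dropout > 0:
        rng = rng or np.random.default_rng()
        keep = 1.0 - params.dropout
        V = V * (rng.random(V.shape) < keep) / keep
    return float(_sigmoid(V @ params.w_out + params.b_out))


# ---------------------------------------------------------------------------
# batched forward/backward used by the trainer
# ---------------------------------------------------------------------------


def _branch_forward(Xb, groups):
    """Conv + ReLU + max-over-time for one branch.

    The convolution is computed as a sum of l dense matmuls (one per window
    offset) rather than by materializing the (B, T, l*d) window tensor; only
    the argmax positions are cached, since max-over-time routes all gradient
    through the winning window of each map.
    """
    pooled_all, caches = [], []
    B, L, d = Xb.shape
    for g in groups:
        l = g.filter_length
        if L < l:
            raise ValueError(f"input length {L} shorter than filter length {l}")
        T = L - l + 1
        Wk = g.weights.reshape(g.n_maps, l, d)
        Z = Xb[:, 0:T, :] @ Wk[:, 0, :].T
        for k in range(1, l):
            Z += Xb[:, k : k + T, :] @ Wk[:, k, :].T
        Z += g.bias
        A = np.maximum(Z, 0.0, out=Z)  # (B, T, n), ReLU in place
        arg = A.argmax(axis=1)  # (B, n)
        pooled = np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :]
        pooled_all.append(pooled)
        caches.append({"arg": arg, "X": Xb})
    return pooled_all, caches


def batch_forward(
    params: ModelParams,
    word_idx: np.ndarray,
    sent_idx: np.ndarray | None = None,
    sent_len: np.ndarray | None = None,
    dropout_rng: np.random.Generator | None = None,
):
    """Vectorized forward over a batch; returns probabilities and a cache.

    Passing *dropout_rng* activates inverted dropout on the penultimate
    feature vector (training mode).
    """
    E = params.embedding
    Xb = E[word_idx]  # (B, L, d)
    word_pooled, word_caches = _branch_forward(Xb, params.word_groups)

    sent_pooled, sent_caches = [], []
    if params.has_sentence_branch:
        E_s = E[sent_idx]  # (B, S, W, d)
        W = sent_idx.shape[2]
        mask = (np.arange(W)[None, None, :] < sent_len[:, :, None]).astype(E.dtype)
        Sb = (E_s * mask[..., None]).sum(axis=2)  # (B, S, d)
        if params.pooling_mode == "average":
            Sb = Sb / np.maximum(sent_len, 1)[:, :, None]
        sent_pooled, sent_caches = _branch_forward(Sb, params.sent_groups)

    V = np.concatenate(word_pooled + sent_pooled, axis=1)  # (B, F)
    drop_mask = None
    V_d = V
    if dropout_rng is not None and params.dropout > 0:
        keep = 1.0 - params.dropout
        drop_mask = (dropout_rng.random(V.shape) < keep) / keep
        V_d = V * drop_mask
    logits = V_d @ params.w_out + params.b_out
    p = _sigmoid(logits)
    cache = {
        "word_idx": word_idx,
        "word_pooled": word_pooled,
        "word_caches": word_caches,
        "sent_pooled": sent_pooled,
        "sent_caches": sent_caches,
        "V_d": V_d,
        "drop_mask": drop_mask,
    }
    return p, cache


def batch_backward(params: ModelParams, cache, dlogits: np.ndarray):
    """Gradients given d(loss)/d(logit) per sample.

    Embedding gradients flow only through the word branch (the sentence
    branch's view of the table is detached), and never into the padding row.
    """
    dlogits = np.asarray(dlogits, dtype=params.w_out.dtype)
    grads = {
        "w_out": cache["V_d"].T @ dlogits,
        "b_out": float(dlogits.sum()),
        "word_groups": [],
        "sent_groups": [],
    }
    dV = np.outer(dlogits, params.w_out)
    if cache["drop_mask"] is not None:
        dV = dV * cache["drop_mask"]

    dE = np.zeros_like(params.embedding)
    V_rows, dim = dE.shape
    dE_flat = np.zeros(V_rows * dim)
    col = np.arange(dim)
    offset = 0
    word_idx = cache["word_idx"]
    B = word_idx.shape[0]
    rows_b = np.arange(B)[:, None]
    for g, pooled, gc in zip(
        params.word_groups, cache["word_pooled"], cache["word_caches"]
    ):
        n, l, d = g.n_maps, g.filter_length, params.dimension
        dpool = dV[:, offset : offset + n] * (pooled > 0)
        offset += n
        Wk = g.weights.reshape(n, l, d)
        dW = np.empty_like(Wk)
        Xb = gc["X"]
        for k in range(l):
            pos = gc["arg"] + k  # (B, n) positions of winner window row k
            rows = Xb[rows_b, pos]  # (B, n, d)
            dW[:, k, :] = np.einsum("bn,bnd->nd", dpool, rows)
            # scatter gradient into the embedding rows of the winning tokens:
            # one bincount over flattened (token, column) bins per offset
            ids = word_idx[rows_b, pos].ravel()
            contrib = (dpool[:, :, None] * Wk[None, :, k, :]).reshape(-1, d)
            bins = (ids[:, None] * dim + col).ravel()
            dE_flat += np.bincount(
                bins, weights=contrib.ravel(), minlength=V_rows * dim
            )
        grads["word_groups"].append(
            {"weights": dW.reshape(n, l * d), "bias": dpool.sum(axis=0)}
        )
    for g, pooled, gc in zip(
        params.sent_groups, cache["sent_pooled"], cache["sent_caches"]
    ):
        n, l, d = g.n_maps, g.filter_length, params.dimension
        dpool = dV[:, offset : offset + n] * (pooled > 0)
        offset += n
        dW = np.empty((n, l, d), dtype=g.weights.dtype)
        Xb = gc["X"]
        for k in range(l):
            rows = Xb[rows_b, gc["arg"] + k]
            dW[:, k, :] = np.einsum("bn,bnd->nd", dpool, rows)
        grads["sent_groups"].append(
            {"weights": dW.reshape(n, l * d), "bias": dpool.sum(axis=0)}
        )
    dE += dE_flat.reshape(V_rows, dim)
    dE[0] = 0.0
    dE[PAD_INDEX] = 0.0
    grads["embedding"] = dE
    return grads
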