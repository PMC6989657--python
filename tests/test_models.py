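"""Forward-pass contracts of the w-CNN and ws-CNN against brute-force oracles."""

import numpy as np
import pytest

from phenocnn import models
from phenocnn.models import (
    ConvFilterGroup,
    conv_feature_map,
    forward,
    init_model,
    max_over_time,
    sentence_embed,
)


def _group(weights, bias, l):
    return ConvFilterGroup(
        filter_length=l,
        weights=np.asarray(weights, dtype=float),
        bias=np.asarray(bias, dtype=float),
    )


def _brute_conv(X, group):
    """Direct implementation of c_i = relu(w . x_{i:i+l-1} + b)."""
    L, _ = X.shape
    l = group.filter_length
    out = np.zeros((group.n_maps, L - l + 1))
    for m in range(group.n_maps):
        for i in range(L - l + 1):
            window = X[i : i + l].ravel()
            out[m, i] = max(0.0, float(window @ group.weights[m]) + group.bias[m])
    return out


class TestConvFeatureMap:
    def test_hand_example(self):
        X = np.array([[1.0], [2.0], [3.0]])
        g = _group([[1.0, 1.0]], [0.0], l=2)
        assert np.allclose(conv_feature_map(X, g), [[3.0, 5.0]])

    def test_zero_weights_zero_bias(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        g = _group(np.zeros((3, 8)), np.zeros(3), l=2)
        assert not conv_feature_map(X, g).any()

    def test_shape_contract(self, rng):
        X = rng.normal(size=(9, 5))
        g = _group(rng.normal(size=(7, 15)), rng.normal(size=7), l=3)
        assert conv_feature_map(X, g).shape == (7, 7)

    def test_too_short_input_rejected(self):
        g = _group(np.ones((1, 4)), [0.0], l=4)
        with pytest.raises(ValueError):
            conv_feature_map(np.ones((3, 1)), g)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(100):
            L = int(rng.integers(2, 10))
            d = int(rng.integers(1, 5))
            l = int(rng.integers(1, L + 1))
            n = int(rng.integers(1, 4))
            X = rng.normal(size=(L, d))
            g = _group(rng.normal(size=(n, l * d)), rng.normal(size=n), l)
            assert np.allclose(conv_feature_map(X, g), _brute_conv(X, g))


class TestMaxOverTime:
    def test_examples(self):
        assert max_over_time([[0.1, 0.5, 0.3]]) == pytest.approx([0.5])
        assert max_over_time([[2.0, 2.0, 2.0]]) == pytest.approx([2.0])

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            max_over_time(np.empty((3, 0)))

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            C = rng.normal(size=(int(rng.integers(1, 6)), int(rng.integers(1, 9))))
            expected = [max(row) for row in C]
            assert np.allclose(max_over_time(C), expected)


class TestSentenceEmbed:
    def test_average_and_sum(self):
        E = np.array([[[1.0, 0.0], [3.0, 2.0]]])
        assert np.allclose(sentence_embed(E, [2], "average"), [[2.0, 1.0]])
        assert np.allclose(sentence_embed(E, [2], "sum"), [[4.0, 2.0]])

    def test_padding_tokens_excluded(self, rng):
        body = rng.normal(size=(1, 3, 4))
        padded = np.concatenate([body, rng.normal(size=(1, 2, 4))], axis=1)
        assert np.allclose(
            sentence_embed(body, [3], "sum"), sentence_embed(padded, [3], "sum")
        )

    def test_all_padding_sentence_is_zero_row(self):
        E = np.ones((2, 3, 4))
        out = sentence_embed(E, [3, 0], "average")
        assert not out[1].any()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sentence_embed(np.ones((1, 1, 1)), [1], "median")


def _toy_model(rng, sent=False, seed=0):
    E = np.vstack([np.zeros(6), rng.normal(size=(9, 6))])
    E[2] = 0.0
    return init_model(
        E,
        word_filter_lengths=(1, 2),
        word_n_maps=4,
        sent_filter_lengths=(1, 2) if sent else (),
        sent_n_maps=3,
        pooling_mode="sum",
        seed=seed,
    )


class TestForward:
    def test_output_in_unit_interval(self, rng):
        m = _toy_model(rng)
        word = rng.integers(1, 10, size=12)
        assert 0.0 < forward(word, m) < 1.0

    def test_zero_output_layer_gives_half(self, rng):
        m = _toy_model(rng)
        m.w_out[:] = 0.0
        m.b_out = 0.0
        assert forward(rng.integers(1, 10, size=8), m) == pytest.approx(0.5)

    def test_deterministic_without_dropout(self, rng):
        m = _toy_model(rng)
        word = rng.integers(1, 10, size=10)
        assert forward(word, m) == forward(word, m)

    def test_feature_vector_length_conservation(self, rng):
        m = _toy_model(rng, sent=True)
        assert m.feature_size == 2 * 4 + 2 * 3 == len(m.w_out)

    def test_combined_requires_sentence_input(self, rng):
        m = _toy_model(rng, sent=True)
        with pytest.raises(ValueError):
            forward(rng.integers(1, 10, size=8), m)

    def test_zeroed_sentence_branch_reproduces_word_model(self, rng):
        """ws-CNN with silent sentence branch == w-CNN with the same word branch."""
        ws = _toy_model(rng, sent=True, seed=3)
        for g in ws.sent_groups:
            g.weights[:] = 0.0
            g.bias[:] = 0.0
        w = models.ModelParams(
            embedding=ws.embedding.copy(),
            word_groups=ws.word_groups,
            w_out=ws.w_out[: 2 * 4].copy(),
            b_out=ws.b_out,
        )
        word = rng.integers(1, 10, size=11)
        sent = rng.integers(1, 10, size=(4, 5))
        lengths = np.array([5, 3, 2, 0])
        p_ws = forward(word, ws, sentence_indices=sent, sentence_lengths=lengths)
        p_w = forward(word, w)
        assert p_ws == pytest.approx(p_w, abs=1e-6)

    def test_padding_suffix_cannot_raise_maxima(self, rng):
        """Constructed case: appended padding responses stay below the maxima.

        With unit-length filters, zero bias and zero padding embeddings every
        padding window responds relu(0) = 0, which never beats a positive
        real-token maximum, so pooled features are unchanged.
        """
        E = np.vstack([np.zeros(4), np.zeros((2, 4)), np.abs(rng.normal(size=(7, 4)))])
        m = init_model(E, word_filter_lengths=(1,), word_n_maps=5, seed=1)
        for g in m.word_groups:
            g.bias[:] = 0.0
            g.weights[:] = np.abs(g.weights)  # positive responses on real tokens
        word = rng.integers(3, 10, size=8)
        padded = np.concatenate([word, np.full(5, 2)])  # index 2 = padding
        assert forward(word, m) == pytest.approx(forward(padded, m), abs=1e-6)


def test_batch_forward_matches_single_forward(rng):
    """The vectorized training path agrees with the reference per-note forward."""
    m = _toy_model(rng, sent=True, seed=9)
    B, L, S, W = 5, 12, 4, 6
    word = rng.integers(1, 10, size=(B, L))
    sent = rng.integers(1, 10, size=(B, S, W))
    sl = rng.integers(0, W + 1, size=(B, S))
    sl[:, 0] = np.maximum(sl[:, 0], 1)
    p_batch, _ = models.batch_forward(m, word, sent, sl)
    for b in range(B):
        p_one = forward(word[b], m, sentence_indices=sent[b], sentence_lengths=sl[b])
        assert p_batch[b] == pytest.approx(p_one, abs=1e-5)


def test_checkpoint_round_trip(tmp_path, rng):
    m = _toy_model(rng, sent=True)
    path = tmp_path / "ckpt.json"
    m.save(path)
    back = models.ModelParams.load(path)
    word = rng.integers(1, 10, size=9)
    sent = rng.integers(1, 10, size=(3, 4))
    sl = np.array([4, 2, 0])
    assert forward(word, m, sent, sl) == pytest.approx(
        forward(word, back, sent, sl), abs=1e-7
    )
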