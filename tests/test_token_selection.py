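"""Zipf fitting, frequency/category filtering and the greedy category trace."""

from collections import Counter

import numpy as np
import pytest

from phenocnn.synthetic import CATEGORIES
from phenocnn.token_selection import (
    FrequencyTable,
    cumulative_fraction,
    filter_by_categories,
    frequency_filter,
    greedy_category_removal,
    information_content,
    required_sample_size,
    token_frequencies,
    zipf_fit,
)


def _table_from_freqs(freqs):
    """Rank table with prescribed (possibly non-integer) frequencies."""
    counts = {f"t{i}": float(f) for i, f in enumerate(freqs)}
    return FrequencyTable(counts=counts, tokens_by_rank=list(counts))


class TestTokenFrequencies:
    def test_counts_and_rank_order(self):
        table = token_frequencies([["a", "a", "b"]])
        assert table.counts == {"a": 2, "b": 1}
        assert table.tokens_by_rank == ["a", "b"]

    def test_ties_broken_by_first_appearance(self):
        table = token_frequencies([["x", "y", "x", "y", "z"]])
        assert table.tokens_by_rank == ["x", "y", "z"]

    def test_total_conserved(self, small_corpus):
        table = token_frequencies(small_corpus.notes)
        n_tokens = sum(len(s) for doc in small_corpus.notes for s in doc)
        assert table.total == n_tokens

    def test_sentence_structured_and_flat_agree(self):
        nested = [[["a", "b"], ["a"]]]
        flat = [["a", "b", "a"]]
        assert token_frequencies(nested).counts == token_frequencies(flat).counts


class TestZipfFit:
    def test_exact_power_law_recovered(self):
        freqs = 1e6 * np.arange(1, 2001, dtype=float) ** -1.0
        fit = zipf_fit(_table_from_freqs(freqs), 10, 1500)
        assert fit.alpha == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_frequencies_give_zero_exponent(self):
        fit = zipf_fit(_table_from_freqs([7.0] * 100), 10, 90)
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS fit equals the closed-form normal-equations solution."""
        for _ in range(20):
            n = int(rng.integers(10, 100))
            freqs = rng.integers(1, 10_000, size=n).astype(float)
            freqs = np.sort(freqs)[::-1]
            lo, hi = 2, n - 1
            fit = zipf_fit(_table_from_freqs(freqs), lo, hi)
            x = np.log10(np.arange(lo, hi + 1))
            y = np.log10(freqs[lo - 1 : hi])
            sxx = ((x - x.mean()) ** 2).sum()
            slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
            assert fit.alpha == pytest.approx(-slope, abs=1e-9)
            assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-9)

    def test_window_validation(self):
        table = _table_from_freqs([5.0, 4.0, 3.0])
        with pytest.raises(ValueError):
            zipf_fit(table, 1, 10)  # beyond table size
        with pytest.raises(ValueError):
            zipf_fit(table, 2, 2)


class TestCumulativeFraction:
    def test_hand_example(self):
        assert np.allclose(
            cumulative_fraction(_table_from_freqs([3.0, 1.0]), 1, 2), [0.75, 1.0]
        )

    def test_last_element_is_exactly_one(self, rng):
        for _ in range(100):
            freqs = np.sort(rng.integers(1, 500, size=int(rng.integers(2, 40))))[::-1]
            cum = cumulative_fraction(_table_from_freqs(freqs.astype(float)), 1, len(freqs))
            assert cum[-1] == 1.0
            assert (np.diff(cum) >= 0).all()


class TestFrequencyFilter:
    def test_hand_count(self):
        corpus = [["a", "b", "a"], ["a", "c"]]  # a:3, b:1, c:1
        filtered, removed, remaining = frequency_filter(corpus, theta=1)
        assert (removed, remaining) == (2, 1)
        assert filtered == [["a", "a"], ["a"]]

    def test_zero_threshold_removes_nothing(self, small_corpus):
        filtered, removed, remaining = frequency_filter(small_corpus.notes, 0)
        assert removed == 0
        assert filtered == small_corpus.notes

    def test_type_accounting_partitions(self, small_corpus):
        table = token_frequencies(small_corpus.notes)
        for theta in (1, 2, 5):
            _, removed, remaining = frequency_filter(small_corpus.notes, theta)
            assert removed + remaining == table.n_types

    def test_surviving_occurrences_conserved(self, small_corpus):
        """Filtering deletes whole types; surviving occurrences are untouched."""
        table = token_frequencies(small_corpus.notes)
        filtered, _, _ = frequency_filter(small_corpus.notes, 2)
        after = token_frequencies(filtered)
        for tok, c in after.counts.items():
            assert c == table.counts[tok]
            assert c > 2


class TestCategoryFilter:
    def test_keeping_all_is_identity(self, small_corpus):
        out = filter_by_categories(
            small_corpus.notes, small_corpus.category_map, CATEGORIES
        )
        assert out == small_corpus.notes

    def test_empty_kept_set_empties_documents(self, small_corpus):
        with pytest.warns(UserWarning):
            out = filter_by_categories(small_corpus.notes, small_corpus.category_map, ())
        assert all(not s for doc in out for s in doc)

    def test_token_counts_partition_across_categories(self, small_corpus):
        total = Counter(
            t for doc in small_corpus.notes for s in doc for t in s
        )
        per_cat = Counter()
        for cat in CATEGORIES:
            out = filter_by_categories(
                small_corpus.notes, small_corpus.category_map, {cat}
            )
            per_cat.update(t for doc in out for s in doc for t in s)
        assert per_cat == total

    def test_unknown_category_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            filter_by_categories(small_corpus.notes, small_corpus.category_map, {"x"})


class TestGreedyRemoval:
    def test_recovers_planted_importance(self):
        """Evaluator rewarding 'symptoms' keeps it to the end (rank 1)."""
        value = {c: 0.1 for c in CATEGORIES}
        value["symptoms"] = 1.0
        value["descriptions"] = 0.3

        def evaluator(kept):
            return sum(value[c] for c in kept)

        # removing the *least* valuable category maximizes the remaining sum,
        # so removal order is ascending in value and 'symptoms' survives
        trace = greedy_category_removal(evaluator, CATEGORIES)
        assert trace.ranks["symptoms"] == 1
        assert trace.ranks["descriptions"] == 2
        assert sorted(trace.ranks.values()) == list(range(1, 8))

    def test_pure_noise_category_removed_first(self):
        def evaluator(kept):
            return 0.9 - 0.5 * ("others" in kept)  # 'others' actively hurts

        trace = greedy_category_removal(evaluator, ("symptoms", "others"))
        assert trace.removed_order == ["others"]
        assert trace.ranks == {"symptoms": 1, "others": 2}

    def test_tie_break_by_name_order(self):
        trace = greedy_category_removal(lambda kept: 0.5, ("b", "a", "c"))
        assert trace.removed_order == ["a", "b"]

    def test_needs_two_categories(self):
        with pytest.raises(ValueError):
            greedy_category_removal(lambda kept: 0.0, ("solo",))


class TestInformationContent:
    def test_psi_formula(self):
        assert information_content(1000, 0.01).psi == pytest.approx(10.0)

    def test_required_sample_size_identity_and_scaling(self):
        assert required_sample_size(1000, 0.02, 0.02) == 1000
        assert required_sample_size(1000, 0.02, 0.01) == 2000

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            information_content(10, 0.0)
        with pytest.raises(ValueError):
            required_sample_size(10, 0.01, 0.0)
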