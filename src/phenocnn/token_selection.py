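"""Token-level data-quality analyses: Zipf statistics and token selection.

Clinical-note token frequencies follow a rank-frequency power law
``f(r) ~ r^-alpha`` (Zipf's law), which motivates two explainability-oriented
token-selection mechanisms:

* **frequency filtering** — drop every token *type* occurring at most
  ``theta`` times (singletons at theta = 1 cannot help a classifier
  generalize: they appear in the train or the test split, never both);
* **greedy category prioritization** — tokens carry one of seven semantic
  categories (symptoms, descriptions, medicine, body, numbers, verbs,
  others); categories are removed one at a time, always the one whose
  removal best preserves classifier performance, yielding an importance
  ranking (rank 1 = survives longest = most important).

The information-content metric ``psi = N x p_t`` combines sample size N with
the fraction of informative tokens p_t; matching a reference information
level N' x p_t' requires N = N' * (p_t' / p_t) samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import CATEGORIES

__all__ = [
    "FrequencyTable",
    "ZipfFit",
    "GreedyTrace",
    "InfoContent",
    "token_frequencies",
    "zipf_fit",
    "cumulative_fraction",
    "frequency_filter",
    "filter_by_categories",
    "greedy_category_removal",
    "information_content",
    "required_sample_size",
]


def _iter_tokens(doc):
    for item in doc:
        if isinstance(item, str):
            yield item
        else:
            yield from item


def _map_document(doc, keep):
    """Rebuild a (possibly sentence-structured) document keeping some tokens."""
    if doc and not isinstance(doc[0], str):
        return [[t for t in sent if keep(t)] for sent in doc]
    return [t for t in doc if keep(t)]


@dataclass
class FrequencyTable:
    """Corpus token counts with a descending-frequency rank order.

    Ties are broken by first appearance in the corpus, so the rank order is
    deterministic for a fixed corpus.
    """

    counts: dict = field(default_factory=dict)
    tokens_by_rank: list = field(default_factory=list)

    @property
    def n_types(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency_of_rank(self, rank: int) -> int:
        return self.counts[self.tokens_by_rank[rank - 1]]

    def frequencies(self) -> np.ndarray:
        return np.array([self.counts[t] for t in self.tokens_by_rank], dtype=float)

    def n_singletons(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)


def token_frequencies(corpus) -> FrequencyTable:
    """Exact token-type counts over a (possibly sentence-structured) corpus."""
    counts: dict = {}
    for doc in corpus:
        for tok in _iter_tokens(doc):
            counts[tok] = counts.get(tok, 0) + 1
    order = sorted(counts, key=lambda t: -counts[t])  # stable: ties keep insertion
    return FrequencyTable(counts=counts, tokens_by_rank=order)


@dataclass(frozen=True)
class ZipfFit:
    rank_lo: int
    rank_hi: int
    alpha: float
    intercept: float  # log10 scale
    r_squared: float


def zipf_fit(table: FrequencyTable, rank_lo: int = 10, rank_hi: int = 1500) -> ZipfFit:
    """OLS of log10(frequency) on log10(rank) over the closed rank window.

    The fitted exponent is ``alpha = -slope``; the default window (ranks
    10-1500) avoids the flattened head and the noisy singleton tail of
    typical rank-frequency curves.
    """
    if not 1 <= rank_lo < rank_hi:
        raise ValueError("need 1 <= rank_lo < rank_hi")
    if rank_hi > table.n_types:
        raise ValueError(
            f"rank_hi={rank_hi} exceeds table size {table.n_types}"
        )
    ranks = np.arange(rank_lo, rank_hi + 1, dtype=float)
    if len(ranks) < 3:
        raise ValueError("fit window must contain at least 3 ranks")
    freqs = table.frequencies()[rank_lo - 1 : rank_hi]
    x, y = np.log10(ranks), np.log10(freqs)
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return ZipfFit(
        rank_lo=rank_lo,
        rank_hi=rank_hi,
        alpha=float(-slope),
        intercept=float(intercept),
        r_squared=r2,
    )


def cumulative_fraction(
    table: FrequencyTable, rank_lo: int, rank_hi: int
) -> np.ndarray:
    """Relative cumulative sum of the window's frequencies (ends at 1.0)."""
    if not 1 <= rank_lo <= rank_hi <= table.n_types:
        raise ValueError("invalid rank window")
    freqs = table.frequencies()[rank_lo - 1 : rank_hi]
    cum = np.cumsum(freqs)
    return cum / cum[-1]


def frequency_filter(corpus, theta: int, table: FrequencyTable | None = None):
    """Drop token types with corpus frequency <= theta from every document.

    Occurrences are deleted (sequences shorten), not mapped to ``unk``.
    Returns ``(filtered_corpus, n_removed_types, n_remaining_types)``.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    table = table or token_frequencies(corpus)
    removed = {t for t, c in table.counts.items() if c <= theta}
    keep = lambda t: t not in removed
    filtered = [_map_document(doc, keep) for doc in corpus]
    return filtered, len(removed), table.n_types - len(removed)


def filter_by_categories(corpus, category_map: dict, kept) -> list:
    """Keep only tokens whose category is in *kept* (occurrence-conserving)."""
    kept = set(kept)
    unknown = kept - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if not kept:
        warnings.warn("empty kept set: all documents will be empty", stacklevel=2)

    def keep(tok):
        try:
            return category_map[tok] in kept
        except KeyError:
            raise KeyError(f"token {tok!r} missing from category map") from None

    return [_map_document(doc, keep) for doc in corpus]


@dataclass
class GreedyTrace:
    categories: tuple
    baseline: float  # performance with every category kept
    removed_order: list  # categories in removal order
    performances: list  # performance after each removal
    ranks: dict  # category -> rank; 1 = most important (never removed)


def greedy_category_removal(
    evaluator,
    categories=CATEGORIES,
    n_removals: int | None = None,
) -> GreedyTrace:
    """Remove categories greedily, keeping the performance as high as possible.

    *evaluator* maps a kept-category frozenset to a scalar performance.  At
    each step the category whose removal maximizes the evaluator is removed
    (ties broken by category name order).  By default K - 1 removals are
    made; the survivor gets rank 1 and the category removed at step s gets
    rank K + 1 - s.
    """
    categories = tuple(categories)
    K = len(categories)
    if K < 2:
        raise ValueError("need at least two categories")
    steps = K - 1 if n_removals is None else n_removals
    if not 1 <= steps <= K - 1:
        raise ValueError("n_removals must be in [1, K-1]")

    kept = set(categories)
    baseline = float(evaluator(frozenset(kept)))
    removed_order, performances = [], []
    for _ in range(steps):
        best_cat, best_perf = None, -math.inf
        for cat in sorted(kept):
            perf = float(evaluator(frozenset(kept - {cat})))
            if perf > best_perf:
                best_cat, best_perf = cat, perf
        kept.remove(best_cat)
        removed_order.append(best_cat)
        performances.append(best_perf)

    ranks = {cat: K + 1 - (s + 1) for s, cat in enumerate(removed_order)}
    # survivors are the most important; with the default full trace there is
    # exactly one, receiving rank 1 (partial traces tie-break by name order)
    for r, cat in enumerate(sorted(kept), start=1):
        ranks[cat] = r
    return GreedyTrace(
        categories=categories,
        baseline=baseline,
        removed_order=removed_order,
        performances=performances,
        ranks=ranks,
    )


@dataclass(frozen=True)
class InfoContent:
    """psi = N x p_t: sample size times informative-token fraction."""

    N: int
    p_t: float
    psi: float


def information_content(N: int, p_t: float) -> InfoContent:
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 < p_t <= 1:
        raise ValueError("p_t must lie in (0, 1]")
    return InfoContent(N=N, p_t=p_t, psi=N * p_t)


def required_sample_size(N_prime: int, p_t_prime: float, p_t: float) -> int:
    """Samples needed to match information content N' x p_t' at fraction p_t."""
    if p_t <= 0 or p_t_prime <= 0:
        raise ValueError("token fractions must be positive")
    return math.ceil(N_prime * p_t_prime / p_t)
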