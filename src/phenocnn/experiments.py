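"""Standard synthetic benchmarks tying the whole stack together.

These are the canned experiments the acceptance suite and the acceptance
script run: each generates a synthetic corpus with known ground truth,
executes the full pipeline (encode -> train -> cross-validate), and returns
the summary quantities.  Problem sizes are deliberately desk-scale — notes
of roughly ten short sentences, corpora of a few hundred notes — so a full
run finishes on one CPU in minutes; docs/methods.md discusses what these
scales do and do not demonstrate.

All randomness fans out from a single integer seed per experiment.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .classifiers import WordCNNClassifier, WordSentenceCNNClassifier, encode_corpus
from .evaluation import CVSummary, LearningCurve, compute_metrics, cross_validate, learning_curve
from .synthetic import CATEGORIES, GeneratorConfig, generate_corpus, permute_labels
from .token_selection import (
    filter_by_categories,
    frequency_filter,
    greedy_category_removal,
    token_frequencies,
    zipf_fit,
)

__all__ = [
    "classification_config",
    "strong_signal_cv",
    "permuted_label_aurocs",
    "balance_comparison",
    "learning_curve_experiment",
    "frequency_filter_stability",
    "greedy_recovery",
    "zipf_recovery",
]


def classification_config(
    n_notes: int = 500,
    seed: int = 0,
    prevalence: float = 0.3,
    signal_rate: float = 0.25,
    signal_tokens: int = 3,
    singleton_rate: float = 0.01,
    vocab_size: int = 2000,
) -> GeneratorConfig:
    """Single-phenotype benchmark corpus: short notes with a clear token signal."""
    return GeneratorConfig(
        n_notes=n_notes,
        n_phenotypes=1,
        vocab_size=vocab_size,
        zipf_alpha=0.97,
        signal_tokens_per_phenotype=signal_tokens,
        signal_rate=signal_rate,
        sentences_per_note=(5, 9),
        words_per_sentence=(4, 9),
        label_prevalences=(prevalence,),
        singleton_rate=singleton_rate,
        seed=seed,
    )


def _word_classifier(seed: int, **overrides) -> WordCNNClassifier:
    kwargs = dict(filter_lengths=(1, 2, 3, 4), n_maps=100, random_state=seed)
    kwargs.update(overrides)
    return WordCNNClassifier(**kwargs)


def _encode(corpus):
    X, _ = encode_corpus(corpus.notes)
    return X, corpus.labels[:, 0].astype(int)


def strong_signal_cv(
    model: str = "word", n_notes: int = 500, seed: int = 0, k: int = 10
) -> CVSummary:
    """10-fold CV of the w-CNN or ws-CNN on a strong-signal corpus."""
    corpus = generate_corpus(classification_config(n_notes=n_notes, seed=seed))
    X, y = _encode(corpus)
    if model == "word":
        est = _word_classifier(seed)
    elif model == "ws":
        est = WordSentenceCNNClassifier(
            word_filter_lengths=(1, 2, 3, 4),
            word_n_maps=100,
            sentence_filter_lengths=(1, 5, 7, 9),
            sentence_n_maps=50,
            pooling_mode="average",
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    return cross_validate(est, X, y, k=k, seed=seed)


def permuted_label_aurocs(
    n_seeds: int = 5, n_notes: int = 500, base_seed: int = 0, k: int = 10
) -> list[float]:
    """Null check: mean CV AUROC per seed after jointly permuting label rows."""
    out = []
    for s in range(n_seeds):
        seed = base_seed + s
        corpus = generate_corpus(classification_config(n_notes=n_notes, seed=seed))
        corpus = permute_labels(corpus, seed=seed + 10_000)
        X, y = _encode(corpus)
        summary = cross_validate(_word_classifier(seed), X, y, k=k, seed=seed)
        out.append(summary.mean("auroc"))
    return out


def balance_comparison(
    n_notes: int = 400, seed: int = 0, k: int = 10
) -> dict:
    """Minority-class recall with and without 1/n_c loss weighting.

    Prevalence 0.1 and a weak per-sentence signal make the unweighted model
    drift toward the majority class; the comparison reports the CV recall of
    both variants on identical folds.
    """
    cfg = classification_config(
        n_notes=n_notes, seed=seed, prevalence=0.1, signal_rate=0.1, signal_tokens=2
    )
    corpus = generate_corpus(cfg)
    X, y = _encode(corpus)
    balanced = cross_validate(
        _word_classifier(seed, class_weighting=True), X, y, k=k, seed=seed
    )
    unbalanced = cross_validate(
        _word_classifier(seed, class_weighting=False), X, y, k=k, seed=seed
    )
    return {
        "balanced": balanced,
        "unbalanced": unbalanced,
        "recall_balanced": balanced.mean("recall"),
        "recall_unbalanced": unbalanced.mean("recall"),
    }


def learning_curve_experiment(
    fractions=(0.1, 1.0), n_notes: int = 500, seed: int = 0, k: int = 10
) -> LearningCurve:
    corpus = generate_corpus(classification_config(n_notes=n_notes, seed=seed))
    X, y = _encode(corpus)
    return learning_curve(_word_classifier(seed), X, y, fractions, k=k, seed=seed)


def frequency_filter_stability(
    n_notes: int = 500, seed: int = 0, k: int = 10, theta: int = 1
) -> dict:
    """F1 before and after removing tokens of frequency <= theta.

    Singletons carry no generalizable information, so the filtered corpus
    should perform indistinguishably (within 2 SE) from the full one.
    """
    cfg = classification_config(n_notes=n_notes, seed=seed, singleton_rate=0.02)
    corpus = generate_corpus(cfg)
    X, y = _encode(corpus)
    baseline = cross_validate(_word_classifier(seed), X, y, k=k, seed=seed)

    filtered_docs, n_removed, n_remaining = frequency_filter(corpus.notes, theta)
    Xf, _ = encode_corpus(filtered_docs)
    filtered = cross_validate(_word_classifier(seed), Xf, y, k=k, seed=seed)
    return {
        "baseline": baseline,
        "filtered": filtered,
        "n_removed_types": n_removed,
        "n_remaining_types": n_remaining,
        "f1_change": filtered.mean("f1") - baseline.mean("f1"),
        "f1_se": baseline.se("f1"),
    }


def _holdout_f1_evaluator(corpus, y, seed: int):
    """Evaluator for the greedy trace: holdout F1 of a light w-CNN.

    Re-encodes the category-filtered corpus, trains a reduced classifier
    (two filter groups, 50 maps, 8 epochs) on a stratified 70/30 split and
    scores F1 on the holdout.  Lighter than full CV but the same pipeline.
    """

    def evaluate(kept: frozenset) -> float:
        docs = filter_by_categories(corpus.notes, corpus.category_map, kept)
        X, _ = encode_corpus(docs)
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=0.3, stratify=y, random_state=seed
        )
        est = _word_classifier(seed, filter_lengths=(1, 2), n_maps=50, epochs=8)
        est.fit(X[idx_train], y[idx_train])
        scores = est.predict_proba(X[idx_test])[:, 1]
        return compute_metrics(scores, y[idx_test]).f1

    return evaluate


def greedy_recovery(n_seeds: int = 5, n_notes: int = 240, base_seed: int = 0) -> dict:
    """How often the greedy trace ranks the true signal category first.

    The generator plants all signal tokens in one category ("symptoms"), so
    a correct trace must remove that category last.
    """
    ranks, successes = [], 0
    for s in range(n_seeds):
        seed = base_seed + s
        corpus = generate_corpus(classification_config(n_notes=n_notes, seed=seed))
        y = corpus.labels[:, 0].astype(int)
        trace = greedy_category_removal(
            _holdout_f1_evaluator(corpus, y, seed), CATEGORIES
        )
        signal_rank = trace.ranks[corpus.config.signal_category]
        ranks.append(signal_rank)
        successes += signal_rank == 1
    return {"signal_ranks": ranks, "n_rank_one": successes, "n_seeds": n_seeds}


def zipf_recovery(
    alpha: float = 0.97,
    n_notes: int = 500,
    seed: int = 0,
    rank_window=(10, 1500),
) -> float:
    """Fit the rank-frequency exponent of a generated corpus (~1e6 draws)."""
    cfg = GeneratorConfig(
        n_notes=n_notes,
        n_phenotypes=1,
        vocab_size=48_848,
        zipf_alpha=alpha,
        signal_tokens_per_phenotype=1,
        signal_rate=0.0,
        sentences_per_note=(200, 250),
        words_per_sentence=(5, 13),
        label_prevalences=(0.3,),
        singleton_rate=0.0,
        seed=seed,
    )
    corpus = generate_corpus(cfg)
    table = token_frequencies(corpus.notes)
    return zipf_fit(table, *rank_window).alpha
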