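"""Synthetic clinical-note corpora with controlled statistical structure.

Real discharge-summary corpora are access-controlled, so every analysis in
this package is exercised on generated notes that reproduce the statistical
features the analyses rely on:

* a Zipf-distributed background vocabulary (rank-frequency ``f(r) ~ r^-alpha``),
* documents made of many short sentences (around nine words each),
* once-only "noise" tokens emulating spelling errors and stray number strings,
* a handful of phenotype-specific *signal tokens*, tagged with a semantic
  category, emitted only in positive notes,
* independent multi-label phenotype assignment with uneven prevalences.

Defaults mirror the scale of the benchmark annotation set this package
targets: 1,610 notes, 10 phenotypes, ~48.8k background types, alpha = 0.97,
~200 sentences per note.  Tests and benchmarks pass smaller explicit configs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CATEGORIES",
    "GeneratorConfig",
    "SyntheticCorpus",
    "generate_corpus",
    "permute_labels",
]

#: the seven semantic token categories used by category prioritization
CATEGORIES = (
    "symptoms",
    "descriptions",
    "medicine",
    "body",
    "numbers",
    "verbs",
    "others",
)



@dataclass(frozen=True)
class GeneratorConfig:
    n_notes: int = 1610
    n_phenotypes: int = 10
    vocab_size: int = 48848
    zipf_alpha: float = 0.97
    signal_tokens_per_phenotype: int = 20
    signal_category: str = "symptoms"
    signal_rate: float = 0.05
    sentences_per_note: tuple[int, int] = (100, 300)
    words_per_sentence: tuple[int, int] = (5, 13)
    label_prevalences: tuple[float, ...] | float | None = None
    singleton_rate: float = 0.006
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")
        if self.n_notes < 2:
            raise ValueError("n_notes must be >= 2 (corpora must be splittable)")
        if self.n_phenotypes < 1 or self.signal_tokens_per_phenotype < 1:
            raise ValueError("counts must be >= 1")
        if self.zipf_alpha <= 0:
            raise ValueError("zipf_alpha must be positive")
        prevs = self.label_prevalences
        if prevs is None:
            # uneven class sizes spanning the benchmark's prevalence range
            prevs = tuple(
                np.round(np.linspace(0.29, 0.08, self.n_phenotypes), 3)
            )
            object.__setattr__(self, "label_prevalences", prevs)
        elif np.isscalar(prevs):
            prevs = (float(prevs),) * self.n_phenotypes
            object.__setattr__(self, "label_prevalences", prevs)
        if len(prevs) != self.n_phenotypes:
            raise ValueError("label_prevalences length must equal n_phenotypes")
        for p in (*prevs, self.signal_rate, self.singleton_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.sentences_per_note, self.words_per_sentence):
            if not 1 <= lo <= hi:
                raise ValueError("integer ranges must satisfy 1 <= lo <= hi")
        if self.signal_category not in CATEGORIES:
            raise ValueError(f"unknown category {self.signal_category!r}")


@dataclass
class SyntheticCorpus:
    """Generated notes plus the ground truth behind them."""

    notes: list  # list of documents; document = list of sentences (token lists)
    labels: np.ndarray  # (n_notes, n_phenotypes) binary
    category_map: dict  # token -> category
    truth: dict  # phenotype index -> set of its signal tokens
    phenotype_names: list
    config: GeneratorConfig | None = None
    n_singletons_emitted: int = 0

    def __len__(self) -> int:
        return len(self.notes)

    def texts(self) -> list:
        """Notes rendered as raw text, sentences joined by ' . '."""
        return [" . ".join(" ".join(s) for s in doc) + " ." for doc in self.notes]

    def flat_tokens(self, i: int) -> list:
        return [tok for sent in self.notes[i] for tok in sent]

    # -- disk round trip -------------------------------------------------
    def write(self, notes_path, labels_path) -> None:
        with open(notes_path, "w", encoding="utf-8") as fh:
            for i, doc in enumerate(self.notes):
                rec = {
                    "id": i,
                    "text": " . ".join(" ".join(s) for s in doc) + " .",
                    "sentences": doc,
                }
                fh.write(json.dumps(rec) + "\n")
        with open(labels_path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["note_id", *self.phenotype_names])
            for i, row in enumerate(self.labels):
                writer.writerow([i, *row.tolist()])

    @classmethod
    def read(cls, notes_path, labels_path) -> "SyntheticCorpus":
        notes = []
        with open(notes_path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    notes.append(json.loads(line)["sentences"])
        with open(labels_path, encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            rows = [[int(v) for v in row[1:]] for row in reader if row]
        return cls(
            notes=notes,
            labels=np.asarray(rows, dtype=np.int8),
            category_map={},
            truth={},
            phenotype_names=header[1:],
        )

    def write_category_map(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok, cat in self.category_map.items():
                fh.write(f"{tok}\t{cat}\n")


def zipf_probabilities(vocab_size: int, alpha: float) -> np.ndarray:
    """Normalized rank-frequency law p(r) ~ r^-alpha over ranks 1..vocab_size."""
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks**-alpha
    return p / p.sum()


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Draw a corpus from the generative model described in the module docs.

    Background tokens are sampled by inverse-CDF lookup over the fixed rank
    table (exact control of the exponent, rejection-free); every draw is
    routed through one :class:`numpy.random.Generator` so a seed pins the
    corpus byte-for-byte.
    """
    rng = np.random.default_rng(config.seed)
    P = config.n_phenotypes
    background = [f"w{r}" for r in range(1, config.vocab_size + 1)]
    cdf = np.cumsum(zipf_probabilities(config.vocab_size, config.zipf_alpha))
    cdf[-1] = 1.0

    phenotype_names = [f"phenotype_{p}" for p in range(P)]
    truth = {
        p: {f"sig{p}_{j}" for j in range(config.signal_tokens_per_phenotype)}
        for p in range(P)
    }
    category_map = {
        tok: CATEGORIES[r % len(CATEGORIES)] for r, tok in enumerate(background)
    }
    for toks in truth.values():
        for tok in toks:
            category_map[tok] = config.signal_category

    prevs = np.asarray(config.label_prevalences, dtype=float)
    labels = (rng.random((config.n_notes, P)) < prevs).astype(np.int8)

    signal_lists = {p: sorted(truth[p]) for p in range(P)}
    n_singletons = 0
    notes = []
    for i in range(config.n_notes):
        lo, hi = config.sentences_per_note
        n_sent = int(rng.integers(lo, hi + 1))
        wlo, whi = config.words_per_sentence
        sent_lens = rng.integers(wlo, whi + 1, size=n_sent)
        total = int(sent_lens.sum())
        draws = np.searchsorted(cdf, rng.random(total), side="left")
        singleton_mask = rng.random(total) < config.singleton_rate
        positives = np.nonzero(labels[i])[0]

        doc = []
        pos = 0
        for L in sent_lens:
            sent = []
            for j in range(pos, pos + int(L)):
                if singleton_mask[j]:
                    tok = f"noise_{n_singletons}_{rng.integers(1 << 32):08x}"
                    n_singletons += 1
                    category_map[tok] = "others"
                    sent.append(tok)
                else:
                    sent.append(background[draws[j]])
            pos += int(L)
            for p in positives:
                for tok in signal_lists[p]:
                    if rng.random() < config.signal_rate:
                        sent.insert(int(rng.integers(len(sent) + 1)), tok)
            doc.append(sent)
        notes.append(doc)

    return SyntheticCorpus(
        notes=notes,
        labels=labels,
        category_map=category_map,
        truth=truth,
        phenotype_names=phenotype_names,
        config=config,
        n_singletons_emitted=n_singletons,
    )


def permute_labels(corpus: SyntheticCorpus, seed: int | None) -> SyntheticCorpus:
    """Null model: permute label *rows* jointly across phenotypes.

    ``seed=None`` is the documented identity sentinel (notes and labels
    returned unchanged, as a copy); any integer seeds the permutation.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if seed is None:
        perm = np.arange(len(corpus))
    else:
        perm = np.random.default_rng(seed).permutation(len(corpus))
    return replace_labels(corpus, corpus.labels[perm])


def replace_labels(corpus: SyntheticCorpus, labels: np.ndarray) -> SyntheticCorpus:
    out = SyntheticCorpus(
        notes=corpus.notes,
        labels=np.asarray(labels),
        category_map=corpus.category_map,
        truth=corpus.truth,
        phenotype_names=corpus.phenotype_names,
        config=corpus.config,
        n_singletons_emitted=corpus.n_singletons_emitted,
    )
    return out
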