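"""Text preprocessing for clinical notes.

Free-text discharge notes are turned into fixed-shape integer inputs in four
steps: *cleansing* (drop characters outside a small kept set), *tokenization*
(whitespace split with kept punctuation emitted as separate tokens), optional
*sentence segmentation* (periods always break; commas break only after long
spans), and *indexing + padding* against a first-appearance vocabulary with
two reserved entries (``unk`` = 1, ``padding`` = 2).

Indices are 1-based by contract; embedding tables allocate a dummy row 0 so
that token index ``i`` addresses row ``i`` directly.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UNK_INDEX",
    "PAD_INDEX",
    "UNK_TOKEN",
    "PAD_TOKEN",
    "DEFAULT_KEPT_PUNCT",
    "Vocabulary",
    "Note",
    "SentenceNote",
    "cleanse",
    "tokenize",
    "segment_sentences",
    "build_vocabulary",
    "index_and_pad_words",
    "index_and_pad_sentences",
]

UNK_INDEX = 1
PAD_INDEX = 2
UNK_TOKEN = "unk"
PAD_TOKEN = "padding"

#: punctuation characters kept by cleansing and emitted as standalone tokens
DEFAULT_KEPT_PUNCT = ",()!?'."


@dataclass
class Vocabulary:
    """Token <-> 1-based index map with reserved ``unk``/``padding`` entries.

    Real tokens are numbered from 3 upward in order of first appearance.
    ``case_sensitive=False`` lower-cases every token before lookup/insertion.
    """

    case_sensitive: bool = True
    _token_to_index: dict[str, int] = field(default_factory=dict)
    _index_to_token: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self._token_to_index:
            self._token_to_index = {UNK_TOKEN: UNK_INDEX, PAD_TOKEN: PAD_INDEX}
            self._index_to_token = [UNK_TOKEN, PAD_TOKEN]

    def _key(self, token: str) -> str:
        return token if self.case_sensitive else token.lower()

    def add(self, token: str) -> int:
        key = self._key(token)
        idx = self._token_to_index.get(key)
        if idx is None:
            idx = len(self._index_to_token) + 1
            self._token_to_index[key] = idx
            self._index_to_token.append(key)
        return idx

    def index(self, token: str) -> int:
        """Index of *token*, or ``UNK_INDEX`` for out-of-vocabulary tokens."""
        return self._token_to_index.get(self._key(token), UNK_INDEX)

    def token(self, index: int) -> str:
        if not 1 <= index <= len(self._index_to_token):
            raise KeyError(index)
        return self._index_to_token[index - 1]

    def __len__(self) -> int:
        return len(self._index_to_token)

    def __contains__(self, token: str) -> bool:
        return self._key(token) in self._token_to_index

    @property
    def tokens(self) -> list[str]:
        """All tokens in index order, reserved entries first."""
        return list(self._index_to_token)

    def real_tokens(self) -> list[str]:
        return self._index_to_token[2:]

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, tok in enumerate(self._index_to_token, start=1):
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def from_tsv(cls, path, case_sensitive: bool = True) -> "Vocabulary":
        vocab = cls(case_sensitive=case_sensitive)
        entries: list[tuple[str, int]] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                tok, idx = line.rstrip("\n").split("\t")
                entries.append((tok, int(idx)))
        entries.sort(key=lambda e: e[1])
        for tok, idx in entries:
            if idx in (UNK_INDEX, PAD_INDEX):
                continue
            got = vocab.add(tok)
            if got != idx:
                raise ValueError(f"non-contiguous vocabulary file at {tok!r}")
        return vocab


@dataclass
class Note:
    """A document as a padded 1-based token-index vector."""

    indices: np.ndarray  # shape (L_max,), int
    true_length: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)


@dataclass
class SentenceNote:
    """A document as an S_max x W_max padded index matrix."""

    indices: np.ndarray  # shape (S_max, W_max), int
    sentence_lengths: np.ndarray  # shape (S_max,), int; 0 for padding sentences
    n_sentences: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.sentence_lengths = np.asarray(self.sentence_lengths, dtype=np.int64)


def cleanse(text: str, kept_punct: str = DEFAULT_KEPT_PUNCT) -> str:
    """Replace every character outside the kept set by a space and collapse.

    The kept set is ASCII letters, digits, space, and *kept_punct*. Runs of
    removed characters and spaces collapse to one space; the result is
    stripped. The Unicode prime often seen in place of an apostrophe is
    normalized to ``'`` first.
    """
    text = text.replace("′", "'").replace("’", "'")
    pattern = "[^A-Za-z0-9 " + re.escape(kept_punct) + "]"
    text = re.sub(pattern, " ", text)
    return re.sub(r" {2,}", " ", text).strip()


def tokenize(clean_text: str, kept_punct: str = DEFAULT_KEPT_PUNCT) -> list[str]:
    """Split cleansed text into tokens; kept punctuation becomes its own token."""
    if not clean_text:
        return []
    spaced = re.sub("([" + re.escape(kept_punct) + "])", r" \1 ", clean_text)
    return spaced.split()


def segment_sentences(
    clean_text: str,
    min_comma_span: int = 5,
    kept_punct: str = DEFAULT_KEPT_PUNCT,
) -> list[list[str]]:
    """Segment cleansed text into sentences (lists of tokens).

    A period always ends a sentence. A comma ends one only when strictly more
    than *min_comma_span* tokens have accumulated since the previous boundary
    (clinical notes use long comma-spliced runs as de-facto sentences).
    Boundary characters are dropped from the emitted sequences; empty
    segments are discarded.
    """
    sentences: list[list[str]] = []
    current: list[str] = []
    for tok in tokenize(clean_text, kept_punct=kept_punct):
        if tok == ".":
            if current:
                sentences.append(current)
            current = []
        elif tok == ",":
            if len(current) > min_comma_span:
                sentences.append(current)
                current = []
            # short span: comma is not a boundary and is not kept as a token
        else:
            current.append(tok)
    if current:
        sentences.append(current)
    return sentences


def build_vocabulary(corpus, case_sensitive: bool = True) -> Vocabulary:
    """Build a first-appearance-ordered vocabulary from token sequences.

    *corpus* is an iterable of token sequences (or of sentence-structured
    documents, which are flattened).
    """
    vocab = Vocabulary(case_sensitive=case_sensitive)
    empty = True
    for doc in corpus:
        for item in doc:
            if isinstance(item, str):
                vocab.add(item)
                empty = False
            else:  # sentence-structured document
                for tok in item:
                    vocab.add(tok)
                    empty = False
    if empty:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return vocab


def _fit_length(tokens: list, limit: int, policy: str, what: str) -> list:
    if len(tokens) <= limit:
        return tokens
    if policy == "truncate":
        warnings.warn(
            f"{what} of length {len(tokens)} truncated to {limit}", stacklevel=3
        )
        return tokens[:limit]
    raise ValueError(
        f"{what} has {len(tokens)} items but the maximum is {limit} "
        "(pass overflow='truncate' to tail-truncate)"
    )


def index_and_pad_words(
    tokens: list[str],
    vocab: Vocabulary,
    L_max: int,
    overflow: str = "error",
) -> Note:
    """Map tokens to indices and right-pad with ``PAD_INDEX`` to *L_max*."""
    tokens = _fit_length(list(tokens), L_max, overflow, "note")
    indices = np.full(L_max, PAD_INDEX, dtype=np.int64)
    for i, tok in enumerate(tokens):
        indices[i] = vocab.index(tok)
    return Note(indices=indices, true_length=len(tokens))


def index_and_pad_sentences(
    sentences: list[list[str]],
    vocab: Vocabulary,
    W_max: int,
    S_max: int,
    overflow: str = "error",
) -> SentenceNote:
    """Two-dimensional padding: each sentence to *W_max*, the note to *S_max*."""
    sentences = _fit_length(list(sentences), S_max, overflow, "note (sentences)")
    mat = np.full((S_max, W_max), PAD_INDEX, dtype=np.int64)
    lengths = np.zeros(S_max, dtype=np.int64)
    for s, sent in enumerate(sentences):
        sent = _fit_length(list(sent), W_max, overflow, "sentence")
        lengths[s] = len(sent)
        for j, tok in enumerate(sent):
            mat[s, j] = vocab.index(tok)
    return SentenceNote(
        indices=mat, sentence_lengths=lengths, n_sentences=len(sentences)
    )


def notes_to_jsonl(notes, path) -> None:
    """Serialize indexed notes as JSONL (id, indices, sentence data)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, item in enumerate(notes):
            rec = {"id": i}
            if isinstance(item, tuple):
                note, snote = item
            elif isinstance(item, Note):
                note, snote = item, None
            else:
                note, snote = None, item
            if note is not None:
                rec["indices"] = note.indices.tolist()
                rec["true_length"] = note.true_length
            if snote is not None:
                rec["sentence_indices"] = snote.indices.tolist()
                rec["sentence_lengths"] = snote.sentence_lengths.tolist()
                rec["n_sentences"] = snote.n_sentences
            fh.write(json.dumps(rec) + "\n")
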