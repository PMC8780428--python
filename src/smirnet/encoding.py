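"""Character vocabularies and one-hot encoding for the sequence autoencoder.

A vocabulary is the domain alphabet (observed or fixed) plus three reserved
symbols appended last: pad, start-of-sequence, and end-of-sequence.  The
reserved symbols use characters outside both biological alphabets so they
can never collide with data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import MIRNA_ALPHABET, SequenceRecord

PAD = "\x00"
START = "\x02"
END = "\x03"


class UnknownCharacterError(ValueError):
    """A string contains a character outside the vocabulary."""


class LengthError(ValueError):
    """A string exceeds the vocabulary's maximum length."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered character set with reserved pad/start/end symbols.

    ``chars`` lists the domain alphabet first (deterministically sorted)
    followed by the three reserved symbols; ``index`` is the inverse map.
    """

    chars: tuple[str, ...]
    max_len: int
    index: dict[str, int] = field(compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.chars)) != len(self.chars):
            raise ValueError("vocabulary characters must be unique")
        for special in (PAD, START, END):
            if special not in self.chars:
                raise ValueError("vocabulary must contain pad/start/end symbols")
        if self.max_len <= 0:
            raise ValueError("max_len must be positive")
        object.__setattr__(self, "index", {c: i for i, c in enumerate(self.chars)})

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def pad_char(self) -> str:
        return PAD

    @property
    def start_char(self) -> str:
        return START

    @property
    def end_char(self) -> str:
        return END

    @property
    def domain_chars(self) -> tuple[str, ...]:
        return tuple(c for c in self.chars if c not in (PAD, START, END))

    def save(self, path: str | Path) -> None:
        """One char per line; reserved symbols written as names."""
        names = {PAD: "<pad>", START: "<start>", END: "<end>"}
        with open(path, "w") as fh:
            fh.write(f"#max_len={self.max_len}\n")
            for c in self.chars:
                fh.write(names.get(c, c) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        names = {"<pad>": PAD, "<start>": START, "<end>": END}
        chars: list[str] = []
        max_len = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#max_len="):
                    max_len = int(line.split("=", 1)[1])
                elif line:
                    chars.append(names.get(line, line))
        return cls(chars=tuple(chars), max_len=max_len)


def build_vocabulary(
    corpus: Sequence[SequenceRecord],
    max_len: int,
    fixed_alphabet: Sequence[str] | None = None,
) -> Vocabulary:
    """Build a vocabulary from a corpus or a fixed alphabet.

    With ``fixed_alphabet`` the corpus is validated against it; otherwise
    the alphabet is the sorted set of observed characters.  Reserved
    symbols are appended last either way, so ordering is deterministic.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if fixed_alphabet is not None:
        domain = list(dict.fromkeys(fixed_alphabet))
        allowed = set(domain)
        for rec in corpus:
            bad = set(rec.text) - allowed
            if bad:
                raise UnknownCharacterError(
                    f"record {rec.id!r} contains characters {sorted(bad)} "
                    "outside the fixed alphabet"
                )
    else:
        observed: set[str] = set()
        for rec in corpus:
            observed.update(rec.text)
        domain = sorted(observed)
    return Vocabulary(chars=tuple(domain) + (PAD, START, END), max_len=max_len)


def mirna_vocabulary(max_len: int = 30) -> Vocabulary:
    """The fixed six-character nucleotide vocabulary (A, C, G, T, N, '-')."""
    return Vocabulary(chars=tuple(MIRNA_ALPHABET) + (PAD, START, END), max_len=max_len)


def filter_by_length(
    corpus: Sequence[SequenceRecord], max_len: int
) -> tuple[list[SequenceRecord], int]:
    """Keep records of length <= max_len, preserving order."""
    kept = [r for r in corpus if len(r) <= max_len]
    return kept, len(corpus) - len(kept)


def encode_indices(text: str, vocab: Vocabulary, truncate: bool = False) -> np.ndarray:
    """Map a string to a length-max_len integer index array (pad-filled)."""
    if len(text) > vocab.max_len:
        if not truncate:
            raise LengthError(
                f"string of length {len(text)} exceeds max_len {vocab.max_len}"
            )
        text = text[: vocab.max_len]
    idx = np.full(vocab.max_len, vocab.index[PAD], dtype=np.int64)
    for i, ch in enumerate(text):
        j = vocab.index.get(ch)
        if j is None:
            raise UnknownCharacterError(f"character {ch!r} not in vocabulary")
        idx[i] = j
    return idx


def one_hot_encode(
    record: SequenceRecord | str, vocab: Vocabulary, truncate: bool = False
) -> np.ndarray:
    """One-hot a string into a max_len x |vocab| binary matrix.

    Positions past the string encode the pad symbol, so every row sums to 1.
    """
    text = record.text if isinstance(record, SequenceRecord) else record
    idx = encode_indices(text, vocab, truncate=truncate)
    mat = np.zeros((vocab.max_len, len(vocab)), dtype=np.float64)
    mat[np.arange(vocab.max_len), idx] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray, vocab: Vocabulary) -> str:
    """Invert :func:`one_hot_encode`; stops at the first pad row."""
    matrix = np.asarray(matrix)
    if matrix.shape != (vocab.max_len, len(vocab)):
        raise ValueError(
            f"expected shape {(vocab.max_len, len(vocab))}, got {matrix.shape}"
        )
    chars = []
    for row in matrix:
        c = vocab.chars[int(np.argmax(row))]
        if c == PAD:
            break
        chars.append(c)
    return "".join(chars)
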