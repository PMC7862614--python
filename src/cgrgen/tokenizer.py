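"""Tokenizer and one-hot encoding for SMILES/CGR strings.

Every bracketed expression (conventional atom, dynamic atom, or dynamic
bond) is one token; the two-letter organic-subset elements Cl and Br are one
token; everything else is a single character.
"""

from __future__ import annotations

import json
import re

import numpy as np

from .errors import LengthError, SmilesSyntaxError, VocabularyError

TOKEN_RE = re.compile(
    r"\[[^\[\]]*\]"  # any bracket expression
    r"|Cl|Br"  # two-letter organic subset
    r"|%\d\d"  # two-digit ring closure
    r"|[A-Za-z]"  # one-letter element / aromatic atom
    r"|[0-9]"  # ring closure digit
    r"|[-=#:().>*+]"  # bonds, branches, separators
)

PAD, SOS, EOS = "<pad>", "<sos>", "<eos>"
SPECIALS = (PAD, SOS, EOS)


def tokenize(s: str) -> list[str]:
    """Split a SMILES/CGR string into dialect tokens.

    Raises SmilesSyntaxError on characters outside the alphabet or on a
    dangling ``[``.
    """
    tokens = []
    pos = 0
    while pos < len(s):
        if s[pos] == "[" and "]" not in s[pos:]:
            raise SmilesSyntaxError("unclosed bracket", pos)
        m = TOKEN_RE.match(s, pos)
        if m is None:
            raise SmilesSyntaxError(f"unexpected character {s[pos]!r}", pos)
        tokens.append(m.group())
        pos = m.end()
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


class Vocabulary:
    """Fixed token -> index mapping with pad/start/end specials."""

    def __init__(self, tokens):
        ordered = [t for t in SPECIALS]
        for t in sorted(set(tokens) - set(SPECIALS)):
            ordered.append(t)
        self.tokens = ordered
        self.index = {t: i for i, t in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token) -> bool:
        return token in self.index

    @classmethod
    def from_corpus(cls, strings) -> "Vocabulary":
        tokens: set[str] = set()
        for s in strings:
            tokens.update(tokenize(s))
        return cls(tokens)

    def encode(self, tokens: list[str]) -> list[int]:
        try:
            return [self.index[t] for t in tokens]
        except KeyError as exc:
            raise VocabularyError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, ids) -> list[str]:
        return [self.tokens[i] for i in ids]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.index, fh, indent=0, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            index = json.load(fh)
        vocab = cls.__new__(cls)
        vocab.tokens = [t for t, _ in sorted(index.items(), key=lambda kv: kv[1])]
        vocab.index = dict(index)
        return vocab


def one_hot_encode(tokens: list[str], vocab: Vocabulary, max_len: int = 256) -> np.ndarray:
    """(max_len, |vocab|) one-hot matrix; trailing rows one-hot at PAD."""
    if len(tokens) > max_len:
        raise LengthError(f"sequence of {len(tokens)} tokens exceeds max_len={max_len}")
    ids = vocab.encode(tokens)
    mat = np.zeros((max_len, len(vocab)), dtype=np.float32)
    mat[np.arange(len(ids)), ids] = 1.0
    mat[len(ids):, vocab.index[PAD]] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray, vocab: Vocabulary) -> list[str]:
    """Argmax-decode a one-hot (or softmax) matrix back to tokens."""
    pad = vocab.index[PAD]
    eos = vocab.index[EOS]
    tokens = []
    for row in np.asarray(matrix).argmax(axis=1):
        if row == pad or row == eos:
            break
        tokens.append(vocab.tokens[row])
    return tokens
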