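"""Atom-level SMILES tokenization, vocabulary, and fixed-length encoding.

Greedy left-to-right rules: bracket atoms ``[...]`` are single tokens,
two-letter elements (Cl, Br, Si, ...) take precedence over single letters,
aromatic lowercase atoms are tokens, and bond symbols, branch parentheses,
ring-closure digits (including ``%nn``), and the ``.`` separator are
one token each. ``atom_positions`` marks exactly the atomic tokens, in
SMILES appearance order, so they align 1:1 with the rows of the heavy-atom
adjacency matrix.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPECIAL_TOKENS", "PAD", "START", "END", "MASK", "UNK",
    "TokenizationError", "TokenSequence", "Vocabulary", "EncodedInput",
    "tokenize", "build_vocab", "encode", "decode",
]

PAD, START, END, MASK, UNK = "<PAD>", "<START>", "<END>", "<MASK>", "<UNK>"
SPECIAL_TOKENS = (PAD, START, END, MASK, UNK)

# Outside brackets SMILES only permits the organic subset, so the sole bare
# two-letter elements are Cl and Br (matched before C/B so they never split);
# anything else (Si, Se, Sn, ...) arrives as a bracket atom and stays whole.
_TWO_LETTER = "Cl|Br"
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]"          # bracket atom, one token
    rf"|{_TWO_LETTER}"      # two-letter halogens
    r"|[BCNOPSFI]"          # organic-subset single-letter elements
    r"|[bcnops]"            # aromatic single-letter atoms
    r"|\*"                  # wildcard atom
    r"|%\d\d"               # two-digit ring closure
    r"|[0-9]"               # ring-closure digit
    r"|[=#/\\\-:~.()+$])"   # bonds, branches, separators
)
_ATOM_RE = re.compile(
    rf"\[[^\]]+\]|{_TWO_LETTER}|[BCNOPSFI]|[bcnops]|\*"
)


class TokenizationError(ValueError):
    """Raised when a character sequence matches no tokenization rule."""


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]
    atom_positions: tuple[int, ...]

    @property
    def smiles(self) -> str:
        return "".join(self.tokens)


def tokenize(smiles: str) -> TokenSequence:
    """Split a SMILES string into surface tokens with atomic positions marked."""
    tokens: list[str] = []
    atom_positions: list[int] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"cannot tokenize {smiles!r} at position {pos} ({smiles[pos]!r})"
            )
        tok = m.group(0)
        if _ATOM_RE.fullmatch(tok):
            atom_positions.append(len(tokens))
        tokens.append(tok)
        pos = m.end()
    return TokenSequence(tokens=tuple(tokens), atom_positions=tuple(atom_positions))


class Vocabulary:
    """Bijective token<->id map with reserved low ids for special tokens."""

    def __init__(self, tokens: list[str]):
        for sp in SPECIAL_TOKENS:
            if sp in tokens:
                raise ValueError(f"special token {sp} may not appear in corpus tokens")
        self._tokens = list(SPECIAL_TOKENS) + list(tokens)
        self._ids = {t: i for i, t in enumerate(self._tokens)}
        if len(self._ids) != len(self._tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._ids

    def id_of(self, token: str) -> int:
        return self._ids.get(token, self._ids[UNK])

    def token_of(self, idx: int) -> str:
        if not 0 <= idx < len(self._tokens):
            raise KeyError(f"id {idx} outside vocabulary of size {len(self._tokens)}")
        return self._tokens[idx]

    @property
    def pad_id(self) -> int:
        return self._ids[PAD]

    @property
    def start_id(self) -> int:
        return self._ids[START]

    @property
    def end_id(self) -> int:
        return self._ids[END]

    @property
    def mask_id(self) -> int:
        return self._ids[MASK]

    @property
    def unk_id(self) -> int:
        return self._ids[UNK]

    @property
    def n_special(self) -> int:
        return len(SPECIAL_TOKENS)

    def chemistry_ids(self) -> np.ndarray:
        """Ids of all non-special vocabulary entries."""
        return np.arange(self.n_special, len(self._tokens))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self._ids, fh, indent=0, sort_keys=False)

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        with open(path) as fh:
            ids = json.load(fh)
        ordered = sorted(ids, key=ids.get)
        if tuple(ordered[: len(SPECIAL_TOKENS)]) != SPECIAL_TOKENS:
            raise ValueError(f"vocabulary file {path} lacks the reserved special tokens")
        return cls(ordered[len(SPECIAL_TOKENS):])


def build_vocab(corpus: list[str]) -> Vocabulary:
    """Deterministic vocabulary: specials, then lexicographic corpus tokens."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen: set[str] = set()
    for smiles in corpus:
        seen.update(tokenize(smiles).tokens)
    return Vocabulary(sorted(seen))


@dataclass(frozen=True)
class EncodedInput:
    """Fixed-length id sequence: START + tokens + END + PAD..., with the
    atomic-token positions shifted by one for the START token."""

    ids: np.ndarray
    atom_positions: np.ndarray
    n_real: int  # count of ids before padding, including START and END

    @property
    def padding_mask(self) -> np.ndarray:
        """True at real positions, False at PAD."""
        mask = np.zeros(len(self.ids), dtype=bool)
        mask[: self.n_real] = True
        return mask


class SequenceLengthError(ValueError):
    """Raised when a token sequence does not fit in max_len with START/END."""


def encode(seq: TokenSequence, vocab: Vocabulary, max_len: int = 256) -> EncodedInput:
    n = len(seq.tokens)
    if n + 2 > max_len:
        raise SequenceLengthError(
            f"sequence of {n} tokens exceeds max_len={max_len} (with START/END)"
        )
    ids = np.full(max_len, vocab.pad_id, dtype=np.intp)
    ids[0] = vocab.start_id
    for i, tok in enumerate(seq.tokens):
        ids[i + 1] = vocab.id_of(tok)
    ids[n + 1] = vocab.end_id
    atom_positions = np.asarray(seq.atom_positions, dtype=np.intp) + 1
    return EncodedInput(ids=ids, atom_positions=atom_positions, n_real=n + 2)


def decode(ids, vocab: Vocabulary) -> str:
    """Strip special tokens and concatenate surface tokens."""
    out: list[str] = []
    for idx in np.asarray(ids, dtype=np.intp):
        tok = vocab.token_of(int(idx))
        if tok in SPECIAL_TOKENS:
            continue
        out.append(tok)
    return "".join(out)
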