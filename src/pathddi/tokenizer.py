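"""SMILES tokenization, vocabulary management, and fixed-length encoding.

SMILES strings are split by a single compiled regular expression whose
alternation is ordered longest-match-first: bracketed atom groups (``[nH]``,
``[O-]``), two-letter halogen symbols (``Cl``, ``Br``), two-digit ring
closures (``%12``), then any single character (atoms, aromatic lowercase
atoms, digits, bond markers ``- = # :``, branch symbols ``( )``, and
stereochemistry marks ``@ / \\``).  The token list always covers the input
exactly, so concatenating the tokens reproduces the string.

Four special tokens are reserved at the lowest vocabulary IDs: ``<PAD>``,
``<UNK>``, ``<CLS>``, ``<SEP>``.  ``<SEP>`` is reserved for vocabulary
compatibility but never placed during sequence assembly.  Encoding prepends
``<CLS>`` and truncates or pads to a fixed length ``L`` (default 128).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

PAD, UNK, CLS, SEP = "<PAD>", "<UNK>", "<CLS>", "<SEP>"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP)

_PATTERN = re.compile(r"\[[^\]]+\]|Br|Cl|%\d{2}|.")
_PATTERN_CI = re.compile(r"\[[^\]]+\]|[Bb]r|[Cc]l|%\d{2}|.")


class TokenizationError(ValueError):
    pass


def tokenize(smiles: str, case_sensitive: bool = True) -> list[str]:
    """Split a SMILES string into tokens (lossless cover of the input).

    Raises :class:`TokenizationError` for an empty input or a bracket group
    that is opened but never closed.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    pattern = _PATTERN if case_sensitive else _PATTERN_CI
    tokens = pattern.findall(smiles)
    for tok in tokens:
        if tok in ("[", "]"):
            raise TokenizationError(
                f"unbalanced bracket group in SMILES {smiles!r}"
            )
    return tokens


@dataclass
class Vocabulary:
    """Token-to-ID map with the 4 special tokens at IDs 0..3."""

    token_to_id: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.token_to_id:
            self.token_to_id = {t: i for i, t in enumerate(SPECIAL_TOKENS)}

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.token_to_id[UNK])

    def add(self, token: str) -> int:
        if token not in self.token_to_id:
            self.token_to_id[token] = len(self.token_to_id)
        return self.token_to_id[token]

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(self.token_to_id, indent=0, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        table = json.loads(text)
        for i, t in enumerate(SPECIAL_TOKENS):
            if table.get(t) != i:
                raise ValueError(f"special token {t} must have ID {i}")
        return cls(token_to_id=table)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_vocab(corpus: list[str], case_sensitive: bool = True) -> Vocabulary:
    """Vocabulary of the 4 specials plus every distinct corpus token, in
    first-occurrence order (deterministic for a fixed corpus order)."""
    if not corpus:
        raise ValueError("empty corpus")
    vocab = Vocabulary()
    for smiles in corpus:
        for tok in tokenize(smiles, case_sensitive=case_sensitive):
            vocab.add(tok)
    return vocab


@dataclass
class TokenSequence:
    """Fixed-length integer encoding of one SMILES.

    ``ids[0]`` is always ``<CLS>``; ``mask`` is True at real-token positions
    (including ``<CLS>``) and False exactly at ``<PAD>`` positions.
    """

    ids: np.ndarray
    mask: np.ndarray
    raw_tokens: list[str]

    def __len__(self) -> int:
        return len(self.ids)


def encode(smiles: str, vocab: Vocabulary, L: int = 128,
           case_sensitive: bool = True) -> TokenSequence:
    """Encode one SMILES to a length-``L`` ID vector with ``<CLS>`` prepended.

    Tokens beyond position ``L-1`` are dropped (the prefix is kept); shorter
    sequences are padded with ``<PAD>``.
    """
    if L < 2:
        raise ValueError("L must be at least 2")
    tokens = tokenize(smiles, case_sensitive=case_sensitive)
    kept = tokens[: L - 1]
    ids = np.full(L, vocab.id_of(PAD), dtype=np.int64)
    ids[0] = vocab.id_of(CLS)
    for i, tok in enumerate(kept, start=1):
        ids[i] = vocab.id_of(tok)
    mask = np.zeros(L, dtype=bool)
    mask[: 1 + len(kept)] = True
    return TokenSequence(ids=ids, mask=mask, raw_tokens=tokens)
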