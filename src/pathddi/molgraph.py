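"""SMILES-token-to-graph construction and position-aware node features.

A tokenized SMILES is re-read as a walk over atoms: atom tokens become graph
nodes at their sequence positions (position 0 is reserved for ``<CLS>`` and is
never an atom), consecutive atoms are bonded with the pending bond weight,
branch parentheses push/pop the attachment atom, and matching ring-closure
digits bond the two atoms that opened them.  The result is a fixed-size
``L x L`` symmetric weighted adjacency matrix aligned to the token positions
used by the sequence encoder, so the two molecular views share an index space.

Bond weights follow bond multiplicities: ``-`` 1, ``=`` 2, ``#`` 3, ``:`` and
implicit bonds between two aromatic atoms 1.5.  Stereochemistry marks are
parsed but create no geometry.  Self-loops (weight 1 on the atom diagonal) can
be added for numerical stability and are on by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BOND_WEIGHTS = {"-": 1.0, "=": 2.0, "#": 3.0, ":": 1.5}
_STRUCTURAL = set(BOND_WEIGHTS) | {"(", ")", ".", "/", "\\", "@", "+"}
_AROMATIC_SINGLE = {"b", "c", "n", "o", "p", "s"}


class GraphConstructionError(ValueError):
    pass


def is_atom_token(token: str) -> bool:
    """Atom tokens: bracket groups, element symbols, aromatic lowercase atoms.

    Any purely alphabetic token counts as an atom; digits, ``%nn`` ring
    closures, bond markers, branch symbols, and stereo marks do not.
    """
    if token.startswith("["):
        return True
    if token in _STRUCTURAL:
        return False
    return token.isalpha()


def is_aromatic_token(token: str) -> bool:
    if token in _AROMATIC_SINGLE:
        return True
    if token.startswith("["):
        inner = token[1:-1]
        for ch in inner:
            if ch.isalpha():
                return ch.islower()
    return False


def _is_ring_closure(token: str) -> bool:
    return token.isdigit() or (token.startswith("%") and token[1:].isdigit())


@dataclass
class MolecularGraph:
    """L x L weighted adjacency plus the atom mask over token positions."""

    adjacency: np.ndarray
    atom_mask: np.ndarray
    tokens: list[str]

    @property
    def n_atoms(self) -> int:
        return int(self.atom_mask.sum())

    def bonds(self) -> list[tuple[int, int, float]]:
        """Undirected off-diagonal edges as (i, j, weight), i < j, sorted."""
        A = self.adjacency
        iu, ju = np.triu_indices_from(A, k=1)
        sel = A[iu, ju] > 0
        return sorted(
            (int(i), int(j), float(A[i, j]))
            for i, j in zip(iu[sel], ju[sel])
        )

    def dump_edges(self) -> str:
        """Plain-text edge list for diffing against an external oracle."""
        lines = [f"{i}\t{j}\t{w:g}" for i, j, w in self.bonds()]
        return "\n".join(lines) + ("\n" if lines else "")


def parse_to_adjacency(tokens: list[str], L: int,
                       add_self_loops: bool = True) -> MolecularGraph:
    """Build the molecular graph for one tokenized SMILES.

    ``tokens`` are the raw tokens (no ``<CLS>``); token ``i`` sits at matrix
    position ``i + 1``, matching the encoder layout.  Tokens beyond position
    ``L - 1`` are dropped, mirroring sequence truncation; a ring closure left
    open (by malformed input or by the cut) is an error.
    """
    A = np.zeros((L, L), dtype=np.float64)
    atom_mask = np.zeros(L, dtype=bool)
    kept = tokens[: L - 1]

    prev_atom: int | None = None
    prev_aromatic = False
    pending: float | None = None          # explicit bond marker, if any
    stack: list[tuple[int | None, bool]] = []
    open_rings: dict[str, tuple[int, bool, float | None]] = {}

    def bond_weight(explicit: float | None, a_arom: bool, b_arom: bool) -> float:
        if explicit is not None:
            return explicit
        return 1.5 if (a_arom and b_arom) else 1.0

    for i, tok in enumerate(kept):
        pos = i + 1
        if is_atom_token(tok):
            atom_mask[pos] = True
            arom = is_aromatic_token(tok)
            if prev_atom is not None:
                w = bond_weight(pending, prev_aromatic, arom)
                A[prev_atom, pos] = A[pos, prev_atom] = w
            prev_atom, prev_aromatic = pos, arom
            pending = None
        elif tok in BOND_WEIGHTS:
            pending = BOND_WEIGHTS[tok]
        elif tok == "(":
            stack.append((prev_atom, prev_aromatic))
        elif tok == ")":
            if not stack:
                raise GraphConstructionError(
                    f"unmatched ')' at token position {pos}"
                )
            prev_atom, prev_aromatic = stack.pop()
            pending = None
        elif _is_ring_closure(tok):
            if prev_atom is None:
                raise GraphConstructionError(
                    f"ring closure {tok!r} with no preceding atom"
                )
            if tok in open_rings:
                open_pos, open_arom, open_bond = open_rings.pop(tok)
                explicit = pending if pending is not None else open_bond
                w = bond_weight(explicit, open_arom, prev_aromatic)
                A[open_pos, prev_atom] = A[prev_atom, open_pos] = w
            else:
                open_rings[tok] = (prev_atom, prev_aromatic, pending)
            pending = None
        elif tok == ".":
            prev_atom, prev_aromatic, pending = None, False, None
        # stereo marks and any other residual token: no geometric effect

    if open_rings:
        digits = ", ".join(sorted(open_rings))
        raise GraphConstructionError(
            f"ring closure(s) opened but never closed: {digits}"
        )

    if add_self_loops:
        idx = np.where(atom_mask)[0]
        A[idx, idx] = 1.0

    return MolecularGraph(adjacency=A, atom_mask=atom_mask, tokens=list(tokens))


def positional_encoding(L: int, d: int, decay: str = "logistic") -> np.ndarray:
    """Sinusoidal position encoding with a logistic position-dependent decay.

    ``P[pos, 2k]   = sin(pos / 10000^(2k/d)) * g(pos)``
    ``P[pos, 2k+1] = cos(pos / 10000^(2k/d)) * g(pos)``

    with ``g(pos) = 1 / (1 + exp(-pos/100))``, a bounded monotone envelope
    rising from 0.5 at position 0 toward 1.  ``decay`` selects the placement
    of the envelope: ``"logistic"`` scales the amplitude (default),
    ``"argument"`` applies it inside the sinusoid argument, ``"none"``
    disables it.  All entries lie in [-1, 1].
    """
    if d % 2 or d < 2:
        raise ValueError("feature width d must be even and >= 2")
    pos = np.arange(L, dtype=np.float64)[:, None]
    k = np.arange(d // 2, dtype=np.float64)[None, :]
    freq = 1.0 / np.power(10000.0, 2.0 * k / d)
    g = 1.0 / (1.0 + np.exp(-pos / 100.0))
    if decay == "logistic":
        sin, cos = np.sin(pos * freq) * g, np.cos(pos * freq) * g
    elif decay == "argument":
        sin, cos = np.sin(pos * g * freq), np.cos(pos * g * freq)
    elif decay == "none":
        sin, cos = np.sin(pos * freq), np.cos(pos * freq)
    else:
        raise ValueError(f"unknown decay mode {decay!r}")
    P = np.empty((L, d), dtype=np.float64)
    P[:, 0::2] = sin
    P[:, 1::2] = cos
    return P


def node_features(E: np.ndarray, P: np.ndarray,
                  atom_mask: np.ndarray,
                  use_positional: bool = True) -> np.ndarray:
    """Position-aware node features: ``(E + P)`` at atom rows, zero elsewhere.

    With ``use_positional=False`` (the positional-ablation mode) the features
    reduce to the token embeddings at atom rows.
    """
    E = np.asarray(E, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    if E.shape != P.shape:
        raise ValueError(f"shape mismatch: E {E.shape} vs P {P.shape}")
    mask = np.asarray(atom_mask, dtype=bool)[:, None]
    H = E * mask
    if use_positional:
        H = (H + P) * mask
    return H
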