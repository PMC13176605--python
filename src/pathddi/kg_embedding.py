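"""Knowledge-graph embeddings: translational scoring, the per-drug stacked
embedding matrix, and the size-invariant Conv->GAP->FC aggregator.

A triple ``(h, r, t)`` is scored by the translational criterion
``f(h, r, t) = ||h + r - t||_2^2`` — low score means plausible.  For a drug
subgraph with entity set ``E_d`` and relation-type set ``R_d``, the stored
vectors are stacked row-wise into ``M_d`` of shape ``(S, dim)`` with
``S = |E_d| + |R_d|`` and no pre-aggregation.  Row order is canonical
(entities sorted lexicographically, then relation types sorted
lexicographically): deterministic, but carrying no semantic meaning.

The aggregator treats ``M_d`` as a one-channel grid, applies a 2-D
convolution (kernel 5x5, stride 3x3, zero padding 1) with ``C`` output
channels and a LeakyReLU, global-average-pools over the spatial grid to a
``C``-vector, and projects to the knowledge-graph vector ``z_kg`` (default
width 20).  The output width is independent of ``S``, so subgraphs of any
size map to the same feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .io import EmbeddingStore
from .kg import DrugSubgraph


def transe_score(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """Squared Euclidean norm of ``h + r - t``."""
    h, r, t = (np.asarray(v, dtype=np.float64) for v in (h, r, t))
    if not (h.shape == r.shape == t.shape):
        raise ValueError(
            f"dimension mismatch: h{h.shape}, r{r.shape}, t{t.shape}"
        )
    diff = h + r - t
    return float(diff @ diff)


def train_toy_transe(triples, dim: int, margin: float = 1.0,
                     epochs: int = 100, lr: float = 0.01,
                     rng_seed: int = 0) -> EmbeddingStore:
    """Margin-based ranking training of translational embeddings, at test
    scale.

    For each positive triple a corrupted triple is drawn by replacing the
    head or the tail with a random entity; the hinge loss
    ``max(0, margin + f(pos) - f(neg))`` is minimized by SGD with entity
    vectors renormalized to the unit sphere each epoch.  This exists to
    produce realistic synthetic stores, not to train on real graphs.
    """
    triples = list(triples)
    if not triples:
        raise ValueError("empty triple set")
    rng = np.random.default_rng(rng_seed)
    entities = sorted({h for h, _, _ in triples} | {t for _, _, t in triples})
    relations = sorted({r for _, r, _ in triples})
    ent_vec = {e: rng.normal(0, 1.0 / np.sqrt(dim), dim) for e in entities}
    rel_vec = {r: rng.normal(0, 1.0 / np.sqrt(dim), dim) for r in relations}

    for _ in range(epochs):
        for e in entities:  # project entities back to the unit sphere
            ent_vec[e] /= max(np.linalg.norm(ent_vec[e]), 1e-12)
        order = rng.permutation(len(triples))
        for idx in order:
            h, r, t = triples[idx]
            corrupt_head = rng.random() < 0.5
            other = entities[rng.integers(len(entities))]
            h2, t2 = (other, t) if corrupt_head else (h, other)
            d_pos = ent_vec[h] + rel_vec[r] - ent_vec[t]
            d_neg = ent_vec[h2] + rel_vec[r] - ent_vec[t2]
            loss = margin + d_pos @ d_pos - d_neg @ d_neg
            if loss <= 0:
                continue
            g_pos = 2.0 * lr * d_pos
            g_neg = 2.0 * lr * d_neg
            ent_vec[h] -= g_pos
            ent_vec[t] += g_pos
            rel_vec[r] -= g_pos - g_neg
            ent_vec[h2] += g_neg
            ent_vec[t2] -= g_neg

    table = {**ent_vec, **rel_vec}
    return EmbeddingStore(table)


@dataclass
class SubgraphMatrix:
    """Stacked embedding rows of one drug subgraph (no aggregation)."""

    M: np.ndarray                                # (S, dim)
    row_index: list[tuple[str, str]]             # (kind, identifier)

    @property
    def S(self) -> int:
        return self.M.shape[0]


def build_matrix(subgraph: DrugSubgraph, store: EmbeddingStore
                 ) -> SubgraphMatrix:
    """Stack stored vectors for the subgraph's entities then relation types,
    each block sorted lexicographically.  A missing identifier raises a
    lookup error naming it."""
    rows = []
    index = []
    for entity in sorted(subgraph.entities):
        rows.append(store.lookup(entity))
        index.append(("entity", entity))
    for relation in sorted(subgraph.relations):
        rows.append(store.lookup(relation))
        index.append(("relation", relation))
    if not rows:
        raise ValueError(f"subgraph of {subgraph.drug!r} is empty")
    return SubgraphMatrix(M=np.stack(rows), row_index=index)


class ConvGapAggregator(nn.Module):
    """Size-invariant set-to-vector projection of a subgraph matrix.

    The convolution is a learnable aggregation over embedding coordinates,
    not a spatial-reasoning module; adaptive global average pooling then
    removes all dependence on the subgraph size S.  Matrices with fewer than
    3 rows are zero-padded to 3 so the convolution output grid is non-empty.
    """

    KERNEL = (5, 5)
    STRIDE = (3, 3)
    PADDING = (1, 1)
    MIN_ROWS = 3

    def __init__(self, emb_dim: int, channels: int, d_kg: int,
                 rng: np.random.Generator, slope: float = 0.01):
        super().__init__()
        self.emb_dim = emb_dim
        self.conv = nn.Conv2d(1, channels, self.KERNEL, self.STRIDE,
                              self.PADDING, rng)
        self.proj = nn.Linear(channels, d_kg, rng)
        self.slope = slope

    def __call__(self, M) -> nn.Tensor:
        M = nn.as_tensor(M)
        S, dim = M.shape
        if S < 1:
            raise ValueError("subgraph matrix must have at least one row")
        if dim != self.emb_dim:
            raise ValueError(
                f"embedding width {dim} != configured {self.emb_dim}"
            )
        if S < self.MIN_ROWS:
            pad = nn.Tensor(np.zeros((self.MIN_ROWS - S, dim)))
            M = nn.concat([M, pad], axis=0)
            S = self.MIN_ROWS
        grid = M.reshape(1, 1, S, dim)
        feat = self.conv(grid).leaky_relu(self.slope)   # 1,C,oh,ow
        pooled = feat.reshape(1, feat.shape[1], -1).mean(axis=2)  # 1,C
        return self.proj(pooled).reshape(-1)            # (d_kg,)

    def output_grid(self, S: int) -> tuple[int, int]:
        """Spatial grid size after the convolution for an S-row matrix."""
        S = max(S, self.MIN_ROWS)
        return self.conv.out_shape(S, self.emb_dim)
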