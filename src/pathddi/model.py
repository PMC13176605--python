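"""End-to-end DDI model: per-drug encoders, concatenation fusion, and the
multiclass (or binary) classifier head.

For a pair (a, b) the joint feature is the fixed-order concatenation

    x = [z_trans_a || z_gat_a || z_kg_a || z_trans_b || z_gat_b || z_kg_b]

of width ``D = 2 (d_model + K d' + d_kg)``; ablation variants keep only a
subset of the three blocks (the ``+sp`` suffix of the KG variants is a
pipeline-level switch — with vs without the pathway/shortest-path extraction
— and does not change the fusion layout).  The head is a fully connected
stack with batch normalization, LeakyReLU, and dropout; class probabilities
are the softmax of its logits.  Binary mode uses a 2-logit softmax for
uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import RunConfig
from .encoders import TransformerBranch, GATBranch
from .kg_embedding import ConvGapAggregator
from .molgraph import positional_encoding

VARIANT_BLOCKS = {
    "transformer": ("trans",),
    "gat": ("gat",),
    "transformer+gat": ("trans", "gat"),
    "kg-rw": ("kg",),
    "kg-rw+sp": ("kg",),
    "transformer+kg-rw": ("trans", "kg"),
    "transformer+kg-rw+sp": ("trans", "kg"),
    "full": ("trans", "gat", "kg"),
}


@dataclass
class DrugBatch:
    """Precomputed per-drug model inputs, aligned by drug index."""

    drug_ids: list[str]
    token_ids: np.ndarray        # (n, L) int
    token_mask: np.ndarray       # (n, L) bool
    adjacency: np.ndarray        # (n, L, L)
    atom_mask: np.ndarray        # (n, L) bool
    subgraph_matrices: list[np.ndarray] | None   # per drug (S_i, emb_dim)

    def __len__(self) -> int:
        return len(self.drug_ids)


def block_widths(cfg: RunConfig) -> dict[str, int]:
    return {
        "trans": cfg.d_model,
        "gat": cfg.K_heads * cfg.d_prime,
        "kg": cfg.d_kg,
    }


def fused_width(cfg: RunConfig) -> int:
    """D for the configured ablation variant (2x the per-drug block sum)."""
    widths = block_widths(cfg)
    return 2 * sum(widths[b] for b in VARIANT_BLOCKS[cfg.ablation])


def fuse(reps_a: dict[str, nn.Tensor], reps_b: dict[str, nn.Tensor],
         blocks=("trans", "gat", "kg")) -> nn.Tensor:
    """Concatenate drug-a blocks then drug-b blocks in fixed order."""
    parts = [reps_a[b] for b in blocks] + [reps_b[b] for b in blocks]
    return nn.concat(parts, axis=-1)


class DDIModel(nn.Module):
    """Joint encoder + classifier; every submodule is trained end to end
    while the embedding store behind the subgraph matrices stays frozen."""

    def __init__(self, cfg: RunConfig, vocab_size: int, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.blocks = VARIANT_BLOCKS[cfg.ablation]
        self.n_classes = 2 if cfg.task_mode == "binary" else n_classes
        self.embed = nn.Embedding(vocab_size, cfg.d_emb, rng)
        self.P = positional_encoding(cfg.L, cfg.d_emb, cfg.positional_decay)
        if "trans" in self.blocks:
            self.transformer = TransformerBranch(
                cfg.L, cfg.d_emb, cfg.d_model, cfg.n_layers, cfg.n_head,
                cfg.d_ff, rng,
            )
        if "gat" in self.blocks:
            self.gat = GATBranch(cfg.d_emb, cfg.K_heads, cfg.d_prime, rng,
                                 readout=cfg.gat_readout,
                                 use_edge_weights=cfg.use_edge_weights)
        if "kg" in self.blocks:
            self.aggregator = ConvGapAggregator(
                cfg.embedding_dim, cfg.conv_channels, cfg.d_kg, rng
            )
        D = fused_width(cfg)
        self.head = nn.MLP([D, *cfg.head_hidden, self.n_classes], rng,
                           batchnorm=True, dropout=cfg.dropout)

    # -- per-drug encoding ----------------------------------------------------

    def encode_drugs(self, batch: DrugBatch) -> dict[str, nn.Tensor]:
        """Encode every drug in the batch; returns per-block (n, width)."""
        reps: dict[str, nn.Tensor] = {}
        E = self.embed(batch.token_ids)                       # n,L,d_emb
        if "trans" in self.blocks:
            reps["trans"] = self.transformer(E, batch.token_mask)
        if "gat" in self.blocks:
            m = batch.atom_mask[..., None].astype(float)
            H = E * nn.Tensor(m)
            if self.cfg.use_positional:
                H = H + nn.Tensor(self.P[None, :, :] * m)
            reps["gat"] = self.gat(H, batch.adjacency, batch.atom_mask)
        if "kg" in self.blocks:
            zs = [self.aggregator(M).reshape(1, -1)
                  for M in batch.subgraph_matrices]
            reps["kg"] = nn.concat(zs, axis=0)
        return reps

    # -- pair-level forward ---------------------------------------------------

    def pair_features(self, reps: dict[str, nn.Tensor],
                      a_idx: np.ndarray, b_idx: np.ndarray) -> nn.Tensor:
        reps_a = {b: reps[b][a_idx] for b in self.blocks}
        reps_b = {b: reps[b][b_idx] for b in self.blocks}
        return fuse(reps_a, reps_b, self.blocks)

    def logits(self, batch: DrugBatch, a_idx, b_idx) -> nn.Tensor:
        reps = self.encode_drugs(batch)
        x = self.pair_features(reps, np.asarray(a_idx), np.asarray(b_idx))
        return self.head(x)

    def predict_proba(self, batch: DrugBatch, a_idx, b_idx) -> np.ndarray:
        self.eval()
        p = nn.softmax(self.logits(batch, a_idx, b_idx), axis=-1)
        return p.data


def predict(x: nn.Tensor, head: nn.Module) -> nn.Tensor:
    """Class probabilities ``p = softmax(f_theta(x))`` for a pair feature."""
    if x.ndim == 1:
        x = x.reshape(1, -1)
    return nn.softmax(head(x), axis=-1)
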