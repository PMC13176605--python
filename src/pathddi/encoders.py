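"""Molecular encoders: the Transformer sequence branch and the K-head GAT
structural branch.

The sequence branch embeds token IDs, projects to the model width, runs a
stack of encoder layers with a padding mask (attention never sees ``<PAD>``
positions), and reads out the ``<CLS>`` row as ``z_trans``.  No positional
encoding is added in this branch: positional signal enters the pipeline only
through the graph branch's node features, where it preserves order-aware
distinctions for the token-to-graph construction.

The graph branch runs one K-head graph-attention layer over the molecular
adjacency.  Attention logits exist only on edges (self-loops included);
per-head outputs pass through an ELU and are concatenated to width
``K * d'``; a masked mean or max readout over atom positions followed by a
residual MLP yields ``z_gat``.  Bond multiplicities define the edge set and,
by default, scale the messages; a switch restricts them to defining the edge
set only.
"""

from __future__ import annotations

import numpy as np

from . import nn


class TransformerBranch(nn.Module):
    """Sequence encoder producing ``z_trans`` (the ``<CLS>`` row)."""

    def __init__(self, L: int, d_emb: int, d_model: int, n_layers: int,
                 n_head: int, d_ff: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.L = L
        self.proj = nn.Linear(d_emb, d_model, rng)
        self.layers = [
            nn.TransformerEncoderLayer(d_model, n_head, d_ff, rng, dropout)
            for _ in range(n_layers)
        ]

    def __call__(self, E: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
        """``E``: embedded tokens (B, L, d_emb); ``mask``: True at real
        tokens.  Returns (B, d_model)."""
        if E.shape[1] > self.L:
            raise ValueError(
                f"sequence length {E.shape[1]} exceeds configured L={self.L}"
            )
        x = self.proj(E)
        for layer in self.layers:
            x = layer(x, mask)
        return x[:, 0, :]   # <CLS> position


class GATLayer(nn.Module):
    """One multi-head graph attention layer over a weighted adjacency."""

    def __init__(self, d_in: int, K: int, d_prime: int,
                 rng: np.random.Generator, leaky_slope: float = 0.2,
                 use_edge_weights: bool = True):
        super().__init__()
        self.K, self.d_prime = K, d_prime
        self.W = [nn.Linear(d_in, d_prime, rng, bias=False) for _ in range(K)]
        self.a_src = [nn.Parameter(nn.layers.glorot(rng, d_prime, 1, (d_prime,)))
                      for _ in range(K)]
        self.a_dst = [nn.Parameter(nn.layers.glorot(rng, d_prime, 1, (d_prime,)))
                      for _ in range(K)]
        self.leaky_slope = leaky_slope
        self.use_edge_weights = use_edge_weights

    def attention(self, H: nn.Tensor, A: np.ndarray, head: int) -> nn.Tensor:
        """Edge-masked attention matrix for one head: rows over neighbors sum
        to 1; non-edges (and rows of edgeless positions) are exactly zero."""
        Wh = self.W[head](H)                                # B,L,d'
        s_src = (Wh * self.a_src[head]).sum(axis=-1)        # B,L
        s_dst = (Wh * self.a_dst[head]).sum(axis=-1)
        B, L = s_src.shape
        logits = (s_src.reshape(B, L, 1) + s_dst.reshape(B, 1, L)
                  ).leaky_relu(self.leaky_slope)
        edges = np.asarray(A) > 0                           # B,L,L
        has_edge = edges.any(axis=-1)                       # B,L
        # edgeless rows attend to their own diagonal to keep softmax defined,
        # then get zeroed below
        diag = np.zeros_like(edges)
        idx = np.arange(L)
        diag[:, idx, idx] = ~has_edge
        alpha = nn.softmax(logits.masked_fill(~(edges | diag), nn.NEG_FILL),
                           axis=-1)
        return alpha * nn.Tensor(has_edge[:, :, None].astype(float))

    def __call__(self, H: nn.Tensor, A: np.ndarray) -> nn.Tensor:
        outs = []
        A = np.asarray(A, dtype=np.float64)
        for k in range(self.K):
            alpha = self.attention(H, A, k)
            coef = alpha * nn.Tensor(A) if self.use_edge_weights else alpha
            outs.append((coef @ self.W[k](H)).elu())
        return nn.concat(outs, axis=-1)                     # B,L,K*d'


class GATBranch(nn.Module):
    """GAT layer + masked readout + residual MLP producing ``z_gat``."""

    def __init__(self, d_in: int, K: int, d_prime: int,
                 rng: np.random.Generator, readout: str = "mean",
                 use_edge_weights: bool = True):
        super().__init__()
        if readout not in ("mean", "max"):
            raise ValueError(f"unknown readout mode {readout!r}")
        width = K * d_prime
        self.gat = GATLayer(d_in, K, d_prime, rng,
                            use_edge_weights=use_edge_weights)
        self.mlp_in = nn.Linear(width, width, rng)
        self.mlp_out = nn.Linear(width, width, rng)
        self.readout_mode = readout

    def readout(self, nodes: nn.Tensor, atom_mask: np.ndarray) -> nn.Tensor:
        mask = np.asarray(atom_mask, dtype=bool)
        counts = mask.sum(axis=-1)
        if (counts == 0).any():
            raise ValueError("readout requires at least one atom node")
        if self.readout_mode == "mean":
            m = nn.Tensor(mask[..., None].astype(float))
            return (nodes * m).sum(axis=1) / nn.Tensor(counts[:, None].astype(float))
        filled = nodes.masked_fill(
            np.broadcast_to(~mask[..., None], nodes.shape), nn.NEG_FILL
        )
        return filled.max(axis=1)

    def __call__(self, H: nn.Tensor, A: np.ndarray,
                 atom_mask: np.ndarray) -> nn.Tensor:
        nodes = self.gat(H, A)
        pooled = self.readout(nodes, atom_mask)
        return pooled + self.mlp_out(self.mlp_in(pooled).leaky_relu())
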