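"""Run configuration: every tunable in one serializable record.

Defaults are desk-scale (small synthetic runs on one CPU); the values used in
large-scale knowledge-graph runs (walk budget 20,000 steps x 10,000 iterations
with restart probability 0.3 and a 10^6-node spread, 400-D embeddings,
sequence length 128) are all reachable through the same fields.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import yaml

DATASET_VARIANTS = ("CGPDS", "CGPD")
TASK_MODES = ("multiclass", "binary")
SPLIT_MODES = ("pair-stratified", "drug-disjoint")
ABLATION_VARIANTS = (
    "transformer", "gat", "transformer+gat", "kg-rw", "kg-rw+sp",
    "transformer+kg-rw", "transformer+kg-rw+sp", "full",
)


@dataclass
class RunConfig:
    # sequence branch
    L: int = 64
    d_emb: int = 32
    d_model: int = 32
    n_layers: int = 1
    n_head: int = 2
    d_ff: int = 64
    case_sensitive: bool = True

    # graph branch
    K_heads: int = 2
    d_prime: int = 8
    gat_readout: str = "mean"           # mean | max
    add_self_loops: bool = True
    use_positional: bool = True
    positional_decay: str = "logistic"  # logistic | argument | none
    use_edge_weights: bool = True

    # knowledge-graph branch
    d_kg: int = 20
    conv_channels: int = 32
    embedding_dim: int = 32             # synthetic store width; 400 on real data

    # walk / extraction
    walk_steps: int = 100
    walk_restart_prob: float = 0.3
    walk_iterations: int = 50
    walk_spread: int = 120
    hop_limit: int = 4

    # training
    n_folds: int = 5
    patience: int = 10
    max_epochs: int = 60
    batch_size: int = 64
    lr: float = 1e-3
    dropout: float = 0.3
    head_hidden: tuple[int, ...] = (256, 128)

    # run identity
    seed: int = 0
    variant: str = "CGPDS"              # CGPDS | CGPD
    task_mode: str = "multiclass"       # multiclass | binary
    split_mode: str = "pair-stratified" # pair-stratified | drug-disjoint
    ablation: str = "full"

    def __post_init__(self):
        if self.variant not in DATASET_VARIANTS:
            raise ValueError(f"unknown dataset variant {self.variant!r}")
        if self.task_mode not in TASK_MODES:
            raise ValueError(f"unknown task mode {self.task_mode!r}")
        if self.split_mode not in SPLIT_MODES:
            raise ValueError(f"unknown split mode {self.split_mode!r}")
        if self.ablation not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {self.ablation!r}")
        if self.d_model % self.n_head:
            raise ValueError("d_model must be divisible by n_head")
        self.head_hidden = tuple(self.head_hidden)

    # -- serialization (lossless round trip) ----------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_hidden"] = list(self.head_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
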