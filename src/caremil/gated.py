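"""Gated-attention MIL baseline.

Each instance embedding is transformed D -> H, then scored by the product
of a tanh branch and a sigmoid (gate) branch; softmax over instances gives
attention weights, and the bag representation is the attention-weighted sum
of instance vectors, fed to a linear-softmax head. The instance transform
matches the CAREMIL parallel network's capacity so the comparison isolates
the aggregation mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .bags import CellBag
from .model import _glorot, _init_mlp, _mlp_forward

__all__ = ["GatedMilConfig", "GatedMilModel", "gated_attention_weights",
           "gated_forward", "gated_predict_proba"]


@dataclass
class GatedMilConfig:
    D: int = 1000
    H: int = 128
    instance_hidden: Sequence[int] = (64,)
    L: Optional[int] = None          # gate dimension; defaults to H // 2
    mlp_hidden: Sequence[int] = (64,)
    n_classes: int = 2
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.instance_hidden = tuple(self.instance_hidden)
        self.mlp_hidden = tuple(self.mlp_hidden)
        if self.L is None:
            self.L = max(1, self.H // 2)
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


class GatedMilModel:
    def __init__(self, config: GatedMilConfig, params: Optional[Dict[str, Tensor]] = None):
        self.config = config
        if params is not None:
            self.params = params
            return
        rng = np.random.default_rng(config.seed)
        p: Dict[str, Tensor] = {}
        _init_mlp(rng, (config.D, *config.instance_hidden, config.H), "inst", p)
        p["gate_V"] = Tensor(_glorot(rng, config.H, config.L), requires_grad=True)
        p["gate_U"] = Tensor(_glorot(rng, config.H, config.L), requires_grad=True)
        p["gate_w"] = Tensor(_glorot(rng, config.L, 1), requires_grad=True)
        _init_mlp(rng, (config.H, *config.mlp_hidden, config.n_classes), "head", p)
        self.params = p

    def parameters(self):
        return self.params.values()

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


def gated_attention_weights(H_inst, model: GatedMilModel):
    """softmax_i( w . (tanh(V h_i) * sigmoid(U h_i)) ) over instances.

    Accepts an (N, H) ndarray or Tensor of transformed instances; returns a
    length-N Tensor of positive weights summing to 1.
    """
    h = Tensor.as_tensor(H_inst)
    if h.shape[0] < 1:
        raise ValueError("empty bag")
    gated = T.tanh(h @ model.params["gate_V"]) * T.sigmoid(h @ model.params["gate_U"])
    scores = (gated @ model.params["gate_w"]).reshape(1, h.shape[0])
    return T.softmax(scores, axis=-1).reshape(h.shape[0])


def gated_forward(model: GatedMilModel, bag: CellBag, training: bool = False,
                  rng: Optional[np.random.Generator] = None):
    """Returns (logits Tensor of shape (n_classes,), weights Tensor of shape (N,))."""
    cfg = model.config
    if bag.dim != cfg.D:
        raise ValueError(f"bag {bag.slide_id!r} has D={bag.dim}, model expects {cfg.D}")

    dropout_mask = None
    if training and cfg.dropout > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        keep = 1.0 - cfg.dropout
        dropout_mask = {}
        for prefix, sizes in (("inst", cfg.instance_hidden), ("head", cfg.mlp_hidden)):
            for i, hsz in enumerate(sizes):
                dropout_mask[f"{prefix}_h{i}"] = (
                    rng.random(hsz) < keep).astype(np.float64) / keep

    X = Tensor(bag.embeddings)
    n_inst = len(cfg.instance_hidden) + 1
    Hm = _mlp_forward(model.params, "inst", X, n_inst, dropout_mask=dropout_mask)
    weights = gated_attention_weights(Hm, model)
    z = (weights.reshape(1, bag.n_cells) @ Hm)          # (1, H) weighted sum
    n_head = len(cfg.mlp_hidden) + 1
    logits = _mlp_forward(model.params, "head", z, n_head,
                          dropout_mask=dropout_mask).reshape(cfg.n_classes)
    return logits, weights


def gated_predict_proba(model: GatedMilModel, bag: CellBag) -> np.ndarray:
    logits, _ = gated_forward(model, bag)
    e = np.exp(logits.data - logits.data.max())
    return e / e.sum()
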