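"""The CAREMIL network: trainable per-cell transforms, summary-statistic
class tokens, one transformer-style self-attention layer, and an MLP head.

Forward pipeline for a bag of N cell embeddings (N x D):

1. the *aggregator network* maps each cell D -> H;
2. summary statistics (mean, variance, optional power means) over these
   N vectors yield K class tokens of dimension H;
3. the *parallel network* independently maps each cell D -> H;
4. the sequence [K class tokens ; N cell vectors] passes through one
   multi-head self-attention layer (full attention, no residual connection:
   a token's output is exactly its attention-weighted value mixture);
5. the K post-attention class-token outputs are concatenated and fed to
   an MLP that emits the class logits.

Because the class tokens are order-free statistics and self-attention is
permutation-equivariant over the cell positions, the logits are invariant
to cell order and the per-cell attention scores are equivariant.

The class-token -> cell block of the attention matrix provides per-cell
relevance scores: each class-token row is averaged over heads, restricted
to cell columns, and renormalized to sum to 1 over cells (the attention
mass a token spends on other tokens is discarded; this renormalization is
recorded in the report metadata).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .aggregators import AggregatorConfig, build_summary_tokens
from .bags import CellBag

__all__ = ["CaremilConfig", "CaremilModel", "AttentionReport",
           "initialize", "forward", "predict_proba", "extract_cell_attention",
           "save_model", "load_model"]


@dataclass
class CaremilConfig:
    D: int = 1000
    H: int = 128
    aggregator_hidden: Sequence[int] = (64,)
    parallel_hidden: Sequence[int] = (64,)
    n_heads: int = 4
    mlp_hidden: Sequence[int] = (64,)
    n_classes: int = 2
    aggregator_config: AggregatorConfig = field(default_factory=AggregatorConfig)
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.aggregator_config, dict):
            self.aggregator_config = AggregatorConfig(**self.aggregator_config)
        self.aggregator_hidden = tuple(self.aggregator_hidden)
        self.parallel_hidden = tuple(self.parallel_hidden)
        self.mlp_hidden = tuple(self.mlp_hidden)
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.H % self.n_heads != 0:
            raise ValueError(f"H={self.H} must be divisible by n_heads={self.n_heads}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aggregator_config"] = {
            "use_mean": self.aggregator_config.use_mean,
            "use_variance": self.aggregator_config.use_variance,
            "genmean_powers": list(self.aggregator_config.genmean_powers),
        }
        return d


@dataclass
class AttentionReport:
    """Per-cell attention extracted from the class-token -> cell block."""

    scores: np.ndarray          # (N,) nonnegative, token- and head-averaged
    per_token_scores: np.ndarray  # (K, N), each row sums to 1 over cells
    slide_id: str
    token_names: Sequence[str] = ()
    normalization: str = "class-token rows renormalized over cell columns"


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_mlp(rng, sizes, prefix: str, params: Dict[str, Tensor]) -> None:
    for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
        params[f"{prefix}_W{i}"] = Tensor(_glorot(rng, a, b), requires_grad=True)
        params[f"{prefix}_b{i}"] = Tensor(np.zeros(b), requires_grad=True)


def _mlp_forward(params: Dict[str, Tensor], prefix: str, x: Tensor, n_layers: int,
                 final_activation=None, dropout_mask=None) -> Tensor:
    for i in range(n_layers):
        x = x @ params[f"{prefix}_W{i}"] + params[f"{prefix}_b{i}"]
        if i < n_layers - 1:
            x = T.tanh(x)
            if dropout_mask is not None and dropout_mask.get(f"{prefix}_h{i}") is not None:
                x = x * Tensor(dropout_mask[f"{prefix}_h{i}"])
    if final_activation is not None:
        x = final_activation(x)
    return x


class CaremilModel:
    def __init__(self, config: CaremilConfig, params: Optional[Dict[str, Tensor]] = None):
        self.config = config
        if params is not None:
            self.params = params
            return
        rng = np.random.default_rng(config.seed)
        p: Dict[str, Tensor] = {}
        _init_mlp(rng, (config.D, *config.aggregator_hidden, config.H), "agg", p)
        _init_mlp(rng, (config.D, *config.parallel_hidden, config.H), "par", p)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"attn_{name}"] = Tensor(_glorot(rng, config.H, config.H), requires_grad=True)
            p[f"attn_b{name[1:]}"] = Tensor(np.zeros(config.H), requires_grad=True)
        K = config.aggregator_config.n_tokens
        _init_mlp(rng, (K * config.H, *config.mlp_hidden, config.n_classes), "head", p)
        self.params = p

    @property
    def n_tokens(self) -> int:
        return self.config.aggregator_config.n_tokens

    def parameters(self):
        return self.params.values()

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


def initialize(config: CaremilConfig) -> CaremilModel:
    """Build a model with seed-deterministic Glorot-initialized parameters."""
    return CaremilModel(config)


def extract_cell_attention(full_attention: np.ndarray, K: int) -> np.ndarray:
    """Isolate the class-token -> cell block of a softmax attention matrix.

    ``full_attention`` has shape (K+N, K+N, heads) with rows normalized over
    all key positions. Returns the (K, N) block averaged over heads, each
    row renormalized to sum to 1 over the cell columns.
    """
    att = np.asarray(full_attention, dtype=np.float64)
    if att.ndim == 2:
        att = att[:, :, None]
    total = att.shape[0]
    if K >= total:
        raise ValueError(f"K={K} must be smaller than the sequence length {total}")
    block = att[:K, K:, :].mean(axis=2)  # (K, N), head-averaged
    row_sums = block.sum(axis=1, keepdims=True)
    return block / row_sums


def _attention_layer(model: CaremilModel, seq: Tensor) -> Tuple[Tensor, np.ndarray]:
    """One multi-head self-attention layer with residual; returns output and
    the softmax attention probabilities as a (T, T, heads) array."""
    cfg = model.config
    p = model.params
    total = seq.shape[0]
    dh = cfg.H // cfg.n_heads
    q = seq @ p["attn_Wq"] + p["attn_bq"]
    k = seq @ p["attn_Wk"] + p["attn_bk"]
    v = seq @ p["attn_Wv"] + p["attn_bv"]
    # (T, H) -> (heads, T, dh)
    q = q.reshape(total, cfg.n_heads, dh).transpose((1, 0, 2))
    k = k.reshape(total, cfg.n_heads, dh).transpose((1, 0, 2))
    v = v.reshape(total, cfg.n_heads, dh).transpose((1, 0, 2))
    logits = (q @ k.T) * (1.0 / np.sqrt(dh))
    attn = T.softmax(logits, axis=-1)          # (heads, T, T)
    heads_out = attn @ v                        # (heads, T, dh)
    merged = heads_out.transpose((1, 0, 2)).reshape(total, cfg.H)
    out = merged @ p["attn_Wo"] + p["attn_bo"]
    # no residual: a class token's output is purely its attention mixture, so
    # the head can only read what the token attends to — this is what makes
    # the extracted token->cell attention faithful to the prediction.
    return out, np.moveaxis(attn.data, 0, -1)


def forward(model: CaremilModel, bag: CellBag, training: bool = False,
            rng: Optional[np.random.Generator] = None):
    """Run the CAREMIL forward pass on one bag.

    Returns ``(logits, report)`` where ``logits`` is a Tensor of shape
    (n_classes,) (differentiable when ``training=True``) and ``report``
    is the :class:`AttentionReport` for the bag.
    """
    cfg = model.config
    if bag.dim != cfg.D:
        raise ValueError(f"bag {bag.slide_id!r} has D={bag.dim}, model expects {cfg.D}")
    if bag.n_cells < 1:
        raise ValueError("empty bag")

    dropout_mask = None
    if training and cfg.dropout > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        keep = 1.0 - cfg.dropout
        dropout_mask = {}
        for prefix, sizes in (("agg", cfg.aggregator_hidden),
                              ("par", cfg.parallel_hidden),
                              ("head", cfg.mlp_hidden)):
            for i, h in enumerate(sizes):
                dropout_mask[f"{prefix}_h{i}"] = (
                    rng.random(h) < keep).astype(np.float64) / keep

    X = Tensor(bag.embeddings)
    agg_final = T.relu if cfg.aggregator_config.genmean_powers else None
    n_agg = len(cfg.aggregator_hidden) + 1
    A = _mlp_forward(model.params, "agg", X, n_agg, final_activation=agg_final,
                     dropout_mask=dropout_mask)
    summary = build_summary_tokens(A, cfg.aggregator_config)
    K = len(summary.tokens)
    tokens = T.concat([t.reshape(1, cfg.H) for t in summary.tokens], axis=0)

    n_par = len(cfg.parallel_hidden) + 1
    P = _mlp_forward(model.params, "par", X, n_par, dropout_mask=dropout_mask)

    seq = T.concat([tokens, P], axis=0)        # (K + N, H)
    out_seq, attn_probs = _attention_layer(model, seq)

    cls = out_seq[slice(0, K)].reshape(1, K * cfg.H)
    n_head = len(cfg.mlp_hidden) + 1
    logits = _mlp_forward(model.params, "head", cls, n_head,
                          dropout_mask=dropout_mask).reshape(cfg.n_classes)

    per_token = extract_cell_attention(attn_probs, K)
    report = AttentionReport(scores=per_token.mean(axis=0),
                             per_token_scores=per_token,
                             slide_id=bag.slide_id,
                             token_names=summary.token_names)
    return logits, report


def predict_proba(model: CaremilModel, bag: CellBag) -> np.ndarray:
    """Class probabilities (softmax of the logits)."""
    logits, _ = forward(model, bag)
    z = logits.data - logits.data.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Checkpointing (shared by the gated baseline, which mirrors this layout)
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize params + config to an .npz checkpoint; round-trips bit-identically."""
    arrays = {f"param:{k}": v.data for k, v in model.params.items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps({"class": type(model).__name__, "config": model.config.to_dict()}
                   ).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path):
    from .gated import GatedMilConfig, GatedMilModel  # local import: avoids cycle
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["config_json"].tobytes()).decode())
        params = {k[len("param:"):]: Tensor(npz[k].copy(), requires_grad=True)
                  for k in npz.files if k.startswith("param:")}
    if meta["class"] == "CaremilModel":
        return CaremilModel(CaremilConfig(**meta["config"]), params=params)
    if meta["class"] == "GatedMilModel":
        return GatedMilModel(GatedMilConfig(**meta["config"]), params=params)
    raise ValueError(f"unknown model class {meta['class']!r} in checkpoint")
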