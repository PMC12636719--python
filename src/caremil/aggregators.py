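"""Bag-level summary statistics that serve as class tokens.

Each aggregator reduces an N x H matrix of transformed cell vectors to a
single H-vector describing the whole cell population — mean (composition),
population variance (heterogeneity), and the generalized (power) mean.
The resulting vectors are prepended to the per-cell token sequence as
class tokens, analogous to the [CLS] token in BERT-style transformers.

Every function accepts either a plain ndarray or an autodiff
:class:`~caremil._tensor.Tensor`, so the same code runs at inference and
inside the training graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from ._tensor import Tensor

__all__ = [
    "AggregatorConfig",
    "SummaryTokens",
    "mean_aggregate",
    "variance_aggregate",
    "generalized_mean_aggregate",
    "build_summary_tokens",
]


@dataclass
class AggregatorConfig:
    use_mean: bool = True
    use_variance: bool = True
    genmean_powers: Sequence[float] = ()

    def __post_init__(self):
        self.genmean_powers = tuple(float(p) for p in self.genmean_powers)
        for p in self.genmean_powers:
            if p == 0 or not np.isfinite(p):
                raise ValueError(f"generalized-mean power must be finite and nonzero, got {p}")
        if not (self.use_mean or self.use_variance or self.genmean_powers):
            raise ValueError("at least one aggregation must be enabled")

    @property
    def n_tokens(self) -> int:
        return int(self.use_mean) + int(self.use_variance) + len(self.genmean_powers)

    @property
    def token_names(self) -> List[str]:
        names = []
        if self.use_mean:
            names.append("mean")
        if self.use_variance:
            names.append("variance")
        names.extend(f"genmean_{p:g}" for p in self.genmean_powers)
        return names


@dataclass
class SummaryTokens:
    tokens: list  # K vectors (ndarray or Tensor), each of dimension H
    token_names: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.tokens:
            raise ValueError("SummaryTokens requires at least one token")
        if len(set(self.token_names)) != len(self.token_names):
            raise ValueError("token names must be unique")


def _check_nonempty(X):
    n = X.shape[0]
    if n == 0:
        raise ValueError("aggregation over an empty bag is undefined")
    return n


def mean_aggregate(X):
    """Coordinate-wise arithmetic mean over cells (rows)."""
    _check_nonempty(X)
    return X.mean(axis=0)


def variance_aggregate(X):
    """Coordinate-wise population variance (divide by N, so N=1 gives zeros)."""
    _check_nonempty(X)
    mu = X.mean(axis=0)
    return ((X - mu) ** 2).mean(axis=0)


def generalized_mean_aggregate(X, p: float):
    """Coordinate-wise power mean ((1/N) sum x_i^p)^(1/p) for nonnegative input.

    p=1 reduces to the arithmetic mean; large p approaches the coordinate
    maximum. p=0 (geometric mean) is not supported.
    """
    _check_nonempty(X)
    p = float(p)
    if p == 0 or not np.isfinite(p):
        raise ValueError("p must be finite and nonzero (geometric mean not implemented)")
    data = X.data if isinstance(X, Tensor) else np.asarray(X)
    if np.any(data < 0):
        raise ValueError("generalized mean requires nonnegative entries")
    if isinstance(X, Tensor):
        # epsilon keeps the p<1 gradient finite at exact zeros
        return ((X + 1e-12) ** p).mean(axis=0) ** (1.0 / p) - 1e-12
    return (np.mean(data ** p, axis=0)) ** (1.0 / p)


def build_summary_tokens(X, config: AggregatorConfig) -> SummaryTokens:
    """Apply the enabled aggregators in fixed order [mean, variance, genmean(p)...]."""
    tokens = []
    if config.use_mean:
        tokens.append(mean_aggregate(X))
    if config.use_variance:
        tokens.append(variance_aggregate(X))
    for p in config.genmean_powers:
        tokens.append(generalized_mean_aggregate(X, p))
    return SummaryTokens(tokens=tokens, token_names=config.token_names)
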