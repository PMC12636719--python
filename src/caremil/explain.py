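"""Attention-derived interpretability.

From a model's per-cell attention scores: rank cells by diagnostic
relevance, assemble top/random/bottom review panels, select top-attention
fractions, test cell-type enrichment among the most-attended cells
(per-type 2x2 chi-squared with Bonferroni correction, log-odds with
Haldane-Anscombe smoothing for rare types), and measure overlap between
high-attention cells and independently flagged marker cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .model import AttentionReport

__all__ = ["CellRanking", "PanelSelection", "EnrichmentTable", "rank_cells",
           "select_panel", "top_fraction_set", "enrichment_table",
           "chi_squared_2x2", "marker_overlap"]


@dataclass
class CellRanking:
    order: np.ndarray   # permutation of 0..N-1, descending score, ties by index
    scores: np.ndarray  # scores aligned with `order`

    @property
    def n_cells(self) -> int:
        return len(self.order)


@dataclass
class PanelSelection:
    top: np.ndarray
    random: np.ndarray
    bottom: np.ndarray


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # one row per cell type
    fraction: float
    n_top: int
    n_total: int
    m_tests: int
    alpha: float = 0.05

    def __getitem__(self, cell_type: str) -> pd.Series:
        return self.table.set_index("cell_type").loc[cell_type]


def rank_cells(report: AttentionReport) -> CellRanking:
    """Stable descending sort of cells by attention score (ties by cell index)."""
    scores = np.asarray(report.scores, dtype=float)
    if scores.size < 1:
        raise ValueError("empty attention report")
    order = np.argsort(-scores, kind="stable")
    return CellRanking(order=order, scores=scores[order])


def select_panel(ranking: CellRanking, k: int = 10, seed: int = 0) -> PanelSelection:
    """Top-k, seeded random-k (from all cells), and bottom-k cell indices.

    When N < 3k the rows may overlap; that is reported, not an error.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    n = ranking.n_cells
    kk = min(k, n)
    rng = np.random.default_rng(seed)
    rand = rng.choice(n, size=kk, replace=False)
    return PanelSelection(top=ranking.order[:kk], random=rand,
                          bottom=ranking.order[n - kk:])


def top_fraction_set(ranking: CellRanking, fraction: float) -> np.ndarray:
    """The ceil(fraction*N) highest-attention cell indices."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * ranking.n_cells)
    return ranking.order[:k]


def chi_squared_2x2(table: np.ndarray) -> Tuple[float, float]:
    """Pearson chi-squared (no continuity correction), 1 df, on a 2x2 table.

    Returns (statistic, p-value). Zero-margin tables give statistic 0, p 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    total = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if total == 0 or np.any(row == 0) or np.any(col == 0):
        return 0.0, 1.0
    expected = row @ col / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, df=1))


def enrichment_table(records: Sequence[Tuple[AttentionReport, Sequence[str]]],
                     fraction: float, vocabulary: Sequence[str],
                     alpha: float = 0.05) -> EnrichmentTable:
    """Cell-type enrichment among the top-attention cells, pooled over slides.

    For each slide the top ``fraction`` of cells by attention is selected;
    counts are pooled over all given slides (typically the correctly
    classified slides of one disease category). For every cell type a
    2x2 table (in top set vs not) x (is type vs not) yields a chi-squared
    statistic; Bonferroni correction uses m = number of types observed in
    the pooled population. Log-odds use Haldane-Anscombe +0.5 on zero cells.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    vocab = list(vocabulary)
    count_top = dict.fromkeys(vocab, 0)
    count_all = dict.fromkeys(vocab, 0)
    n_top_total = 0
    n_total = 0
    for report, cell_types in records:
        if cell_types is None:
            raise ValueError(f"slide {report.slide_id!r} has untyped cells")
        cell_types = list(cell_types)
        unknown = set(cell_types) - set(vocab)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")
        ranking = rank_cells(report)
        top_idx = top_fraction_set(ranking, fraction)
        n_top_total += len(top_idx)
        n_total += len(cell_types)
        for t in cell_types:
            count_all[t] += 1
        for i in top_idx:
            count_top[cell_types[i]] += 1

    observed_types = [t for t in vocab if count_all[t] > 0]
    m = len(observed_types)
    rows = []
    for t in vocab:
        ct, ca = count_top[t], count_all[t]
        frac_top = ct / n_top_total if n_top_total else 0.0
        frac_all = ca / n_total if n_total else 0.0
        ratio = frac_top / frac_all if frac_all > 0 else float("nan")
        # 2x2: (top, not-top) x (type t, other)
        tbl = np.array([[ct, n_top_total - ct],
                        [ca - ct, (n_total - n_top_total) - (ca - ct)]], dtype=float)
        stat, p = chi_squared_2x2(tbl)
        expected_min = float((tbl.sum(axis=1, keepdims=True)
                              @ tbl.sum(axis=0, keepdims=True) / tbl.sum()).min()) if tbl.sum() else 0.0
        a, b = frac_top, frac_all

        def _odds(f, num, den):
            if 0.0 < f < 1.0:
                return f / (1 - f)
            # Haldane-Anscombe: +0.5 to both cells of the degenerate margin
            return (num + 0.5) / (den - num + 0.5)

        log_odds = (math.log(_odds(a, ct, n_top_total)) - math.log(_odds(b, ca, n_total))
                    if n_total and n_top_total else float("nan"))
        rows.append({
            "cell_type": t, "count_top": ct, "count_all": ca,
            "frac_top": frac_top, "frac_all": frac_all, "ratio": ratio,
            "log_odds": log_odds, "chi2_stat": stat, "p_raw": p,
            "significant_bonferroni": bool(ca > 0 and p < alpha / m),
            "low_expected_count": expected_min < 5,
        })
    return EnrichmentTable(table=pd.DataFrame(rows), fraction=fraction,
                           n_top=n_top_total, n_total=n_total, m_tests=m, alpha=alpha)


def marker_overlap(report: AttentionReport, marker_flags: Sequence[bool],
                   fraction: float = 0.25) -> Tuple[float, float]:
    """Precision and recall of the top-attention set against flagged marker cells."""
    flags = np.asarray(marker_flags, dtype=bool)
    if flags.size != len(report.scores):
        raise ValueError("marker_flags must have one entry per cell")
    n_markers = int(flags.sum())
    if n_markers == 0:
        raise ValueError("no marker cells: recall undefined")
    top = top_fraction_set(rank_cells(report), fraction)
    hits = int(flags[top].sum())
    return hits / len(top), hits / n_markers
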