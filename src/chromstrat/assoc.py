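"""Association layer: stage trends, correlations, expression filters and
GSEA input tables.

Stage comparisons use one-tailed Welch (unequal-variance) t-tests with the
star bands * p<0.01, ** p<0.001, *** p<0.0001. Expression/accessibility
relationships use Pearson's product-moment correlation with its two-sided
t-based p-value. The basal-like exclusion filter removes samples in the
bottom quartile of expression for BOTH of two luminal marker genes
(FOXA1 and GATA3 by default), with a type-7 linear-interpolation quantile
and an inclusive (<= cut) boundary.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (1e-2, 1e-3, 1e-4)


def stars(p: float, alphas: Sequence[float] = DEFAULT_ALPHAS) -> str:
    """Significance stars: '*' p<0.01, '**' p<0.001, '***' p<0.0001."""
    a1, a2, a3 = sorted(alphas, reverse=True)
    if p < a3:
        return "***"
    if p < a2:
        return "**"
    if p < a1:
        return "*"
    return ""


def one_tailed_t(x, y, direction: str) -> float:
    """One-sided Welch two-sample t-test p-value.

    ``direction='greater'`` tests mean(x) > mean(y); ``'less'`` the reverse.
    Both samples need >= 2 observations. With zero variance in both samples
    and equal means the p-value is 0.5 by convention.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        dx = float(np.mean(x) - np.mean(y))
        if dx == 0:
            return 0.5
        favors = dx > 0 if direction == "greater" else dx < 0
        return 0.0 if favors else 1.0
    res = stats.ttest_ind(x, y, equal_var=False, alternative=direction)
    return float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided t-based p-value; requires n >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson requires two equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pearson requires finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def basal_filter(
    expr: ExpressionMatrix,
    markers: tuple[str, str] = ("FOXA1", "GATA3"),
    quartile: float = 0.25,
    boundary: str = "le",
) -> tuple[list[str], list[str]]:
    """Remove samples in the bottom quartile of expression for BOTH markers.

    The cut per marker is the type-7 (linear interpolation) quantile across
    all samples; samples at or below the cut for both markers are removed
    (``boundary='le'``; pass ``'lt'`` for a strict cut, exposed because the
    removal set on small cohorts is sensitive to this convention). Returns
    ``(kept_ids, removed_ids)`` in matrix sample order.
    """
    if boundary not in ("le", "lt"):
        raise ValueError("boundary must be 'le' or 'lt'")
    for m in markers:
        if m not in expr.data.index:
            raise ValueError(f"marker gene {m!r} absent from expression matrix")
    a = expr.data.loc[markers[0]].to_numpy()
    b = expr.data.loc[markers[1]].to_numpy()
    cut_a = float(np.quantile(a, quartile))  # numpy default = type-7 linear
    cut_b = float(np.quantile(b, quartile))
    if boundary == "le":
        removed_mask = (a <= cut_a) & (b <= cut_b)
    else:
        removed_mask = (a < cut_a) & (b < cut_b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        logger.warning("degenerate input: all samples tie at the quartile cut; all removed")
    samples = list(expr.sample_ids)
    removed = [s for s, r in zip(samples, removed_mask) if r]
    kept = [s for s, r in zip(samples, removed_mask) if not r]
    return kept, removed


def divergent_genes(
    expr: ExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudo_count: float = 1.0,
    lfc_threshold: float = 1.0,
) -> tuple[pd.Series, pd.Series]:
    """Genes with |log2((mean_a + pc)/(mean_b + pc))| beyond the threshold.

    Returns ``(higher_in_a, lower_in_a)`` as log2FC series. The sample sets
    must be disjoint and non-empty; a threshold of 0 classifies every gene
    with unequal means.
    """
    sa, sb = list(samples_a), list(samples_b)
    if not sa or not sb:
        raise ValueError("both sample sets must be non-empty")
    if set(sa) & set(sb):
        raise ValueError("sample sets must be disjoint")
    mean_a = expr.data[sa].mean(axis=1)
    mean_b = expr.data[sb].mean(axis=1)
    lfc = np.log2((mean_a + pseudo_count) / (mean_b + pseudo_count))
    higher = lfc[lfc > lfc_threshold].sort_values(ascending=False)
    lower = lfc[lfc < -lfc_threshold].sort_values()
    return higher, lower


@dataclass
class DecileTables:
    """Expression-decile selections and their per-gene mean expression."""

    gene: str
    top_samples: list[str]
    bottom_samples: list[str]
    top_means: pd.Series
    bottom_means: pd.Series


def decile_tables(
    expr: ExpressionMatrix,
    gene: str,
    decile: float = 0.10,
) -> DecileTables:
    """Per-gene mean expression in the top and bottom decile of one gene.

    Samples are ordered by the gene's expression with ties broken by sample
    id; ``floor(n * decile)`` samples go into each table. These tables are
    the input prepared for gene-set enrichment scoring (the enrichment
    engine itself is out of scope).
    """
    if gene not in expr.data.index:
        raise ValueError(f"gene {gene!r} absent from expression matrix")
    n = len(expr.sample_ids)
    n_sel = int(np.floor(n * decile))
    if n_sel < 1:
        raise ValueError(f"n * decile = {n * decile:.3g} selects no samples")
    order = sorted(expr.sample_ids, key=lambda s: (expr.data.at[gene, s], s))
    bottom = order[:n_sel]
    top = order[-n_sel:]
    return DecileTables(
        gene=gene,
        top_samples=top,
        bottom_samples=bottom,
        top_means=expr.data[top].mean(axis=1),
        bottom_means=expr.data[bottom].mean(axis=1),
    )


@dataclass
class StagePair:
    stage_a: str
    stage_b: str
    p_value: float
    stars: str


@dataclass
class StageComparison:
    """Adjacent and extreme-pair one-tailed comparisons across ordered stages."""

    stages: tuple[str, ...]
    values: dict[str, np.ndarray]
    direction: str
    comparisons: list[StagePair] = field(default_factory=list)

    def max_adjacent_p(self) -> float:
        # adjacent pairs come first; the extreme pair (if any) is appended last
        return max(c.p_value for c in self.comparisons[: len(self.stages) - 1])


def stage_trend(
    values_by_stage: Mapping[str, Sequence[float]],
    direction: str = "greater",
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> StageComparison:
    """One-tailed comparisons of each adjacent stage pair plus the extreme pair.

    ``values_by_stage`` maps ordered stage labels to per-sample values;
    ``direction='greater'`` tests that each later stage exceeds the earlier
    one (an increasing trend), ``'less'`` the reverse. Requires >= 2 stages
    with >= 2 samples each.
    """
    stages = tuple(values_by_stage.keys())
    if len(stages) < 2:
        raise ValueError("stage_trend requires at least 2 stages")
    values = {s: np.asarray(v, dtype=float) for s, v in values_by_stage.items()}
    for s, v in values.items():
        if len(v) < 2:
            raise ValueError(f"stage {s!r} has fewer than 2 samples")
    comp = StageComparison(stages=stages, values=values, direction=direction)
    pairs = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    if len(stages) > 2:
        pairs.append((stages[0], stages[-1]))
    for a, b in pairs:
        p = one_tailed_t(values[b], values[a], direction)
        comp.comparisons.append(StagePair(a, b, p, stars(p, alphas)))
    return comp
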