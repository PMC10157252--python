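"""Rank-based comparison of behavioral-state groups.

The statistical unit is the per-animal, trial-averaged value (N = 7 animals
per state by design). Groups are compared with the tie-corrected
Kruskal-Wallis H test (chi-square approximation, df = k - 1); which states
differ is then localised with a post-hoc pairwise procedure, by default
Dunn's z-test on the joint ranks with Holm adjustment (Dunn-Bonferroni and
rank-sum-Bonferroni are selectable). Significance is declared at p < 0.05
and annotated with the conventional star codes (* / ** / *** at 0.05, 0.01,
0.001, strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "posthoc_pairwise",
    "star_code",
    "compare_states",
    "POSTHOC_METHODS",
]

POSTHOC_METHODS = ("dunn-holm", "dunn-bonferroni", "ranksum-bonferroni")
ALPHA = 0.05


@dataclass
class GroupComparison:
    """A k-group rank comparison with its post-hoc table."""

    labels: tuple
    h: float
    df: int
    p_value: float
    pairwise: pd.DataFrame
    alpha: float = ALPHA
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _validate_groups(groups: Sequence) -> list:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least three observations in total")
    return groups


def kruskal_wallis(groups: Sequence):
    """Tie-corrected Kruskal-Wallis test.

    Returns (H, df, p) with p from the chi-square approximation,
    df = k - 1. All-identical pooled values yield (0, df, 1) rather than an
    error (zero variance carries no evidence either way).
    """
    groups = _validate_groups(groups)
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = spstats.kruskal(*groups)
    return float(h), df, float(p)


def _dunn_pvalues(groups: list) -> dict:
    """Two-sided Dunn z-test p-values on joint ranks, tie-corrected."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = spstats.rankdata(pooled)
    # tie correction term: sum(t^3 - t) / (12 (n - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    variance_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    offset = 0
    for g in groups:
        mean_ranks.append(ranks[offset : offset + g.size].mean())
        sizes.append(g.size)
        offset += g.size
    pvals = {}
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            pvals[(i, j)] = 1.0
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pvals[(i, j)] = float(2.0 * spstats.norm.sf(abs(z)))
    return pvals


def posthoc_pairwise(
    groups: Sequence,
    method: str = "dunn-holm",
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pairwise post-hoc comparison after Kruskal-Wallis.

    Methods: ``dunn-holm`` (default), ``dunn-bonferroni``,
    ``ranksum-bonferroni``. Adjusted p-values are never below the raw ones.
    Returns a DataFrame with columns pair, group_a, group_b, p_raw, p_adj,
    stars, significant.
    """
    if method not in POSTHOC_METHODS:
        raise ValueError(
            f"unknown post-hoc method {method!r}; choose from {POSTHOC_METHODS}"
        )
    groups = _validate_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pairs = list(combinations(range(len(groups)), 2))
    if method.startswith("dunn"):
        raw = _dunn_pvalues(groups)
        p_raw = np.array([raw[p] for p in pairs])
        adjust = "holm" if method.endswith("holm") else "bonferroni"
    else:
        p_raw = np.array(
            [
                spstats.ranksums(groups[i], groups[j]).pvalue
                for i, j in pairs
            ]
        )
        adjust = "bonferroni"
    _, p_adj, _, _ = multipletests(p_raw, method=adjust)
    p_adj = np.minimum(np.maximum(p_adj, p_raw), 1.0)
    return pd.DataFrame(
        {
            "pair": [f"{labels[i]} vs {labels[j]}" for i, j in pairs],
            "group_a": [labels[i] for i, j in pairs],
            "group_b": [labels[j] for i, j in pairs],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "stars": [star_code(p) for p in p_adj],
            "significant": p_adj < ALPHA,
        }
    )


def star_code(p: float) -> str:
    """Figure-legend star annotation: */**/*** at 0.05/0.01/0.001 (strict)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_states(
    groups: dict,
    method: str = "dunn-holm",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Full state comparison: Kruskal-Wallis plus the post-hoc table.

    ``groups`` maps state labels to per-animal value arrays.
    """
    labels = tuple(groups.keys())
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    h, df, p = kruskal_wallis(values)
    degenerate = h == 0.0 and p == 1.0
    pairwise = posthoc_pairwise(values, method=method, labels=list(labels))
    return GroupComparison(
        labels=labels,
        h=h,
        df=df,
        p_value=p,
        pairwise=pairwise,
        alpha=alpha,
        degenerate=degenerate,
    )
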