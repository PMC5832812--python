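"""Group-wise expression comparison with pathway-level Simes combination.

Consumes already-normalised relative expression values (genes × samples)
with a control / hyperuricemia / gout group assignment. Outliers are
removed once per gene × group by the Tukey 1.5·IQR box-plot rule before
testing (configurable); each gene is compared between group pairs with
the two-sided Wilcoxon rank-sum test, and member genes of a set are
combined with the Simes rule on raw P-values.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .pathway import simes_combine
from .types import ExpressionResult, GeneSet

__all__ = [
    "remove_outliers",
    "wilcoxon_rank_sum",
    "wilcoxon_pairwise",
    "pathway_expression_test",
]

#: group pairs compared, case group first
PAIRS = (
    ("gout_vs_control", "gout", "control"),
    ("gout_vs_hua", "gout", "hyperuricemia"),
    ("hua_vs_control", "hyperuricemia", "control"),
)


def remove_outliers(values: Sequence[float]) -> np.ndarray:
    """Drop values outside the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Applied once, never re-iterated. Fewer than 4 values are returned
    unchanged with a warning (quartiles would be meaningless).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        warnings.warn("fewer than 4 values; outlier removal skipped")
        return arr
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return arr[(arr >= lo) & (arr <= hi)]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) P-value.

    Exact distribution when the combined sample is small (≤ 20) and free
    of ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    return float(st.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _summary(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(med), float(q3)


def wilcoxon_pairwise(
    matrix: pd.DataFrame,
    groups: pd.Series,
    *,
    remove_for_test: bool = True,
) -> list[ExpressionResult]:
    """Pairwise rank-sum comparisons for every gene in the matrix.

    ``matrix`` is genes × samples; ``groups`` maps sample → group label.
    Box-plot summaries (Q1, median, Q3) are always computed after outlier
    removal; ``remove_for_test=False`` keeps outliers in the test itself.
    """
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = matrix.columns[groups.isna()][0]
        raise ValueError(f"sample {missing!r} has no group assignment")
    results: list[ExpressionResult] = []
    for gene, row in matrix.iterrows():
        by_group = {
            g: row[groups.index[groups == g]].to_numpy(dtype=float)
            for g in groups.unique()
        }
        filtered = {g: remove_outliers(v) if len(v) >= 4 else v for g, v in by_group.items()}
        tested = filtered if remove_for_test else by_group
        for pair, case, comp in PAIRS:
            if case not in tested or comp not in tested:
                continue
            p = wilcoxon_rank_sum(tested[case], tested[comp])
            results.append(ExpressionResult(
                gene=str(gene), pair=pair, p=p,
                summary={g: _summary(filtered[g]) for g in (case, comp)},
                n_used={g: int(len(tested[g])) for g in (case, comp)},
            ))
    return results


def pathway_expression_test(
    gene_results: Sequence[ExpressionResult] | Mapping[str, float],
    gene_set: GeneSet,
    pair: str | None = None,
) -> float:
    """Simes-combined pathway P over member genes' rank-sum P-values.

    Raw P-values are combined (no FDR substitution at the expression
    stage). ``gene_results`` is either a gene → P mapping or a list of
    :class:`ExpressionResult` filtered to ``pair``.
    """
    if isinstance(gene_results, Mapping):
        pvals = {g: p for g, p in gene_results.items() if g in gene_set.genes}
    else:
        pvals = {
            r.gene: r.p for r in gene_results
            if r.gene in gene_set.genes and (pair is None or r.pair == pair)
        }
    if not pvals:
        raise ValueError(f"{gene_set.set_id}: no member gene has a P-value")
    return simes_combine(list(pvals.values()))
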