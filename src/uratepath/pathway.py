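"""Multiplicity machinery: FDR adjustment variants and the Simes pathway test.

Two FDR modes are provided. ``"bh"`` is the standard Benjamini–Hochberg
step-up (rank scaling followed by running-minimum monotonicity enforcement,
delegated to statsmodels). ``"paper"`` is plain rank scaling,

    adj_i = min(1, p_i * N / r_i),    r_i = #{j : p_j <= p_i},

i.e. ties take the *maximum* rank and no monotonicity pass is applied, so an
adjusted sequence can be non-monotone in the raw ordering. This variant is
the default because it is the one that reproduces the published reference
tables for the urate transporter panel, including their non-monotone
adjusted pairs; ``"bh"`` is the statistically standard choice.

Pathway-level evidence is combined with the Simes rule over the member
SNPs' FDR-adjusted P-values: p = min_m N·P(m)/m over the ordered values.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .types import AnalysisConfig, AssocResult, GeneSet, PathwayResult, VariantInfo

__all__ = ["fdr_adjust", "simes_combine", "pathway_scan"]


def _validate_pvals(pvals: Sequence[float]) -> np.ndarray:
    arr = np.asarray(pvals, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr))):
        bad = arr[(arr < 0) | (arr > 1) | ~np.isfinite(arr)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    return arr


def fdr_adjust(pvals: Sequence[float], mode: str = "paper") -> np.ndarray:
    """FDR-adjust a vector of P-values.

    Parameters
    ----------
    pvals
        Raw P-values in [0, 1].
    mode
        ``"paper"`` — rank scaling with max-tie ranks, no monotonicity
        enforcement; ``"bh"`` — standard Benjamini–Hochberg step-up.

    Returns
    -------
    numpy.ndarray
        Adjusted P-values in the input order, capped at 1.
    """
    arr = _validate_pvals(pvals)
    if arr.size == 0:
        return arr
    n = arr.size
    if mode == "paper":
        # rank under ties = count of values <= p_i (max rank)
        ranks = np.array([(arr <= p).sum() for p in arr], dtype=float)
        return np.minimum(1.0, arr * n / ranks)
    if mode == "bh":
        return multipletests(arr, method="fdr_bh")[1]
    raise ValueError(f"unknown fdr mode {mode!r}")


def simes_combine(pvals: Sequence[float]) -> float:
    """Simes-combine P-values: min over m of N·P(m)/m on the sorted values.

    Valid as a test of the global null under independence or positive
    dependence of the components; capped at 1.
    """
    arr = _validate_pvals(pvals)
    if arr.size == 0:
        raise ValueError("cannot Simes-combine an empty list")
    n = arr.size
    order = np.sort(arr)
    scaled = n * order / np.arange(1, n + 1)
    return float(min(1.0, scaled.min()))


def members_in_panel(gene_set: GeneSet, panel: Sequence[VariantInfo]) -> list[str]:
    """rsIDs of panel SNPs whose gene belongs to the set (panel order)."""
    return [v.rsid for v in panel if v.gene in gene_set.genes]


def pathway_scan(
    assoc: Iterable[AssocResult],
    sets: Sequence[GeneSet],
    panel: Sequence[VariantInfo],
    config: AnalysisConfig | None = None,
    *,
    use_fdr: bool = True,
) -> list[PathwayResult]:
    """Combine per-SNP results to pathway level for every stratum × contrast cell.

    For each gene set the member SNPs' adjusted P-values (``p_fdr``; raw
    ``p`` if ``use_fdr=False``) are Simes-combined, then the combined values
    are FDR-adjusted across the gene sets within the cell (same mode). Sets
    with no usable member in a cell are flagged and excluded from the
    pathway-level FDR denominator.
    """
    config = config or AnalysisConfig()
    cells: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    for res in assoc:
        value = res.p_fdr if use_fdr else res.p
        if value is None or res.flag:
            continue
        cells[(res.stratum, res.contrast)][res.rsid] = value

    results: list[PathwayResult] = []
    for (stratum, contrast), by_rsid in cells.items():
        combinable: list[PathwayResult] = []
        for gene_set in sets:
            member_vals = [
                by_rsid[rsid]
                for rsid in members_in_panel(gene_set, panel)
                if rsid in by_rsid
            ]
            pr = PathwayResult(
                set_id=gene_set.set_id,
                stratum=stratum,
                contrast=contrast,
                member_pfdr=tuple(sorted(member_vals)),
                n_members=len(member_vals),
            )
            if member_vals:
                pr.p_simes = simes_combine(member_vals)
                combinable.append(pr)
            else:
                pr.flag = "no genotyped member"
            results.append(pr)
        if combinable:
            adjusted = fdr_adjust([pr.p_simes for pr in combinable], config.fdr_mode)
            for pr, adj in zip(combinable, adjusted):
                pr.p_fdr = float(adj)
    return results
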