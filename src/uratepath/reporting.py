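"""Effect-size correlation and assembly of publication-shaped result tables.

Includes the "reproduce-from-printed-values" path: given only per-SNP
FDR-adjusted P-values (e.g. the published reference columns for the
transporter panel), the pathway block — Simes-combined pathway P plus the
cross-pathway FDR adjustment — is regenerated without any cohort data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .pathway import pathway_scan
from .types import (
    AnalysisConfig,
    AssocResult,
    EffectCorrelation,
    GeneSet,
    PathwayResult,
    VariantInfo,
)

__all__ = [
    "correlate_effects",
    "pathway_block_from_pfdr",
    "read_pfdr_table",
    "build_pathway_table",
]


def correlate_effects(
    x: Sequence[float],
    y: Sequence[float],
    x_label: str = "x",
    y_label: str = "y",
    *,
    log_or: bool = False,
) -> EffectCorrelation:
    """Pearson correlation between two per-locus effect-size vectors.

    By default odds ratios are correlated on their natural scale;
    ``log_or=True`` log-transforms the ``y`` axis first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("effect correlation needs at least 3 loci")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("effects must be finite")
    if log_or:
        y = np.log(y)
        y_label = f"log({y_label})"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one axis")
    r = float(st.pearsonr(x, y)[0])
    return EffectCorrelation(
        x_label=x_label, y_label=y_label, r=r, r_squared=r * r,
        n_loci=int(x.size), pairs=tuple(zip(x.tolist(), y.tolist())),
    )


def pathway_block_from_pfdr(
    pfdr_by_cell: Mapping[tuple[str, str], Mapping[str, float]],
    sets: Sequence[GeneSet],
    panel: Sequence[VariantInfo],
    config: AnalysisConfig | None = None,
) -> list[PathwayResult]:
    """Regenerate the pathway block from per-SNP adjusted P-values alone.

    ``pfdr_by_cell`` maps (stratum, contrast) to a rsid → P_FDR mapping;
    for each cell the member SNPs of each set are Simes-combined and the
    pathway P-values FDR-adjusted across sets (``config.fdr_mode``).
    """
    assoc = [
        AssocResult(rsid=rsid, stratum=stratum, contrast=contrast, p=pfdr, p_fdr=pfdr)
        for (stratum, contrast), cell in pfdr_by_cell.items()
        for rsid, pfdr in cell.items()
    ]
    return pathway_scan(assoc, sets, panel, config)


def read_pfdr_table(path: str | Path) -> dict[tuple[str, str], dict[str, float]]:
    """Read a hand-entered per-SNP P_FDR table.

    TSV with columns ``contrast``, ``stratum``, ``rsid``, ``p_fdr`` — the
    input format of the reproduce-from-printed-values mode.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"contrast", "stratum", "rsid", "p_fdr"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out: dict[tuple[str, str], dict[str, float]] = {}
    for row in df.itertuples():
        out.setdefault((row.stratum, row.contrast), {})[row.rsid] = float(row.p_fdr)
    return out


def build_pathway_table(
    assoc: Sequence[AssocResult],
    pathway_results: Sequence[PathwayResult],
    panel: Sequence[VariantInfo],
) -> pd.DataFrame:
    """Assemble the SNP block and pathway block into one long-format table.

    Rows are (level, id, gene, stratum, contrast) with effect, P and P_FDR
    columns; the SNP block precedes the pathway block, mirroring the
    published table layout. Missing cells stay blank and are flagged in
    the ``flag`` column.
    """
    gene_of = {v.rsid: v.gene for v in panel}
    rows = []
    for r in assoc:
        rows.append({
            "level": "snp", "id": r.rsid, "gene": gene_of.get(r.rsid, ""),
            "stratum": r.stratum, "contrast": r.contrast,
            "effect": r.beta if r.beta is not None else r.odds_ratio,
            "p": r.p, "p_fdr": r.p_fdr, "flag": r.flag,
        })
    for pr in pathway_results:
        rows.append({
            "level": "pathway", "id": pr.set_id, "gene": "",
            "stratum": pr.stratum, "contrast": pr.contrast,
            "effect": None, "p": pr.p_simes, "p_fdr": pr.p_fdr, "flag": pr.flag,
        })
    df = pd.DataFrame(rows)
    order = {"snp": 0, "pathway": 1}
    return df.sort_values(
        ["level", "contrast", "stratum", "id"],
        key=lambda col: col.map(order) if col.name == "level" else col,
        kind="stable",
    ).reset_index(drop=True)
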