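"""Genetic urate risk scores (GRS) and their phenotype associations.

The weighted GRS for a pathway sums, over its member loci, the number of
effect alleles carried (0–2) times the per-allele urate beta estimated in
males; the unweighted GRS simply counts effect alleles. By default the
weights are the male urate betas of the same panel (in-sample weighting,
as the reference analysis did — documented as such); external weights can
be supplied.

The two default pathway locus lists each hold eight of the nine panel
SNPs: the ion-transporter pathway excludes rs2242206 (SLC16A9) and the
secondary-active-transporter pathway excludes rs2728121 (PKD2).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import MALE_BETA
from .types import GRSAssociation, GRSResult

__all__ = [
    "PATHWAY_LOCI",
    "pathway_weights",
    "compute_grs",
    "grs_variance_explained",
    "grs_outcome_association",
    "grs_bin_proportions",
]

#: member loci per pathway, following the two published GRS equations
PATHWAY_LOCI: dict[str, tuple[str, ...]] = {
    "GO:0015075": ("rs2728121", "rs1165165", "rs1165196", "rs11754288",
                   "rs13129697", "rs1395", "rs2071299", "rs3759053"),
    "GO:0015291": ("rs2242206", "rs1165165", "rs1165196", "rs11754288",
                   "rs13129697", "rs1395", "rs2071299", "rs3759053"),
}


def pathway_weights(pathway: str, weights: Mapping[str, float] | None = None) -> list[tuple[str, float]]:
    """(rsid, beta) pairs for a pathway; default weights are the male betas."""
    weights = dict(weights or MALE_BETA)
    loci = PATHWAY_LOCI[pathway]
    missing = [r for r in loci if r not in weights]
    if missing:
        raise KeyError(f"no weight for loci {missing}")
    return [(r, weights[r]) for r in loci]


def compute_grs(
    cohort: pd.DataFrame,
    pathway_loci: Sequence[tuple[str, float]],
    kind: str = "weighted",
    pathway: str = "",
) -> tuple[list[GRSResult], list[str]]:
    """Per-sample GRS over the given (rsid, beta) loci.

    Samples missing any locus are excluded and returned in the second
    element. ``kind="unweighted"`` ignores the betas and counts alleles.
    """
    if kind not in ("weighted", "unweighted"):
        raise ValueError(f"unknown GRS kind {kind!r}")
    for rsid, _ in pathway_loci:
        if rsid not in cohort.columns:
            raise KeyError(f"rsid {rsid!r} not genotyped in cohort")
    dose = cohort[[r for r, _ in pathway_loci]].apply(pd.to_numeric, errors="coerce")
    complete = dose.notna().all(axis=1)
    excluded = [str(s) for s in cohort.index[~complete]]
    dose = dose[complete]
    if kind == "weighted":
        betas = np.array([b for _, b in pathway_loci], dtype=float)
        scores = dose.to_numpy(dtype=float) @ betas
    else:
        scores = dose.to_numpy(dtype=float).sum(axis=1)
    results = [
        GRSResult(sample_id=str(sid), pathway=pathway, kind=kind, score=float(s))
        for sid, s in zip(dose.index, scores)
    ]
    return results, excluded


def _score_series(scores: Sequence[GRSResult] | pd.Series) -> pd.Series:
    if isinstance(scores, pd.Series):
        return scores
    return pd.Series({r.sample_id: r.score for r in scores}, name="score")


def grs_variance_explained(
    cohort: pd.DataFrame, scores: Sequence[GRSResult] | pd.Series, mask: pd.Series | None = None
) -> float:
    """Fraction of urate variance explained by the score (univariate R²).

    Defined as the squared Pearson correlation of score and urate within
    the (optionally masked) stratum. A zero-variance score yields 0 with a
    warning.
    """
    s = _score_series(scores)
    sub = cohort if mask is None else cohort[mask]
    data = pd.DataFrame({"urate": sub["urate"], "score": s}).dropna()
    if len(data) < 10:
        raise ValueError("fewer than 10 samples with urate and score")
    if data["score"].nunique() < 2:
        warnings.warn("score has zero variance; variance explained set to 0")
        return 0.0
    r = float(np.corrcoef(data["score"], data["urate"])[0, 1])
    return r * r


def grs_incremental_r2(
    cohort: pd.DataFrame, scores: Sequence[GRSResult] | pd.Series, mask: pd.Series | None = None
) -> float:
    """R² gained by adding the score to an age-only urate model (secondary)."""
    s = _score_series(scores)
    sub = cohort if mask is None else cohort[mask]
    data = pd.DataFrame({"urate": sub["urate"], "age": sub["age"], "score": s}).dropna()
    if len(data) < 10:
        raise ValueError("fewer than 10 samples with urate, age and score")
    y = data["urate"].to_numpy(dtype=float)
    base = sm.OLS(y, sm.add_constant(data[["age"]])).fit()
    full = sm.OLS(y, sm.add_constant(data[["age", "score"]])).fit()
    return float(base.ssr - full.ssr) / float(((y - y.mean()) ** 2).sum())


def grs_outcome_association(
    cohort: pd.DataFrame,
    scores: Sequence[GRSResult] | pd.Series,
    outcome: str,
    mask: pd.Series | None = None,
    pathway: str = "",
    kind: str = "weighted",
) -> GRSAssociation:
    """Association of the GRS with urate or a binary disease outcome.

    Binary outcomes (``hyperuricemia``: HUA or gout vs control; ``gout``:
    gout vs non-gout) use an age-adjusted logistic fit; ``urate`` uses an
    age-adjusted linear fit. Coefficients are per unit GRS with Wald P.
    """
    from .association import SeparationError

    s = _score_series(scores)
    sub = cohort if mask is None else cohort[mask]
    data = pd.DataFrame({"age": sub["age"], "score": s})
    if outcome == "urate":
        data["y"] = sub["urate"]
    elif outcome == "hyperuricemia":
        data["y"] = sub["status"].isin(("hyperuricemia", "gout")).astype(float)
    elif outcome == "gout":
        data["y"] = (sub["status"] == "gout").astype(float)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    data = data.dropna()
    if data["score"].nunique() < 2:
        raise ValueError("score has zero variance")
    x = sm.add_constant(data[["score", "age"]], has_constant="add")
    y = data["y"].to_numpy(dtype=float)
    ve = None
    if outcome == "urate":
        fit = sm.OLS(y, x).fit()
        ve = grs_variance_explained(sub, s)
    else:
        if data["y"].nunique() < 2:
            raise ValueError("both outcome classes must be present")
        fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        if abs(float(fit.params["score"])) > 15:
            raise SeparationError("separation in GRS logistic fit")
    return GRSAssociation(
        pathway=pathway, kind=kind, outcome=outcome,
        coefficient=float(fit.params["score"]), p=float(fit.pvalues["score"]),
        variance_explained=ve, n_used=len(data),
    )


def grs_bin_proportions(
    cohort: pd.DataFrame,
    scores: Sequence[GRSResult] | pd.Series,
    n_bins: int = 10,
    mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Disease proportions across equal-frequency bins of the score.

    Splits samples into ``n_bins`` quantile bins of the GRS and reports,
    per bin, the fraction with hyperuricemia (HUA or gout) and with gout,
    with the bin edges. If there are fewer distinct scores than bins, bins
    are merged with a warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    s = _score_series(scores)
    sub = cohort if mask is None else cohort[mask]
    data = pd.DataFrame({"score": s, "status": sub["status"]}).dropna()
    if n_bins == 1:
        binned = pd.Series(0, index=data.index)
        edges = np.array([data["score"].min(), data["score"].max()])
    else:
        try:
            binned, edges = pd.qcut(
                data["score"], n_bins, labels=False, retbins=True, duplicates="raise"
            )
        except ValueError:
            warnings.warn("fewer distinct score quantiles than bins; merging bins")
            binned, edges = pd.qcut(
                data["score"], n_bins, labels=False, retbins=True, duplicates="drop"
            )
    rows = []
    for b in sorted(pd.unique(binned)):
        grp = data[binned == b]
        rows.append({
            "bin": int(b),
            "score_lo": float(edges[int(b)]),
            "score_hi": float(edges[int(b) + 1]),
            "n": len(grp),
            "prop_hyperuricemia": float(grp["status"].isin(("hyperuricemia", "gout")).mean()),
            "prop_gout": float((grp["status"] == "gout").mean()),
        })
    return pd.DataFrame(rows).set_index("bin")
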