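"""Per-SNP association tests in each stratum.

Quantitative trait: ordinary least squares of urate on effect-allele
dosage with age (and, in mixed-sex strata, sex) adjustment; the P-value is
the deviance analysis of the nested models, i.e. the F-test on the
residual-sum-of-squares reduction attributable to the SNP term (1
numerator df). For one coefficient this is identical to the squared-t
test from the coefficient table, but the nested-model form is what the
scan reports.

Case-control contrasts: Fisher's exact test on the 2×2 allele-count table
under the additive model (each subject contributes two alleles), with the
sample odds ratio ad/bc (Haldane 0.5 correction only when a cell is zero,
flagged). A Cochran–Armitage genotype-trend alternative and a
covariate-adjusted logistic fit are also available.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .pathway import fdr_adjust
from .types import AnalysisConfig, AssocResult, VariantInfo

__all__ = [
    "hwe_test",
    "stratum_mask",
    "linear_snp_assoc",
    "fisher_allelic_test",
    "cochran_armitage_trend",
    "logistic_snp_assoc",
    "run_association_scan",
    "hwe_report",
]

#: case group and comparison group per case-control contrast
CONTRAST_GROUPS = {
    "gout_vs_control": ("gout", "control"),
    "gout_vs_hua": ("gout", "hyperuricemia"),
    "hua_vs_control": ("hyperuricemia", "control"),
}


class MonomorphicError(ValueError):
    """Dosage has no variance in the requested stratum."""


class SeparationError(ValueError):
    """Perfect separation in a logistic fit (monotone likelihood)."""


def hwe_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Chi-square goodness-of-fit test for Hardy–Weinberg proportions.

    ``counts`` are genotype counts (n_AA, n_Aa, n_aa) with ``a`` the
    counted allele. Expected counts come from the observed allele
    frequency; the statistic has 1 df. A monomorphic site returns (0, 1).
    """
    n_aa0, n_het, n_aa2 = (int(c) for c in counts)
    n = n_aa0 + n_het + n_aa2
    if n < 1:
        raise ValueError("need at least one genotype")
    q = (n_het + 2 * n_aa2) / (2 * n)
    if q in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    observed = np.array([n_aa0, n_het, n_aa2], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(st.chi2.sf(stat, df=1))


def stratum_mask(cohort: pd.DataFrame, stratum: str, config: AnalysisConfig) -> pd.Series:
    """Boolean mask selecting the samples of a named stratum."""
    if stratum == "total":
        return pd.Series(True, index=cohort.index)
    if stratum in ("male", "female"):
        return cohort["sex"] == stratum
    lo, hi = config.bmi_bins
    if stratum == "bmi_under":
        return cohort["bmi"] < lo
    if stratum == "bmi_normal":
        return (cohort["bmi"] >= lo) & (cohort["bmi"] < hi)
    if stratum == "bmi_over":
        return cohort["bmi"] >= hi
    raise ValueError(f"unknown stratum {stratum!r}")


def _design(stratum_df: pd.DataFrame, rsid: str) -> pd.DataFrame:
    """Complete-case design frame: dosage, age, (sex dummy if mixed-sex)."""
    cols = {"dosage": pd.to_numeric(stratum_df[rsid], errors="coerce").astype("float64"),
            "age": stratum_df["age"].astype("float64"),
            "urate": stratum_df["urate"].astype("float64")}
    sexes = stratum_df["sex"].dropna().unique()
    if len(sexes) > 1:
        cols["sex_male"] = (stratum_df["sex"] == "male").astype(float)
    return pd.DataFrame(cols).dropna()


def linear_snp_assoc(
    cohort: pd.DataFrame, rsid: str, stratum: str = "total",
    config: AnalysisConfig | None = None,
) -> AssocResult:
    """Linear urate association for one SNP in one stratum.

    Fits urate ~ dosage + age (+ sex in mixed-sex strata) and tests the
    dosage term by the nested-model F-test against urate ~ age (+ sex).
    """
    config = config or AnalysisConfig()
    sub = cohort[stratum_mask(cohort, stratum, config)]
    data = _design(sub, rsid)
    if len(data) < 10:
        raise ValueError(f"{rsid}/{stratum}: fewer than 10 usable samples")
    if data["dosage"].nunique() < 2:
        raise MonomorphicError(f"{rsid}: monomorphic in stratum {stratum!r}")

    covariates = [c for c in ("age", "sex_male") if c in data.columns]
    x_full = sm.add_constant(data[["dosage", *covariates]], has_constant="add")
    rank = np.linalg.matrix_rank(x_full.to_numpy())
    if rank < x_full.shape[1]:
        for col in covariates:
            reduced = x_full.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ValueError(f"{rsid}/{stratum}: collinear covariate {col!r}")
        raise ValueError(f"{rsid}/{stratum}: rank-deficient design")
    y = data["urate"].to_numpy(dtype=float)
    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, sm.add_constant(data[covariates], has_constant="add")).fit()

    df_resid = full.df_resid
    f_stat = (reduced.ssr - full.ssr) / (full.ssr / df_resid)
    p = float(st.f.sf(f_stat, 1, df_resid)) if f_stat > 0 else 1.0
    return AssocResult(
        rsid=rsid, stratum=stratum, contrast="urate",
        beta=float(full.params["dosage"]), se=float(full.bse["dosage"]),
        p=min(p, 1.0), n_used=len(data),
    )


def _allele_table(
    cohort: pd.DataFrame, rsid: str, contrast: str, stratum: str, config: AnalysisConfig
) -> tuple[np.ndarray, int]:
    case_label, comp_label = CONTRAST_GROUPS[contrast]
    sub = cohort[stratum_mask(cohort, stratum, config)]
    dosage = pd.to_numeric(sub[rsid], errors="coerce")
    table = np.zeros((2, 2))
    n_used = 0
    for row, label in enumerate((case_label, comp_label)):
        group = dosage[(sub["status"] == label) & dosage.notna()]
        if group.empty:
            raise ValueError(f"{rsid}/{stratum}: empty {label!r} group")
        eff = float(group.sum())
        table[row] = (eff, 2 * len(group) - eff)
        n_used += len(group)
    return table, n_used


def fisher_allelic_test(
    cohort: pd.DataFrame, rsid: str, contrast: str, stratum: str = "total",
    config: AnalysisConfig | None = None,
) -> AssocResult:
    """Fisher's exact test on the 2×2 effect-vs-other allele table.

    Each subject contributes two alleles (additive model). The two-sided P
    sums hypergeometric outcomes with point probability ≤ the observed
    one; the OR is the cross-product ratio with a Haldane 0.5 correction
    only when a cell is zero (flagged ``haldane``).
    """
    config = config or AnalysisConfig()
    table, n_used = _allele_table(cohort, rsid, contrast, stratum, config)
    a, b = table[0]
    c, d = table[1]
    if (a + c == 0) or (b + d == 0):
        # all alleles identical in both groups: no contrast to test
        return AssocResult(rsid=rsid, stratum=stratum, contrast=contrast,
                           p=1.0, n_used=n_used, flag="degenerate")
    p = float(st.fisher_exact(table, alternative="two-sided")[1])
    flag = ""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flag = "haldane"
    return AssocResult(
        rsid=rsid, stratum=stratum, contrast=contrast,
        odds_ratio=float(a * d / (b * c)), p=min(p, 1.0), n_used=n_used, flag=flag,
    )


def cochran_armitage_trend(
    cohort: pd.DataFrame, rsid: str, contrast: str, stratum: str = "total",
    config: AnalysisConfig | None = None,
) -> AssocResult:
    """Cochran–Armitage trend test on genotype counts (alternative model).

    Provided as a flag-selectable alternative to the allelic Fisher test;
    scores genotypes 0/1/2 and tests the linear trend in case proportion.
    """
    config = config or AnalysisConfig()
    case_label, comp_label = CONTRAST_GROUPS[contrast]
    sub = cohort[stratum_mask(cohort, stratum, config)]
    dosage = pd.to_numeric(sub[rsid], errors="coerce")
    keep = dosage.notna() & sub["status"].isin((case_label, comp_label))
    dose = dosage[keep].to_numpy(dtype=float)
    case = (sub.loc[keep, "status"] == case_label).to_numpy()
    n = len(dose)
    if n == 0 or case.all() or not case.any():
        raise ValueError(f"{rsid}/{stratum}: both groups must be non-empty")
    # score test for trend == correlation-based chi-square with 1 df
    r = np.corrcoef(dose, case.astype(float))[0, 1]
    if np.isnan(r):
        return AssocResult(rsid=rsid, stratum=stratum, contrast=contrast,
                           p=1.0, n_used=n, flag="degenerate")
    stat = n * r**2
    return AssocResult(rsid=rsid, stratum=stratum, contrast=contrast,
                       p=float(st.chi2.sf(stat, df=1)), n_used=n)


def logistic_snp_assoc(
    cohort: pd.DataFrame, rsid: str, contrast: str, stratum: str = "total",
    covariates: Sequence[str] = ("sex",), config: AnalysisConfig | None = None,
) -> AssocResult:
    """Maximum-likelihood logistic fit of case status on dosage + covariates.

    OR = exp(dosage coefficient); P is the Wald test on that coefficient.
    Perfect separation raises :class:`SeparationError` naming the direction.
    """
    config = config or AnalysisConfig()
    case_label, comp_label = CONTRAST_GROUPS[contrast]
    sub = cohort[stratum_mask(cohort, stratum, config)]
    sub = sub[sub["status"].isin((case_label, comp_label))]
    cols = {"dosage": pd.to_numeric(sub[rsid], errors="coerce")}
    for cov in covariates:
        if cov == "sex":
            if sub["sex"].dropna().nunique() > 1:
                cols["sex_male"] = (sub["sex"] == "male").astype(float)
        else:
            cols[cov] = pd.to_numeric(sub[cov], errors="coerce")
    data = pd.DataFrame(cols)
    y = (sub["status"] == case_label).astype(float)
    keep = data.notna().all(axis=1)
    data, y = data[keep], y[keep]
    if len(data) < 10:
        raise ValueError(f"{rsid}/{stratum}: fewer than 10 usable samples")
    if y.nunique() < 2:
        raise ValueError(f"{rsid}/{stratum}: only one outcome class present")

    x = sm.add_constant(data, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            fit = sm.Logit(y.to_numpy(), x).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels PerfectSeparation* or convergence
            direction = "positive" if data["dosage"].corr(y) >= 0 else "negative"
            raise SeparationError(
                f"{rsid}/{stratum}: separation ({direction} dosage-outcome direction)"
            ) from exc
    coef = float(fit.params["dosage"])
    if abs(coef) > 15:  # effectively infinite log-odds: monotone likelihood
        direction = "positive" if coef > 0 else "negative"
        raise SeparationError(
            f"{rsid}/{stratum}: separation ({direction} dosage-outcome direction)"
        )
    return AssocResult(
        rsid=rsid, stratum=stratum, contrast=contrast,
        odds_ratio=float(np.exp(coef)), se=float(fit.bse["dosage"]),
        p=float(fit.pvalues["dosage"]), n_used=len(data),
    )


#: stratum × contrast grid of the full scan
SCAN_CELLS: tuple[tuple[str, str], ...] = tuple(
    [(s, "urate") for s in ("total", "male", "female", "bmi_under", "bmi_normal", "bmi_over")]
    + [(s, c) for c in ("gout_vs_control", "gout_vs_hua") for s in ("total", "male", "female")]
)


def run_association_scan(
    cohort: pd.DataFrame,
    panel: Sequence[VariantInfo],
    config: AnalysisConfig | None = None,
    *,
    case_control_test: str = "fisher",
) -> list[AssocResult]:
    """Run the full stratum × contrast grid and FDR-adjust within each cell.

    The urate contrast runs in total/male/female and the three BMI bins;
    gout-vs-control and gout-vs-HUA run in total/male/female. Within each
    cell the per-SNP raw P-values are FDR-adjusted across the panel
    (``config.fdr_mode``). Per-cell failures become flagged rows; the scan
    never aborts.
    """
    config = config or AnalysisConfig()
    results: list[AssocResult] = []
    for stratum, contrast in SCAN_CELLS:
        cell: list[AssocResult] = []
        for variant in panel:
            try:
                if contrast == "urate":
                    res = linear_snp_assoc(cohort, variant.rsid, stratum, config)
                elif case_control_test == "fisher":
                    res = fisher_allelic_test(cohort, variant.rsid, contrast, stratum, config)
                elif case_control_test == "trend":
                    res = cochran_armitage_trend(cohort, variant.rsid, contrast, stratum, config)
                else:
                    raise ValueError(f"unknown case_control_test {case_control_test!r}")
            except (ValueError, KeyError) as exc:
                res = AssocResult(rsid=variant.rsid, stratum=stratum,
                                  contrast=contrast, flag=str(exc))
            cell.append(res)
        ok = [r for r in cell if r.p is not None and not r.flag.startswith(("separation",))]
        if ok:
            adjusted = fdr_adjust([r.p for r in ok], config.fdr_mode)
            for r, adj in zip(ok, adjusted):
                r.p_fdr = float(adj)
        results.extend(cell)
    return results


def hwe_report(cohort: pd.DataFrame, panel: Sequence[VariantInfo]) -> pd.DataFrame:
    """Per-SNP Hardy–Weinberg goodness-of-fit over the whole cohort."""
    rows = []
    for v in panel:
        dosage = pd.to_numeric(cohort[v.rsid], errors="coerce").dropna()
        counts = tuple(int((dosage == k).sum()) for k in (0, 1, 2))
        stat, p = hwe_test(counts)
        rows.append({"rsid": v.rsid, "n0": counts[0], "n1": counts[1],
                     "n2": counts[2], "chi2": stat, "p": p})
    return pd.DataFrame(rows).set_index("rsid")
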