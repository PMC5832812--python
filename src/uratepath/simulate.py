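"""Synthetic cohort and expression generators.

The generator emulates the statistical structure the association pipeline
assumes: independent biallelic SNPs in Hardy–Weinberg proportions at the
panel MAFs, an additive per-allele urate model with age and sex covariate
effects, dichotomisation of urate at the hyperuricemia threshold, a
urate-mediated liability model for gout, and log-normal per-group
expression for the panel genes.

By default the per-allele effects act in males only, mirroring the
male-restricted genetic effects the panel was characterised with; female
dosages then carry no urate signal. Defaults place roughly a third of
samples above the 417 µmol/L threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, MALE_BETA
from .types import VariantInfo

__all__ = ["SimulationParams", "simulate_genotypes", "simulate_phenotypes",
           "simulate_cohort", "simulate_expression"]


@dataclass
class SimulationParams:
    """Parameters of the generative cohort model.

    Notes on defaults: ``urate_mean`` is the expected urate (µmol/L) for a
    female of mean age with zero effect alleles; males sit ``gamma_sex``
    higher. ``urate_sd`` is residual noise. ``gout_urate_slope`` is the
    log-odds increment of gout per µmol/L of urate above ``urate_mean``
    (the urate-mediated liability); ``snp_gout_effect`` allows direct
    per-allele log-odds effects on gout and defaults to zero so that any
    SNP–gout association flows through urate.
    """

    panel: tuple[VariantInfo, ...] = DEFAULT_PANEL
    beta: Mapping[str, float] = field(default_factory=lambda: dict(MALE_BETA))
    male_only_effects: bool = True
    urate_mean: float = 350.0
    urate_sd: float = 80.0
    gamma_age: float = 0.5
    gamma_sex: float = 60.0
    age_range: tuple[float, float] = (30.0, 75.0)
    sex_ratio: float = 0.5
    bmi_mean: float = 23.5
    bmi_sd: float = 3.5
    hua_threshold: float = 417.0
    gout_base_rate: float = 0.05
    gout_urate_slope: float = 0.01
    snp_gout_effect: Mapping[str, float] = field(default_factory=dict)
    n: int = 4332
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.urate_sd <= 0:
            raise ValueError("urate_sd must be positive")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex_ratio must be in (0, 1)")
        for v in self.panel:
            if not 0.0 <= v.maf <= 0.5:
                raise ValueError(f"{v.rsid}: MAF outside [0, 0.5]")


def simulate_genotypes(params: SimulationParams, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-SNP genotypes under Hardy–Weinberg proportions.

    Each SNP is drawn independently as Binomial(2, MAF), i.e. genotype
    frequencies (1-q)^2, 2q(1-q), q^2. Returns a samples × rsIDs frame of
    0/1/2 dosages.
    """
    rng = rng or np.random.default_rng(params.seed)
    sample_ids = [f"S{i:06d}" for i in range(params.n)]
    data = {
        v.rsid: rng.binomial(2, v.maf, size=params.n) for v in params.panel
    }
    return pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"), dtype="Int64")


def simulate_phenotypes(
    dosages: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach covariates, urate, and disease status to a dosage block.

    urate = urate_mean + Σ_j β_j·N_j·effect + γ_age·(age − mean age)
            + γ_sex·I(male) + N(0, urate_sd),
    where ``effect`` is 1 for males (always 1 if ``male_only_effects`` is
    off) and 0 for females. Status is gout with probability
    expit(logit(gout_base_rate) + slope·(urate − urate_mean) + direct SNP
    terms); otherwise hyperuricemia iff urate > threshold, else control.
    """
    from scipy.special import expit, logit

    rng = rng or np.random.default_rng(params.seed + 1)
    n = len(dosages)
    lo, hi = params.age_range
    age = rng.uniform(lo, hi, size=n)
    male = rng.random(n) < params.sex_ratio
    bmi = rng.normal(params.bmi_mean, params.bmi_sd, size=n)

    effect_on = np.ones(n) if not params.male_only_effects else male.astype(float)
    genetic = np.zeros(n)
    for rsid, b in params.beta.items():
        if rsid in dosages.columns:
            genetic += b * dosages[rsid].to_numpy(dtype=float)
    urate = (
        params.urate_mean
        + genetic * effect_on
        + params.gamma_age * (age - (lo + hi) / 2.0)
        + params.gamma_sex * male
        + rng.normal(0.0, params.urate_sd, size=n)
    )
    urate = np.maximum(urate, 1.0)  # urate is a positive concentration

    eta = logit(params.gout_base_rate) + params.gout_urate_slope * (urate - params.urate_mean)
    for rsid, g in params.snp_gout_effect.items():
        if rsid in dosages.columns:
            eta += g * dosages[rsid].to_numpy(dtype=float)
    gout = rng.random(n) < expit(eta)

    status = np.where(gout, "gout",
                      np.where(urate > params.hua_threshold, "hyperuricemia", "control"))
    pheno = pd.DataFrame(
        {
            "urate": urate,
            "age": age,
            "sex": np.where(male, "male", "female"),
            "bmi": bmi,
            "status": status,
        },
        index=dosages.index,
    )
    return pd.concat([pheno, dosages], axis=1)


def simulate_cohort(params: SimulationParams) -> pd.DataFrame:
    """Genotypes + phenotypes in one call, reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    dosages = simulate_genotypes(params, rng)
    return simulate_phenotypes(dosages, params, rng)


def simulate_expression(
    group_sizes: Mapping[str, int] | None = None,
    shift: Mapping[str, Mapping[str, float]] | None = None,
    genes: Sequence[str] | None = None,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes × samples relative-expression matrix by group.

    Expression is log-normal: exp(N(shift[gene][group], sigma)). Default
    group sizes are 58 controls, 85 hyperuricemia and 70 gout samples (the
    design of the expression comparison this emulates); default shifts are
    zero (global null).

    Returns the expression matrix and a sample → group Series.
    """
    group_sizes = dict(group_sizes or {"control": 58, "hyperuricemia": 85, "gout": 70})
    for g, size in group_sizes.items():
        if size < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    if genes is None:
        genes = tuple(dict(shift).keys()) if shift else tuple(v.gene for v in DEFAULT_PANEL)
    shift = shift or {}
    rng = np.random.default_rng(seed)

    sample_ids, groups = [], []
    for g, size in group_sizes.items():
        for i in range(size):
            sample_ids.append(f"{g[:4]}_{i:03d}")
            groups.append(g)
    groups = pd.Series(groups, index=pd.Index(sample_ids, name="sample_id"), name="group")

    rows = {}
    for gene in genes:
        gene_shift = shift.get(gene, {})
        mu = np.array([gene_shift.get(g, 0.0) for g in groups])
        rows[gene] = np.exp(rng.normal(mu, sigma))
    matrix = pd.DataFrame(rows, index=groups.index).T
    matrix.index.name = "gene"
    return matrix, groups
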