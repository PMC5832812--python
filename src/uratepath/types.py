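"""Shared domain types for the urate/gout pathway-association pipeline.

The pipeline is rsID-keyed throughout: a *panel* is a list of
:class:`VariantInfo`, a cohort is a :class:`pandas.DataFrame` whose dosage
columns are named by rsID (see :data:`COHORT_COLUMNS`), and gene sets map
gene symbols back to panel SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

VALID_BASES = frozenset("ACGT")

#: Phenotype/covariate columns expected in a cohort table (dosage columns,
#: one per panel rsID, come in addition).
COHORT_COLUMNS = ("urate", "age", "sex", "bmi", "status")

#: Disease-state labels; ``gout`` overrides ``hyperuricemia`` when both apply.
STATUS_LEVELS = ("control", "hyperuricemia", "gout")

#: Strata used in the association scan.
STRATA = ("total", "male", "female", "bmi_under", "bmi_normal", "bmi_over")

#: Phenotype contrasts. ``urate`` is the quantitative trait; the other three
#: are case/comparison group contrasts on disease state.
CONTRASTS = ("urate", "gout_vs_control", "gout_vs_hua", "hua_vs_control")


@dataclass(frozen=True)
class VariantInfo:
    """One candidate SNP: identifier, gene, effect allele and control MAF."""

    rsid: str
    gene: str
    effect_allele: str
    maf: float
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValueError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not a single base"
            )
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: MAF {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. a GO molecular-function term)."""

    set_id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.set_id}: gene set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.set_id}: duplicate gene symbols")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class AnalysisConfig:
    """Tunable analysis settings.

    Parameters
    ----------
    hua_threshold
        Serum urate cutoff (µmol/L) above which a sample is hyperuricemic;
        417 µmol/L is the monosodium-urate saturation point (7 mg/dl).
    bmi_bins
        Two strictly increasing BMI cutpoints splitting the cohort into
        underweight / normal / overweight (WHO bins 18.5 and 25 kg/m²).
    alpha
        Nominal significance level used in reports.
    fdr_mode
        ``"paper"`` — plain rank scaling without monotonicity enforcement
        (the variant that reproduces the published tables); ``"bh"`` —
        standard Benjamini–Hochberg step-up.
    """

    hua_threshold: float = 417.0
    bmi_bins: tuple[float, float] = (18.5, 25.0)
    alpha: float = 0.05
    fdr_mode: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        lo, hi = self.bmi_bins
        if not lo < hi:
            raise ValueError(f"bmi_bins {self.bmi_bins} not strictly increasing")
        if self.fdr_mode not in ("paper", "bh"):
            raise ValueError(f"unknown fdr_mode {self.fdr_mode!r}")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


@dataclass
class AssocResult:
    """Per-SNP association result in one stratum × contrast cell.

    Exactly one of ``beta`` (urate contrast, µmol/L per effect allele) or
    ``odds_ratio`` (case-control contrasts, per effect allele) is populated.
    ``flag`` carries a machine-readable reason when the test could not be
    run (e.g. ``"monomorphic"``, ``"separation"``); flagged rows keep their
    place in the scan instead of aborting it.
    """

    rsid: str
    stratum: str
    contrast: str
    p: float | None = None
    p_fdr: float | None = None
    beta: float | None = None
    odds_ratio: float | None = None
    se: float | None = None  # SE of beta (urate) or of log-OR (logistic)
    n_used: int = 0
    flag: str = ""

    def __post_init__(self) -> None:
        for name in ("p", "p_fdr"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.rsid} {name}={v} outside [0, 1]")
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise ValueError(f"{self.rsid}: odds ratio must be positive")
        if self.beta is not None and self.odds_ratio is not None:
            raise ValueError(f"{self.rsid}: beta and odds_ratio are mutually exclusive")


@dataclass
class PathwayResult:
    """Simes-combined pathway result for one gene set in one cell."""

    set_id: str
    stratum: str
    contrast: str
    member_pfdr: tuple[float, ...] = ()
    p_simes: float | None = None
    p_fdr: float | None = None
    n_members: int = 0
    flag: str = ""


@dataclass
class GRSResult:
    """Per-sample genetic urate risk score for one pathway."""

    sample_id: str
    pathway: str
    kind: str  # "weighted" | "unweighted"
    score: float


@dataclass
class GRSAssociation:
    """Association of a GRS with urate or a binary disease outcome."""

    pathway: str
    kind: str
    outcome: str  # "urate" | "hyperuricemia" | "gout"
    coefficient: float
    p: float
    variance_explained: float | None = None
    variance_explained_incremental: float | None = None
    n_used: int = 0


@dataclass
class ExpressionResult:
    """Pairwise Wilcoxon comparison of one gene's expression."""

    gene: str
    pair: str
    p: float
    summary: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    n_used: dict[str, int] = field(default_factory=dict)


@dataclass
class EffectCorrelation:
    """Pearson correlation between two per-locus effect-size vectors."""

    x_label: str
    y_label: str
    r: float
    r_squared: float
    n_loci: int
    pairs: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_loci < 3:
            raise ValueError("effect correlation needs at least 3 loci")


def result_fields(cls) -> list[str]:
    """Column order for writing a homogeneous result table."""
    return [f.name for f in fields(cls)]


def find_variant(panel: Sequence[VariantInfo], rsid: str) -> VariantInfo:
    for v in panel:
        if v.rsid == rsid:
            return v
    raise KeyError(f"rsid {rsid!r} not in panel")
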