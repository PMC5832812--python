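"""Readers and writers for the pipeline's tabular formats.

Genotype and phenotype tables are delimited text with a header row; the
delimiter is TAB by default and a comma is auto-detected from the header
line (never per-row). Gene sets use the standard GMT format. Result tables
round-trip through TSV with full float precision.
"""

from __future__ import annotations

import ast
import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    AssocResult,
    EffectCorrelation,
    ExpressionResult,
    GeneSet,
    GRSAssociation,
    GRSResult,
    PathwayResult,
    VariantInfo,
    result_fields,
)

_MISSING = {"", "NA", "NaN", "nan", "."}

RESULT_KINDS = (
    AssocResult,
    PathwayResult,
    GRSResult,
    GRSAssociation,
    ExpressionResult,
    EffectCorrelation,
)


def _sniff_delimiter(header_line: str) -> str:
    """TAB unless the header contains commas and no tabs."""
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return "\t"


@dataclasses.dataclass
class GenotypeReadReport:
    """What a genotype read kept, dropped and flagged."""

    n_samples: int = 0
    panel_rsids: list[str] = dataclasses.field(default_factory=list)
    unknown_columns: list[str] = dataclasses.field(default_factory=list)
    missing_panel_rsids: list[str] = dataclasses.field(default_factory=list)
    n_missing_calls: int = 0


def read_genotype_table(
    path: str | Path, panel: Sequence[VariantInfo]
) -> tuple[pd.DataFrame, GenotypeReadReport]:
    """Read a samples × SNPs dosage table (effect-allele counts 0/1/2).

    The first column is the sample identifier; remaining columns are rsIDs.
    Columns not in the panel are excluded from the returned frame and listed
    in the report rather than silently dropped. Any value other than
    0/1/2/NA is a hard error naming the offending row and column.

    Returns
    -------
    (DataFrame, GenotypeReadReport)
        Frame indexed by sample_id with one Int-dtype column per panel rsID
        present in the file (missing calls as NA).
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    sep = _sniff_delimiter(header_line.rstrip("\n"))
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.columns[0].lower() not in ("sample_id", "sample", "id", "iid"):
        raise ValueError(
            f"{path}: first column {raw.columns[0]!r} does not look like a sample id"
        )
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "sample_id"
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")

    panel_rsids = [v.rsid for v in panel]
    report = GenotypeReadReport(n_samples=len(raw))
    report.unknown_columns = [c for c in raw.columns if c not in panel_rsids]
    report.panel_rsids = [c for c in raw.columns if c in panel_rsids]
    report.missing_panel_rsids = [r for r in panel_rsids if r not in raw.columns]

    out = pd.DataFrame(index=raw.index)
    for rsid in report.panel_rsids:
        col = raw[rsid].str.strip()
        parsed = pd.array([pd.NA] * len(col), dtype="Int64")
        for i, val in enumerate(col):
            if val in _MISSING:
                report.n_missing_calls += 1
                continue
            if val not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: invalid dosage {val!r} at sample "
                    f"{raw.index[i]!r}, column {rsid!r} (expected 0/1/2/NA)"
                )
            parsed[i] = int(val)
        out[rsid] = parsed
    return out, report


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/covariate table (urate, age, sex, bmi, status).

    ``sex`` is normalised to {male, female}; ``status`` to
    {control, hyperuricemia, gout}. Missing phenotype columns are allowed
    (they simply restrict which analyses can run) but present columns are
    validated.
    """
    path = Path(path)
    with open(path) as fh:
        sep = _sniff_delimiter(fh.readline().rstrip("\n"))
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    if "sex" in df.columns:
        sex = df["sex"].astype(str).str.strip().str.lower()
        mapping = {"m": "male", "male": "male", "1": "male",
                   "f": "female", "female": "female", "0": "female"}
        bad = sex[~sex.isin(mapping) & ~sex.isin(_MISSING)]
        if len(bad):
            raise ValueError(f"{path}: unrecognised sex value {bad.iloc[0]!r}")
        df["sex"] = sex.map(mapping)
    if "status" in df.columns:
        status = df["status"].astype(str).str.strip().str.lower()
        allowed = {"control", "hyperuricemia", "gout", "hua"}
        bad = status[~status.isin(allowed) & ~status.isin(_MISSING)]
        if len(bad):
            raise ValueError(f"{path}: unrecognised status value {bad.iloc[0]!r}")
        df["status"] = status.replace({"hua": "hyperuricemia"})
    if "urate" in df.columns:
        urate = pd.to_numeric(df["urate"], errors="coerce")
        if (urate <= 0).any():
            raise ValueError(f"{path}: non-positive urate value")
        df["urate"] = urate
    return df


def assemble_cohort(genotypes: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Inner-join dosage and phenotype tables on sample_id."""
    genotypes = genotypes.copy()
    genotypes.index = genotypes.index.astype(str)
    cohort = phenotypes.join(genotypes, how="inner")
    if cohort.empty:
        raise ValueError("no overlapping sample_ids between genotypes and phenotypes")
    return cohort


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.

    Set order is preserved. Duplicate genes within a line are deduplicated
    (first occurrence wins) with a warning; a line with fewer than three
    fields is a hard error naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            set_id, name, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {set_id} deduplicated"
                )
            sets.append(GeneSet(set_id, name, tuple(unique)))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *s.genes]) + "\n")


def _result_kind(results: Sequence) -> type:
    kinds = {type(r) for r in results}
    if len(kinds) > 1:
        raise TypeError(f"mixed result kinds: {sorted(k.__name__ for k in kinds)}")
    (kind,) = kinds
    if kind not in RESULT_KINDS:
        raise TypeError(f"unsupported result kind {kind.__name__}")
    return kind


def write_results_table(results: Sequence, path: str | Path, kind: type | None = None) -> None:
    """Write a homogeneous list of result records to TSV.

    Column order is the dataclass field order; floats keep full precision so
    a round-trip read reproduces values exactly. An empty list needs an
    explicit ``kind`` to emit the header.
    """
    if kind is None:
        if not results:
            raise ValueError("empty result list: pass kind= to write a header-only file")
        kind = _result_kind(results)
    elif results:
        if _result_kind(results) is not kind:
            raise TypeError("results do not match declared kind")
    cols = result_fields(kind)
    rows = [{c: getattr(r, c) for c in cols} for r in results]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_table(path: str | Path, kind: type):
    """Read back a result table written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict(orient="records"):
        clean = {}
        for key, val in row.items():
            if isinstance(val, float) and np.isnan(val):
                val = None
            elif isinstance(val, str) and val.startswith(("(", "{", "[")):
                val = ast.literal_eval(val)  # tuples/dicts we wrote ourselves
            clean[key] = val
        if "flag" in clean and clean["flag"] is None:
            clean["flag"] = ""
        out.append(kind(**clean))
    return out


def read_config(path: str | Path) -> AnalysisConfig:
    """Read a flat key→value YAML file mirroring AnalysisConfig fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "bmi_bins" in data:
        data["bmi_bins"] = tuple(data["bmi_bins"])
    return AnalysisConfig(**data)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["bmi_bins"] = list(data["bmi_bins"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, default_flow_style=False)


def read_vcf_dosages(path: str | Path, panel: Sequence[VariantInfo]) -> pd.DataFrame:
    """Extract effect-allele dosages for panel rsIDs from a VCF (optional extra).

    Only biallelic records whose ID matches a panel rsID are used; the
    effect-allele count per genotype is derived from REF/ALT orientation.
    Requires cyvcf2.
    """
    from cyvcf2 import VCF  # lazy: optional dependency

    by_rsid = {v.rsid: v for v in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, list] = {}
    for record in vcf:
        if record.ID not in by_rsid or len(record.ALT) != 1:
            continue
        variant = by_rsid[record.ID]
        if variant.effect_allele == record.ALT[0]:
            flip = False
        elif variant.effect_allele == record.REF:
            flip = True
        else:
            continue  # effect allele not present at this site
        dosages = []
        for gt in record.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) != 2:
                dosages.append(pd.NA)
                continue
            alt_count = sum(alleles)
            dosages.append(2 - alt_count if flip else alt_count)
        data[record.ID] = dosages
    return pd.DataFrame(data, index=pd.Index(samples, name="sample_id"), dtype="Int64")
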