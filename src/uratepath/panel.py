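"""Default nine-SNP urate transporter panel and the two candidate gene sets.

The panel covers nine genes with transmembrane-transport function (PKD2 and
eight SLC-family transporters). MAFs are control-group minor-allele
frequencies; betas are the per-effect-allele serum urate effects (µmol/L)
estimated in males, which also serve as the weighted-GRS weights.

Both gene sets hold eight genes and share seven: GO:0015075 (ion
transmembrane transporter activity) carries PKD2 but not SLC16A9,
GO:0015291 (secondary active transmembrane transporter activity) carries
SLC16A9 but not PKD2.
"""

from __future__ import annotations

from .types import GeneSet, VariantInfo

DEFAULT_PANEL: tuple[VariantInfo, ...] = (
    VariantInfo("rs2728121", "PKD2", "C", 0.45, "3utr"),
    VariantInfo("rs13129697", "SLC2A9", "T", 0.47, "intron"),
    VariantInfo("rs2242206", "SLC16A9", "G", 0.40, "missense"),
    VariantInfo("rs1165165", "SLC17A3", "T", 0.14, "missense"),
    VariantInfo("rs3759053", "SLC22A11", "T", 0.06, "5upstream"),
    VariantInfo("rs1165196", "SLC17A1", "G", 0.19, "missense"),
    VariantInfo("rs11754288", "SLC17A4", "A", 0.17, "missense"),
    VariantInfo("rs1395", "SLC5A6", "G", 0.13, "missense"),
    VariantInfo("rs2071299", "SLC17A2", "G", 0.32, "missense"),
)

#: Per-effect-allele urate effect in males, µmol/L; default simulation betas
#: and default weighted-GRS weights.
MALE_BETA: dict[str, float] = {
    "rs2728121": -11.09,
    "rs13129697": 10.11,
    "rs2242206": -0.64,
    "rs1165165": 7.27,
    "rs3759053": 5.64,
    "rs1165196": -8.75,
    "rs11754288": -5.92,
    "rs1395": -1.68,
    "rs2071299": -1.41,
}

GO_0015075 = GeneSet(
    "GO:0015075",
    "ion transmembrane transporter activity",
    ("PKD2", "SLC2A9", "SLC17A3", "SLC22A11", "SLC17A1", "SLC17A4", "SLC5A6", "SLC17A2"),
)

GO_0015291 = GeneSet(
    "GO:0015291",
    "secondary active transmembrane transporter activity",
    ("SLC2A9", "SLC17A3", "SLC22A11", "SLC17A1", "SLC17A4", "SLC5A6", "SLC16A9", "SLC17A2"),
)

DEFAULT_GENE_SETS: tuple[GeneSet, ...] = (GO_0015075, GO_0015291)

GENE_TO_RSID: dict[str, str] = {v.gene: v.rsid for v in DEFAULT_PANEL}
RSID_TO_GENE: dict[str, str] = {v.rsid: v.gene for v in DEFAULT_PANEL}
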