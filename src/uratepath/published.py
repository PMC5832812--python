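"""Published reference values for the nine-SNP urate transporter panel.

These are the printed per-SNP and pathway-level association results that the
pipeline's pathway stage can regenerate from: feeding the per-SNP P_FDR
columns into the Simes combination and the rank-scaled FDR adjustment
reproduces every pathway-level value (the "reproduce-from-printed-values"
mode of :mod:`uratepath.reporting`).

Layout: ``SNP_RESULTS[contrast][stratum][rsid] = (effect, p, p_fdr)`` where
``effect`` is beta (µmol/L per allele) for the urate contrast and an odds
ratio otherwise. BMI-subgroup results exist for the urate contrast only.
``PATHWAY_RESULTS[contrast][stratum][set_id] = (p_simes, p_fdr)``.
"""

from __future__ import annotations

# --- per-SNP stratified results, gender strata -----------------------------

SNP_RESULTS: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "urate": {
        "male": {
            "rs2728121": (-11.09, 2.67e-06, 2.40e-05),
            "rs13129697": (10.11, 1.46e-05, 6.55e-05),
            "rs2242206": (-0.64, 0.921, 0.921),
            "rs1165165": (7.27, 0.045, 0.081),
            "rs3759053": (5.64, 0.171, 0.256),
            "rs1165196": (-8.75, 3.88e-03, 0.012),
            "rs11754288": (-5.92, 0.044, 0.100),
            "rs1395": (-1.68, 0.693, 0.780),
            "rs2071299": (-1.41, 0.549, 0.706),
        },
        "female": {
            "rs2728121": (-12.52, 0.011, 0.101),
            "rs13129697": (9.98, 0.026, 0.079),
            "rs2242206": (8.82, 0.069, 0.155),
            "rs1165165": (14.43, 0.017, 0.079),
            "rs3759053": (10.21, 0.340, 0.437),
            "rs1165196": (-5.78, 0.585, 0.585),
            "rs11754288": (-5.77, 0.508, 0.572),
            "rs1395": (7.83, 0.145, 0.260),
            "rs2071299": (3.77, 0.182, 0.273),
        },
        "total": {
            "rs2728121": (-11.18, 1.31e-07, 1.18e-06),
            "rs13129697": (10.43, 9.56e-06, 4.30e-05),
            "rs2242206": (2.03, 0.407, 0.524),
            "rs1165165": (9.24, 3.09e-03, 9.26e-03),
            "rs3759053": (7.11, 0.101, 0.151),
            "rs1165196": (-7.31, 6.24e-03, 0.014),
            "rs11754288": (-5.72, 0.046, 0.083),
            "rs1395": (1.72, 0.697, 0.784),
            "rs2071299": (0.73, 0.882, 0.882),
        },
        # BMI subgroups (urate contrast only)
        "bmi_under": {
            "rs2728121": (-13.03, 0.636, 0.954),
            "rs13129697": (21.05, 0.235, 0.424),
            "rs2242206": (-17.47, 0.202, 0.455),
            "rs1165165": (24.86, 0.062, 0.561),
            "rs3759053": (-9.15, 0.666, 0.856),
            "rs1165196": (-24.38, 0.096, 0.287),
            "rs11754288": (-28.94, 0.089, 0.400),
            "rs1395": (1.26, 0.990, 0.990),
            "rs2071299": (-1.79, 0.865, 0.973),
        },
        "bmi_normal": {
            "rs2728121": (-10.98, 1.29e-04, 1.16e-03),
            "rs13129697": (8.98, 0.034, 0.061),
            "rs2242206": (1.38, 0.793, 0.793),
            "rs1165165": (11.08, 0.015, 0.044),
            "rs3759053": (11.46, 0.139, 0.209),
            "rs1165196": (-11.65, 3.20e-03, 0.014),
            "rs11754288": (-9.99, 0.016, 0.035),
            "rs1395": (-2.48, 0.546, 0.702),
            "rs2071299": (-0.52, 0.784, 0.882),
        },
        "bmi_over": {
            "rs2728121": (-9.49, 3.46e-03, 0.016),
            "rs13129697": (12.82, 2.98e-05, 2.68e-04),
            "rs2242206": (1.17, 0.562, 0.722),
            "rs1165165": (8.96, 0.051, 0.152),
            "rs3759053": (4.08, 0.307, 0.553),
            "rs1165196": (-3.05, 0.449, 0.673),
            "rs11754288": (-2.18, 0.712, 0.712),
            "rs1395": (6.86, 0.160, 0.360),
            "rs2071299": (2.33, 0.613, 0.690),
        },
    },
    "gout_vs_hua": {
        "male": {
            "rs2728121": (0.81, 7.53e-03, 0.068),
            "rs13129697": (1.01, 0.908, 0.908),
            "rs2242206": (1.12, 0.130, 0.235),
            "rs1165165": (0.90, 0.339, 0.436),
            "rs3759053": (1.04, 0.768, 0.864),
            "rs1165196": (0.80, 0.046, 0.104),
            "rs11754288": (0.79, 0.031, 0.094),
            "rs1395": (0.88, 0.276, 0.414),
            "rs2071299": (0.80, 8.76e-03, 0.039),
        },
        "female": {
            "rs2728121": (0.70, 0.250, 1.000),
            "rs13129697": (1.08, 0.884, 0.995),
            "rs2242206": (1.22, 0.563, 1.000),
            "rs1165165": (0.81, 0.843, 1.000),
            "rs3759053": (0.77, 1.000, 1.000),
            "rs1165196": (1.09, 0.856, 1.000),
            "rs11754288": (0.51, 0.179, 1.000),
            "rs1395": (0.57, 0.317, 0.951),
            "rs2071299": (0.92, 0.880, 1.000),
        },
        "total": {
            "rs2728121": (0.81, 2.95e-03, 0.027),
            "rs13129697": (1.01, 0.888, 0.888),
            "rs2242206": (1.09, 0.242, 0.364),
            "rs1165165": (0.90, 0.286, 0.368),
            "rs3759053": (0.94, 0.733, 0.825),
            "rs1165196": (0.79, 0.018, 0.041),
            "rs11754288": (0.77, 9.85e-03, 0.030),
            "rs1395": (0.79, 0.038, 0.068),
            "rs2071299": (0.81, 5.17e-03, 0.023),
        },
    },
    "gout_vs_control": {
        "male": {
            "rs2728121": (0.67, 8.50e-09, 7.65e-08),
            "rs13129697": (1.20, 0.011, 0.019),
            "rs2242206": (1.10, 0.201, 0.258),
            "rs1165165": (0.99, 0.960, 0.960),
            "rs3759053": (1.23, 0.131, 0.197),
            "rs1165196": (0.68, 5.07e-05, 2.28e-04),
            "rs11754288": (0.69, 2.38e-04, 7.15e-04),
            "rs1395": (0.89, 0.318, 0.357),
            "rs2071299": (0.79, 2.17e-03, 4.88e-03),
        },
        "female": {
            "rs2728121": (0.55, 0.047, 0.421),
            "rs13129697": (1.22, 0.572, 1.000),
            "rs2242206": (1.54, 0.150, 0.675),
            "rs1165165": (0.93, 1.000, 1.000),
            "rs3759053": (0.96, 1.000, 1.000),
            "rs1165196": (1.19, 0.589, 1.000),
            "rs11754288": (0.53, 0.253, 0.760),
            "rs1395": (0.75, 0.672, 1.000),
            "rs2071299": (1.05, 0.880, 1.000),
        },
        "total": {
            "rs2728121": (0.66, 7.51e-11, 6.76e-10),
            "rs13129697": (1.19, 9.19e-03, 0.017),
            "rs2242206": (1.12, 0.068, 0.101),
            "rs1165165": (1.00, 0.963, 0.963),
            "rs3759053": (1.14, 0.350, 0.394),
            "rs1165196": (0.71, 1.48e-04, 6.66e-04),
            "rs11754288": (0.71, 1.72e-04, 5.15e-04),
            "rs1395": (0.87, 0.160, 0.206),
            "rs2071299": (0.83, 7.60e-03, 0.017),
        },
    },
}

# --- published pathway-level results (for cross-checking) ------------------

PATHWAY_RESULTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "urate": {
        "male": {"GO:0015075": (1.92e-04, 3.84e-04), "GO:0015291": (5.24e-04, 5.24e-04)},
        "female": {"GO:0015075": (0.269, 0.538), "GO:0015291": (0.317, 0.317)},
        "total": {"GO:0015075": (9.42e-06, 1.88e-05), "GO:0015291": (3.44e-04, 3.44e-04)},
        "bmi_under": {"GO:0015075": (0.990, 0.990), "GO:0015291": (0.898, 1.000)},
        "bmi_normal": {"GO:0015075": (0.009, 0.018), "GO:0015291": (0.115, 0.115)},
        "bmi_over": {"GO:0015075": (2.15e-03, 2.15e-03), "GO:0015291": (2.15e-03, 2.15e-03)},
    },
    "gout_vs_hua": {
        "male": {"GO:0015075": (0.208, 0.416), "GO:0015291": (0.277, 0.277)},
        "female": {"GO:0015075": (1.000, 1.000), "GO:0015291": (1.000, 1.000)},
        "total": {"GO:0015075": (0.079, 0.158), "GO:0015291": (0.111, 0.111)},
    },
    "gout_vs_control": {
        "male": {"GO:0015075": (6.12e-07, 1.22e-06), "GO:0015291": (1.83e-03, 1.83e-03)},
        "female": {"GO:0015075": (1.000, 1.000), "GO:0015291": (1.000, 1.000)},
        "total": {"GO:0015075": (5.41e-09, 1.08e-08), "GO:0015291": (2.66e-03, 2.66e-03)},
    },
}


def snp_pfdr(contrast: str, stratum: str) -> dict[str, float]:
    """Per-SNP published P_FDR values for one stratum × contrast cell."""
    cell = SNP_RESULTS[contrast][stratum]
    return {rsid: vals[2] for rsid, vals in cell.items()}


def snp_effect(contrast: str, stratum: str) -> dict[str, float]:
    """Per-SNP published effect sizes (beta or OR) for one cell."""
    cell = SNP_RESULTS[contrast][stratum]
    return {rsid: vals[0] for rsid, vals in cell.items()}
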