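"""Published reference summary statistics for the 24-pair HCC targeted bis-seq cohort.

These are the printed, amplicon- and gene-level summary tables from the study
this package operationalises: per-amplicon methylation means/SDs and
Bonferroni-adjusted p-values for 29 amplicons over 20 genes (24 tumor /
adjacent non-tumor pairs), qRT-PCR log2 expression summaries for the two
validated genes (GRASP, TSPYL5) in the 24-pair discovery and 42-pair
validation sets, the miRNA screen group means for miRNAs targeting those
genes, and the pooled 66-pair methylation/expression concordance counts.

Only summary statistics are embedded — no per-sample data exists in print.
They serve two purposes:

* arithmetic consistency checks (difference = tumor mean − non-tumor mean,
  signed fold changes from log2 means, concordance percentages from counts);
* calibration of the "paper-like" synthetic scenario, whose amplicon
  baselines and shifts are taken from :data:`AMPLICON_TABLE`.
"""

from __future__ import annotations

import pandas as pd

#: Per-amplicon targeted bis-seq summary: non-tumor / tumor mean methylation
#: percent (SD), tumor − non-tumor difference in percentage points, and the
#: Bonferroni-adjusted paired-t p-value (family of 29 amplicons, 24 pairs).
_AMPLICON_ROWS = [
    # gene, amplicon, n_cpg, mean_nt, sd_nt, mean_t, sd_t, difference, p_adj
    ("CDKL2", "CDKL2.a", 11, 6.49, 8.35, 33.52, 18.80, 27.03, 2.50e-04),
    ("CDKL2", "CDKL2.b", 15, 7.59, 11.57, 41.29, 21.98, 33.70, 1.94e-04),
    ("CDKL2", "CDKL2.c", 27, 13.20, 13.50, 37.15, 20.68, 23.95, 2.83e-02),
    ("CLCN1", "CLCN1", 28, 16.31, 10.83, 47.84, 21.93, 31.53, 3.01e-04),
    ("DUOX1", "DUOX1", 36, 16.93, 16.93, 36.98, 24.43, 20.05, 2.77e-01),
    ("GRASP", "GRASP.a", 24, 12.66, 8.70, 42.45, 23.56, 29.79, 3.92e-04),
    ("ILDR2", "ILDR2.a", 23, 7.66, 4.22, 43.18, 27.32, 35.52, 4.21e-05),
    ("MAST1", "MAST1.a", 16, 16.40, 20.56, 59.15, 33.23, 42.75, 4.99e-04),
    ("MAST1", "MAST1.b", 2, 10.42, 10.98, 34.74, 21.02, 24.32, 4.33e-03),
    ("MAST1", "MAST1.c", 19, 15.25, 8.44, 38.92, 14.03, 23.67, 5.15e-05),
    ("NKX6-2", "NKX6-2.b", 24, 26.17, 9.56, 54.97, 17.70, 28.80, 4.25e-05),
    ("OTX1", "OTX1.a", 8, 22.53, 9.14, 52.15, 24.09, 29.62, 2.63e-03),
    ("OTX1", "OTX1.b", 28, 17.68, 12.10, 49.60, 17.44, 31.92, 1.85e-04),
    ("SERHL", "SERHL.a", 16, 11.94, 4.38, 35.71, 13.19, 23.77, 3.82e-07),
    ("SERHL", "SERHL.b", 11, 4.86, 2.26, 17.15, 12.24, 12.29, 1.08e-03),
    ("SPAG6", "SPAG6.b", 53, 16.07, 5.05, 34.12, 15.67, 18.04, 1.59e-03),
    ("SPDYA", "SPDYA.b", 11, 46.93, 17.40, 73.91, 18.14, 26.98, 1.29e-02),
    ("TRIL", "TRIL.a", 16, 18.13, 6.02, 53.25, 20.58, 35.12, 1.01e-05),
    ("TRIL", "TRIL.b", 22, 13.88, 8.85, 36.95, 17.75, 23.07, 2.22e-03),
    ("TRIL", "TRIL.c", 17, 9.73, 6.70, 41.44, 17.52, 31.71, 6.62e-06),
    ("TRIL", "TRIL.e", 44, 12.10, 10.22, 38.52, 19.07, 26.42, 1.55e-03),
    ("TSPYL5", "TSPYL5", 57, 13.83, 12.12, 41.21, 18.79, 27.38, 8.09e-04),
    ("USP44", "USP44.c", 9, 61.31, 10.17, 73.45, 10.01, 12.14, 6.81e-03),
    ("ZNF397OS", "ZNF397OS.a", 32, 13.76, 11.59, 38.94, 18.21, 25.18, 3.10e-04),
    ("FAM66B", "FAM66B", 13, 91.18, 3.59, 71.89, 17.30, -19.29, 9.49e-04),
    ("KCNQ2", "KCNQ2", 44, 74.06, 14.65, 45.21, 22.68, -28.85, 3.99e-03),
    ("PROKR2", "PROKR2", 14, 83.57, 14.68, 65.11, 12.97, -18.46, 1.11e-02),
    ("PTPRN2", "PTPRN2", 8, 74.68, 11.71, 53.60, 17.39, -21.08, 6.50e-03),
    ("REXO1L2P", "REXO1L2P", 12, 84.14, 14.58, 53.98, 22.99, -30.16, 1.75e-03),
]

AMPLICON_TABLE = pd.DataFrame(
    _AMPLICON_ROWS,
    columns=[
        "gene", "amplicon_name", "n_cpg", "mean_nontumor", "sd_nontumor",
        "mean_tumor", "sd_tumor", "difference", "p_adjusted",
    ],
)

#: qRT-PCR log2 expression summaries (mean, SD) for the discovery (24 pairs)
#: and validation (42 pairs) sets, with the printed signed fold change and
#: one-sided p-value.  Log2 expression is −ΔCt against GAPDH.
QPCR_TABLE = pd.DataFrame(
    [
        ("GRASP", "24 pairs", 24, -7.21, 1.30, -6.51, 0.89, -1.62, 2.75e-02),
        ("GRASP", "42 pairs", 42, -7.49, 1.41, -6.52, 1.26, -1.96, 1.53e-03),
        ("TSPYL5", "24 pairs", 24, -9.67, 1.61, -8.79, 1.13, -1.85, 3.68e-02),
        ("TSPYL5", "42 pairs", 42, -9.71, 1.63, -8.94, 1.22, -1.71, 1.25e-02),
    ],
    columns=[
        "gene", "set_label", "n_pairs", "mean_tumor", "sd_tumor",
        "mean_nontumor", "sd_nontumor", "fold_change", "p",
    ],
)

#: Significantly differentially expressed miRNAs targeting GRASP / TSPYL5:
#: group means (log2), SDs, Bonferroni-adjusted p and the printed direction.
MIRNA_TABLE = pd.DataFrame(
    [
        ("GRASP", "hsa-miR-320b", -8.97, 0.75, -10.10, 0.96, 8.95e-03, "down"),
        ("TSPYL5", "hsa-miR-193a-3p", -8.21, 1.06, -9.53, 0.88, 7.58e-03, "down"),
        ("TSPYL5", "hsa-let-7g", -3.43, 0.67, -4.11, 0.55, 2.32e-02, "down"),
        ("TSPYL5", "hsa-let-7a", -6.43, 0.64, -7.35, 0.86, 1.42e-02, "down"),
        ("TSPYL5", "hsa-let-7e", -4.05, 0.82, -4.78, 0.63, 3.86e-02, "down"),
        ("TSPYL5", "hsa-let-7c", -6.88, 0.50, -8.62, 1.08, 2.24e-04, "down"),
        ("TSPYL5", "hsa-let-7b", -4.53, 0.86, -5.89, 1.18, 8.94e-03, "down"),
        ("TSPYL5", "hsa-miR-320b", -8.97, 0.75, -10.10, 0.96, 8.95e-03, "down"),
        ("TSPYL5", "hsa-miR-27b", -5.69, 0.79, -6.48, 0.70, 2.84e-02, "down"),
    ],
    columns=[
        "gene", "mirna", "mean_nontumor", "sd_nontumor",
        "mean_tumor", "sd_tumor", "p_adjusted", "direction",
    ],
)

#: Pooled 66-pair integrative counts: pairs with tumor hypermethylation, and
#: among those, pairs with tumor mRNA under-expression; plus the published
#: methylation–expression correlation over the cohort.
CONCORDANCE_COUNTS = pd.DataFrame(
    [
        ("GRASP", 66, 65, 45, -0.394, 0.007),
        ("TSPYL5", 66, 64, 47, -0.415, 0.004),
    ],
    columns=[
        "gene", "n_pairs", "n_hypermethylated", "n_under_expressed",
        "pearson_r", "r_pvalue",
    ],
)

#: Tumor-tissue mean methylation fractions (0–1 scale) for the two Chr6q genes
#: whose tumors with copy-number loss showed reduced methylation: group means
#: for no-loss vs loss tumors, with the published two-sample p-value.
CNV_LOSS_METHYLATION = pd.DataFrame(
    [
        ("RGS17", 0.54, 0.41, 0.02),
        ("NR2E1", 0.53, 0.43, 0.05),
    ],
    columns=["gene", "mean_noloss", "mean_loss", "p"],
)

#: Oncomine-style tissue-group log2 median-centered expression levels for the
#: two validated genes (tumor / precursor / normal liver means).
TISSUE_EXPRESSION_MEANS = pd.DataFrame(
    [
        ("GRASP", 1.828, 2.210, 2.134),
        ("TSPYL5", -0.148, 1.585, 1.527),
    ],
    columns=["gene", "mean_tumor", "mean_precursor", "mean_normal"],
)
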