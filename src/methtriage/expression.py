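"""qRT-PCR expression quantification and cross-tissue expression comparison.

Two expression layers feed the triage:

* **qRT-PCR (ΔCt)** on the paired cohort: log2 expression is defined as
  −ΔCt = −(Ct_target − Ct_reference) against a housekeeping reference, so
  higher values mean more transcript.  Tumor vs non-tumor contrasts use a
  one-sided paired Student's t whose direction is bound to the gene's
  methylation call (under-expression expected for hypermethylated genes,
  over-expression for hypomethylated ones), and a signed linear fold change
  −2^|Δ| / +2^|Δ| with Δ the difference of group log2 means.

* **Per-array expression matrices** (public compendium style): linear
  values are log2-transformed, median-centered per array and scaled to unit
  SD per array, then tumor vs precursor and tumor vs normal contrasts use
  an unpaired pooled-variance one-sided Student's t.  A gene is
  "consistently" differentially expressed only when both contrasts are
  significant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io import paired_patients
from .methylation import paired_t_arrays

QPCR_COLUMNS = ["gene", "set_label", "n_pairs", "mean_tumor", "sd_tumor",
                "mean_nontumor", "sd_nontumor", "fold_change", "p", "direction"]


def log2_expression(ct_target: float, ct_reference: float) -> float:
    """log2 expression = −ΔCt = −(Ct_target − Ct_reference).

    Missing Ct (NaN) propagates as NaN; Ct values must lie in (0, 45)
    (the qPCR cycle range) when present.
    """
    if ct_target is None or ct_reference is None:
        return float("nan")
    if math.isnan(ct_target) or math.isnan(ct_reference):
        return float("nan")
    for name, ct in (("target", ct_target), ("reference", ct_reference)):
        if not (0 < ct < 45):
            raise ValidationError(f"Ct {name}={ct} outside the valid cycle range (0, 45)")
    return -(ct_target - ct_reference)


def ct_table_to_expression(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Convert a Ct table to per-sample log2 expression, dropping missing rows."""
    vals = [
        (r.sample_id, r.gene, log2_expression(r.ct_target, r.ct_reference))
        for r in ct_table.itertuples()
    ]
    df = pd.DataFrame(vals, columns=["sample_id", "gene", "log2_expr"])
    return df.dropna(subset=["log2_expr"]).reset_index(drop=True)


def signed_fold_change(mean_tumor: float, mean_nontumor: float) -> float:
    """Signed linear fold from log2 group means.

    Δ = tumor − non-tumor (log2).  Returns +2^Δ when Δ ≥ 0 (higher in
    tumor) and −2^(−Δ) when Δ < 0 (lower in tumor); |fold| ≥ 1 always and
    equal means give +1.
    """
    delta = mean_tumor - mean_nontumor
    if not np.isfinite(delta):
        raise ValidationError("fold change requires finite group means")
    return 2.0 ** delta if delta >= 0 else -(2.0 ** (-delta))


def one_sided_paired_t(values_tumor, values_nontumor, direction: str) -> float:
    """One-sided paired t p-value in the stated direction.

    direction='under' tests tumor < non-tumor (lower tail of t);
    direction='over' tests tumor > non-tumor (upper tail).
    """
    if direction not in ("under", "over"):
        raise ValidationError(f"direction must be 'under' or 'over', got {direction!r}")
    tumor = np.asarray(values_tumor, dtype=float)
    nontumor = np.asarray(values_nontumor, dtype=float)
    if tumor.ndim != 1 or tumor.shape != nontumor.shape:
        raise ValidationError("paired vectors must be 1-D and patient-aligned")
    if len(tumor) < 2:
        raise InsufficientDataError(f"one-sided paired t requires >= 2 pairs, got {len(tumor)}")
    _, t, _ = paired_t_arrays(tumor, nontumor)
    dof = len(tumor) - 1
    return float(stats.t.cdf(t, dof) if direction == "under" else stats.t.sf(t, dof))


@dataclass(frozen=True)
class GroupComparison:
    """Tumor vs non-tumor qPCR summary for one gene in one sample set."""

    gene: str
    set_label: str
    n_pairs: int
    mean_tumor: float
    sd_tumor: float
    mean_nontumor: float
    sd_nontumor: float
    fold_change: float
    p: float
    direction: str  # the tested direction ('under'/'over') or 'two_sided'


def group_comparison(expression: pd.DataFrame, manifest: pd.DataFrame, gene: str,
                     direction: str | None, set_label: str | None = None) -> GroupComparison:
    """Paired qPCR contrast for one gene.

    ``direction`` comes from the gene's methylation call; when None the test
    falls back to two-sided with a warning.  Pairs in which either member
    lacks a value for the gene are excluded.
    """
    sub = expression[expression.gene == gene].set_index("sample_id")["log2_expr"]
    pairs = paired_patients(manifest)
    t_vals, n_vals = [], []
    for pr in pairs.itertuples():
        tv, nv = sub.get(pr.tumor_sample, np.nan), sub.get(pr.nontumor_sample, np.nan)
        if pd.notna(tv) and pd.notna(nv):
            t_vals.append(tv)
            n_vals.append(nv)
    if len(t_vals) < 2:
        raise InsufficientDataError(f"gene {gene}: {len(t_vals)} complete pair(s) < 2")
    t_arr, n_arr = np.array(t_vals), np.array(n_vals)
    if direction is None:
        warnings.warn(f"gene {gene}: no methylation direction; using two-sided test")
        _, _, p = paired_t_arrays(t_arr, n_arr)
        tested = "two_sided"
    else:
        p = one_sided_paired_t(t_arr, n_arr, direction)
        tested = direction
    return GroupComparison(
        gene=gene,
        set_label=set_label or f"{len(t_vals)} pairs",
        n_pairs=len(t_vals),
        mean_tumor=float(t_arr.mean()), sd_tumor=float(t_arr.std(ddof=1)),
        mean_nontumor=float(n_arr.mean()), sd_nontumor=float(n_arr.std(ddof=1)),
        fold_change=signed_fold_change(t_arr.mean(), n_arr.mean()),
        p=float(p), direction=tested,
    )


def normalize_expression_matrix(raw: pd.DataFrame,
                                pseudo_floor: float | None = None) -> pd.DataFrame:
    """log2-transform then median-center and unit-SD-scale each array (column).

    ``raw`` holds strictly positive linear values (genes x arrays).  Zeros or
    negatives are lifted to ``pseudo_floor`` (default: half the smallest
    positive value in the matrix).  A constant array raises, naming it.
    """
    mat = raw.astype(float).copy()
    if (mat <= 0).any().any():
        if pseudo_floor is None:
            positive = mat.to_numpy()[mat.to_numpy() > 0]
            if positive.size == 0:
                raise ValidationError("expression matrix has no positive value")
            pseudo_floor = float(positive.min()) / 2.0
        mat = mat.clip(lower=pseudo_floor)
    logm = np.log2(mat)
    sds = logm.std(axis=0, ddof=1)
    for arr, sd in sds.items():
        if sd == 0 or not np.isfinite(sd):
            raise ValidationError(f"array {arr!r} is constant after log2; cannot scale")
    return (logm - logm.median(axis=0)) / sds


TISSUE_LABELS = ("consistent", "partial", "none", "unavailable")


def compare_tissue_groups(norm: pd.DataFrame, groups, direction="under",
                          alpha: float = 0.05) -> pd.DataFrame:
    """Tumor vs precursor and tumor vs normal contrasts per gene.

    Parameters
    ----------
    norm
        Normalized matrix (genes x arrays).
    groups
        Mapping array -> tissue in {tumor, precursor, normal}.
    direction
        'under'/'over', or a mapping gene -> direction (genes absent from
        the mapping are tested two-sided with a warning).

    Returns one row per gene: group means, one-sided pooled-variance p per
    contrast, and a label — ``consistent`` (both contrasts significant),
    ``partial`` (exactly one), ``none`` (neither), ``unavailable`` (no
    testable contrast; a group with < 2 arrays skips its contrast).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    cols = {t: [a for a in norm.columns if groups.get(a) == t]
            for t in ("tumor", "precursor", "normal")}
    rows = []
    for gene in norm.index:
        if isinstance(direction, str) or direction is None:
            gene_dir = direction
        else:
            gene_dir = direction.get(gene)
        vals = {t: norm.loc[gene, c].to_numpy(dtype=float) for t, c in cols.items()}
        row = {"gene": gene,
               "mean_tumor": np.nan, "mean_precursor": np.nan, "mean_normal": np.nan,
               "p_vs_precursor": np.nan, "p_vs_normal": np.nan}
        for t in ("tumor", "precursor", "normal"):
            if len(vals[t]):
                row[f"mean_{t}"] = float(np.mean(vals[t]))
        n_sig, n_tested = 0, 0
        for other in ("precursor", "normal"):
            if len(vals["tumor"]) < 2 or len(vals[other]) < 2:
                continue  # contrast skipped, stays NaN
            if gene_dir == "under":
                alt = "less"
            elif gene_dir == "over":
                alt = "greater"
            else:
                warnings.warn(f"gene {gene}: no direction; two-sided tissue contrast")
                alt = "two-sided"
            p = float(stats.ttest_ind(vals["tumor"], vals[other], equal_var=True,
                                      alternative=alt).pvalue)
            row[f"p_vs_{other}"] = p
            n_tested += 1
            n_sig += p <= alpha
        if n_tested == 0:
            row["label"] = "unavailable"
        elif n_sig == n_tested and n_sig > 0:
            # with one testable contrast, both-significant degrades gracefully
            row["label"] = "consistent" if n_tested == 2 else "partial"
        elif n_sig > 0:
            row["label"] = "partial"
        else:
            row["label"] = "none"
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "mean_tumor", "mean_precursor",
                                       "mean_normal", "p_vs_precursor",
                                       "p_vs_normal", "label"])


class PairedExpressionModel:
    """qRT-PCR paired expression contrasts for a set of genes.

    Built from a Ct table and the cohort manifest; :meth:`fit` runs the
    one-sided paired contrast per gene with directions taken from the
    methylation stage.
    """

    def __init__(self, ct_table: pd.DataFrame, manifest: pd.DataFrame):
        self.ct_table = ct_table
        self.manifest = manifest
        self.expression = ct_table_to_expression(ct_table)

    def fit(self, directions: dict | None = None,
            set_label: str | None = None) -> "ExpressionResults":
        directions = directions or {}
        comps = []
        for gene in sorted(self.expression.gene.unique()):
            comps.append(group_comparison(self.expression, self.manifest, gene,
                                          directions.get(gene), set_label=set_label))
        return ExpressionResults(comps, self.expression, self.manifest)


class ExpressionResults:
    """Fitted per-gene qPCR comparisons."""

    def __init__(self, comparisons: list[GroupComparison], expression: pd.DataFrame,
                 manifest: pd.DataFrame):
        self.comparisons = comparisons
        self.expression = expression
        self.manifest = manifest

    @property
    def table(self) -> pd.DataFrame:
        from dataclasses import asdict
        df = pd.DataFrame([asdict(c) for c in self.comparisons])
        return df[QPCR_COLUMNS] if len(df) else pd.DataFrame(columns=QPCR_COLUMNS)

    def summary(self) -> str:
        lines = ["Paired qRT-PCR expression (log2 = -dCt)",
                 "=" * 60,
                 f"{'gene':<10}{'set':<12}{'fold':>8}{'p':>11}  test"]
        for c in self.comparisons:
            lines.append(f"{c.gene:<10}{c.set_label:<12}{c.fold_change:>8.2f}"
                         f"{c.p:>11.3g}  {c.direction}")
        return "\n".join(lines)
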