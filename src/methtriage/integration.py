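"""Integrative screens linking methylation to expression, CNVs, miRNAs and chromatin.

These are the filters applied after an amplicon passes differential
methylation: does expression move the opposite way in the same pairs
(concordance and Pearson correlation), could a copy-number loss rather
than methylation explain repression, is a targeting miRNA over-expressed
in tumors, and does the chromatin context (histone marks + DNase
hypersensitivity) corroborate the inferred regulatory state?
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io import CHROMATIN_MARKS, AmpliconDef, PeakSet, paired_patients
from .methylation import bonferroni_adjust, paired_t_arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceSummary:
    """Per-gene paired methylation/expression concordance.

    A pair is *hypermethylated* when tumor methylation exceeds the paired
    non-tumor value (ties count as not hypermethylated) and
    *under-expressed* when tumor log2 expression is below the paired
    non-tumor value.  ``percent_concordant`` is the share of
    hypermethylated pairs that are also under-expressed, to 1 decimal.
    Pearson r is computed over per-pair (Δmethylation, Δexpression).
    """

    gene: str
    n_pairs: int
    n_hypermethylated: int
    n_under_expressed: int
    percent_concordant: float  # NaN when no hypermethylated pair
    pearson_r: float
    r_pvalue: float
    undefined: bool = False


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from t = r·√((n−2)/(1−r²))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("correlation inputs must be aligned 1-D vectors")
    if len(x) < 3:
        raise InsufficientDataError(f"correlation requires n >= 3, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def concordance_classify(gene: str, meth_tumor, meth_nontumor, expr_tumor,
                         expr_nontumor, correlation_on: str = "differences"
                         ) -> ConcordanceSummary:
    """Classify each pair and summarise concordance for one gene.

    Inputs are patient-aligned vectors: methylation percent and log2
    expression for tumor and non-tumor members of each pair.
    ``correlation_on`` selects the Pearson operands: per-pair
    ``"differences"`` (default) or tumor ``"levels"``.
    """
    mt = np.asarray(meth_tumor, dtype=float)
    mn = np.asarray(meth_nontumor, dtype=float)
    et = np.asarray(expr_tumor, dtype=float)
    en = np.asarray(expr_nontumor, dtype=float)
    if not (mt.shape == mn.shape == et.shape == en.shape) or mt.ndim != 1:
        raise ValidationError("concordance inputs must be aligned 1-D vectors")
    n = len(mt)
    d_meth = mt - mn
    d_expr = et - en
    hyper = d_meth > 0          # ties are not hypermethylated
    under = d_expr < 0          # ties are not under-expressed
    n_hyper = int(hyper.sum())
    n_under = int((hyper & under).sum())
    if n_hyper == 0:
        logger.warning("gene %s: no hypermethylated pair; concordance undefined", gene)
        pct, undefined = float("nan"), True
    else:
        pct, undefined = round(100.0 * n_under / n_hyper, 1), False
    if correlation_on == "differences":
        rx, ry = d_meth, d_expr
    elif correlation_on == "levels":
        rx, ry = mt, et
    else:
        raise ValidationError("correlation_on must be 'differences' or 'levels'")
    try:
        r, rp = pearson_correlation(rx, ry)
    except (InsufficientDataError, ValidationError):
        r, rp = float("nan"), float("nan")
    return ConcordanceSummary(gene=gene, n_pairs=n, n_hypermethylated=n_hyper,
                              n_under_expressed=n_under, percent_concordant=pct,
                              pearson_r=r, r_pvalue=rp, undefined=undefined)


@dataclass
class ChiSquareResult:
    chi_square: float
    df: int
    p: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    low_expected: bool  # any expected cell count < 5


def cnv_expression_association(cnv_states=None, expr_directions=None, *,
                               table: pd.DataFrame | None = None) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) of CNV state x expression direction.

    Either give two aligned per-sample label vectors, or a prebuilt
    contingency ``table``.  Empty rows/columns are dropped; fewer than two
    non-empty categories on either axis is degenerate and raises.
    """
    if table is None:
        if cnv_states is None or expr_directions is None:
            raise ValidationError("need either label vectors or a contingency table")
        table = pd.crosstab(pd.Series(list(cnv_states), name="cnv"),
                            pd.Series(list(expr_directions), name="expression"))
    observed = pd.DataFrame(table).astype(float)
    observed = observed.loc[observed.sum(axis=1) > 0, observed.sum(axis=0) > 0]
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValidationError(
            f"degenerate contingency table {observed.shape}; need >= 2 categories per axis")
    chi2, p, dof, expected = stats.chi2_contingency(observed.to_numpy(), correction=False)
    expected = pd.DataFrame(expected, index=observed.index, columns=observed.columns)
    low = bool((expected.to_numpy() < 5).any())
    if low:
        warnings.warn("chi-square: some expected cell counts < 5; p is approximate")
    return ChiSquareResult(chi_square=float(chi2), df=int(dof), p=float(p),
                           observed=observed, expected=expected, low_expected=low)


@dataclass(frozen=True)
class CnvLossComparison:
    """Tumor methylation (0-1 scale) in CNV-loss vs no-loss tumors."""

    gene: str
    n_loss: int
    n_noloss: int
    mean_loss: float
    mean_noloss: float
    t_stat: float
    p: float
    skipped: bool = False
    reason: str = ""


def methylation_by_cnv_loss(gene: str, meth_loss, meth_noloss) -> CnvLossComparison:
    """Two-sided pooled-variance t comparing tumor methylation by CNV-loss status.

    ``meth_loss`` / ``meth_noloss`` are tumor methylation fractions (0-1).
    With fewer than 2 tumors in either group the comparison is skipped and
    returned with a flag rather than raised, so a cohort without losses
    still triages.
    """
    loss = np.asarray(meth_loss, dtype=float)
    noloss = np.asarray(meth_noloss, dtype=float)
    if len(loss) < 2 or len(noloss) < 2:
        return CnvLossComparison(
            gene=gene, n_loss=len(loss), n_noloss=len(noloss),
            mean_loss=float(loss.mean()) if len(loss) else float("nan"),
            mean_noloss=float(noloss.mean()) if len(noloss) else float("nan"),
            t_stat=float("nan"), p=float("nan"), skipped=True,
            reason=f"need >= 2 tumors per group (loss={len(loss)}, no-loss={len(noloss)})")
    res = stats.ttest_ind(loss, noloss, equal_var=True)
    return CnvLossComparison(gene=gene, n_loss=len(loss), n_noloss=len(noloss),
                             mean_loss=float(loss.mean()), mean_noloss=float(noloss.mean()),
                             t_stat=float(res.statistic), p=float(res.pvalue))


@dataclass(frozen=True)
class MirnaScreenResult:
    """Tumor vs non-tumor contrast for one miRNA targeting one gene."""

    gene: str
    mirna: str
    n_pairs: int
    mean_tumor: float
    mean_nontumor: float
    log2_fc: float       # tumor − non-tumor mean (log2)
    p_raw: float
    p_adjusted: float
    direction: str       # up / down / none


@dataclass
class GeneMirnaScreen:
    """Gene-level miRNA screen outcome: is any targeting miRNA up in tumors?"""

    gene: str
    results: list[MirnaScreenResult] = field(default_factory=list)
    confounded: bool = False
    reason: str = ""

    @property
    def table(self) -> pd.DataFrame:
        from dataclasses import asdict
        cols = ["gene", "mirna", "n_pairs", "mean_tumor", "mean_nontumor",
                "log2_fc", "p_raw", "p_adjusted", "direction"]
        return (pd.DataFrame([asdict(r) for r in self.results])[cols]
                if self.results else pd.DataFrame(columns=cols))


def mirna_target_screen(gene: str, target_map: pd.DataFrame, mirna_matrix: pd.DataFrame,
                        manifest: pd.DataFrame, detect_fraction: float = 0.5,
                        alpha: float = 0.05) -> GeneMirnaScreen:
    """Screen miRNAs targeting ``gene`` for tumor over-expression.

    miRNAs detected (non-missing) in at least ``detect_fraction`` of the
    paired samples are tested with a paired t on complete pairs; p-values
    are Bonferroni-adjusted within the gene.  A miRNA is ``up`` when its
    log2 fold change (tumor − non-tumor mean) is positive and adjusted
    p ≤ alpha, ``down`` when negative and significant, otherwise ``none``.
    The gene is flagged confounded iff any targeting miRNA is ``up``.
    """
    targeting = target_map.loc[target_map.gene == gene, "mirna"].unique().tolist()
    if not targeting:
        return GeneMirnaScreen(gene=gene, reason="gene absent from target map")
    pairs = paired_patients(manifest)
    paired_samples = (pairs.tumor_sample.tolist() + pairs.nontumor_sample.tolist())
    paired_samples = [s for s in paired_samples if s in mirna_matrix.columns]
    if not paired_samples:
        return GeneMirnaScreen(gene=gene, reason="no paired sample in miRNA matrix")

    tested = []
    for mirna in targeting:
        if mirna not in mirna_matrix.index:
            continue
        row = mirna_matrix.loc[mirna, paired_samples]
        if row.notna().mean() < detect_fraction:
            continue
        t_vals, n_vals = [], []
        for pr in pairs.itertuples():
            tv = mirna_matrix.loc[mirna].get(pr.tumor_sample, np.nan)
            nv = mirna_matrix.loc[mirna].get(pr.nontumor_sample, np.nan)
            if pd.notna(tv) and pd.notna(nv):
                t_vals.append(float(tv))
                n_vals.append(float(nv))
        if len(t_vals) < 2:
            continue
        _, _, p = paired_t_arrays(np.array(t_vals), np.array(n_vals))
        tested.append((mirna, np.mean(t_vals), np.mean(n_vals),
                       float(np.mean(t_vals) - np.mean(n_vals)), float(p),
                       len(t_vals)))
    if not tested:
        return GeneMirnaScreen(gene=gene, reason="no detectable targeting miRNA")

    p_adj = bonferroni_adjust([t[4] for t in tested])
    results = []
    for (mirna, mt, mn, fc, p_raw, n), pa in zip(tested, p_adj):
        if pa <= alpha:
            direction = "up" if fc > 0 else "down"
        else:
            direction = "none"
        results.append(MirnaScreenResult(gene=gene, mirna=mirna, n_pairs=n,
                                         mean_tumor=float(mt), mean_nontumor=float(mn),
                                         log2_fc=fc, p_raw=p_raw, p_adjusted=float(pa),
                                         direction=direction))
    confounded = any(r.direction == "up" for r in results)
    reason = ("targeting miRNA significantly over-expressed in tumors" if confounded
              else "no significantly over-expressed targeting miRNA")
    return GeneMirnaScreen(gene=gene, results=results, confounded=confounded,
                           reason=reason)


ACTIVE_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac")


@dataclass(frozen=True)
class ChromatinAnnotation:
    """Binary peak overlaps per chromatin feature and the derived state.

    ``state`` is ``active`` when the amplicon overlaps a DNase
    hypersensitivity peak plus at least one active histone mark, ``repressed``
    when it overlaps H3K27me3 without DNase, else ``ambiguous``.  Marks whose
    track was not supplied are recorded as None and the annotation flagged
    incomplete; the state is computed from the available marks.
    """

    amplicon_name: str
    cell_line: str
    overlaps: dict
    state: str
    incomplete: bool = False


def chromatin_state(amplicon: AmpliconDef, peak_sets: list[PeakSet]) -> ChromatinAnnotation:
    """Annotate one amplicon against one cell line's chromatin feature tracks."""
    if not peak_sets:
        raise ValidationError("chromatin_state requires at least one peak track")
    cell_lines = {p.cell_line for p in peak_sets}
    if len(cell_lines) != 1:
        raise ValidationError(f"peak tracks span multiple cell lines: {sorted(cell_lines)}")
    by_mark = {p.mark: p for p in peak_sets}
    unknown = sorted(set(by_mark) - set(CHROMATIN_MARKS))
    if unknown:
        raise ValidationError(f"unknown chromatin mark(s) {unknown}; "
                              f"expected one of {CHROMATIN_MARKS}")
    overlaps: dict[str, bool | None] = {}
    for mark in CHROMATIN_MARKS:
        peaks = by_mark.get(mark)
        overlaps[mark] = (peaks.overlaps(amplicon.chrom, amplicon.start, amplicon.end)
                          if peaks is not None else None)
    incomplete = any(v is None for v in overlaps.values())
    if incomplete:
        missing = [m for m, v in overlaps.items() if v is None]
        logger.info("amplicon %s: missing chromatin track(s) %s",
                    amplicon.amplicon_name, missing)
    dnase = bool(overlaps["DNase"])
    any_active = any(bool(overlaps[m]) for m in ACTIVE_MARKS)
    repressive = bool(overlaps["H3K27me3"])
    if dnase and any_active:
        state = "active"
    elif repressive and not dnase:
        state = "repressed"
    else:
        state = "ambiguous"
    return ChromatinAnnotation(amplicon_name=amplicon.amplicon_name,
                               cell_line=cell_lines.pop(), overlaps=overlaps,
                               state=state, incomplete=incomplete)
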