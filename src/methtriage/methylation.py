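"""Amplicon-level methylation quantification and paired differential testing.

The model: for each targeted amplicon, a sample's methylation level is the
unweighted mean of its per-CpG methylation fractions (methylated reads /
total reads), expressed on a 0-100 percent scale.  Tumor vs adjacent
non-tumor differences are tested with a paired two-sided t-test per
amplicon (pairs aligned by patient), Bonferroni-corrected over the family
of amplicons tested in the run.  Candidate markers are amplicons with an
absolute tumor - non-tumor difference above 20 percentage points and an
adjusted p below 0.05.

Exposed both as free functions (one per operation) and as a
statsmodels-style :class:`PairedMethylationModel` whose :meth:`fit` returns
:class:`DifferentialMethylationResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import InsufficientDataError, ValidationError
from .io import AmpliconDef, paired_patients

logger = logging.getLogger(__name__)

#: fixed column order of the differential-methylation report
DIFFERENTIAL_COLUMNS = [
    "amplicon_name", "gene", "n_cpg", "mean_nontumor", "sd_nontumor",
    "mean_tumor", "sd_tumor", "difference", "t_stat", "p_raw", "p_adjusted",
    "direction", "significant",
]


def cpg_fraction(meth_count: int, unmeth_count: int) -> float:
    """Methylation fraction at one CpG: meth / (meth + unmeth), in [0, 1]."""
    depth = meth_count + unmeth_count
    if meth_count < 0 or unmeth_count < 0:
        raise ValidationError(f"negative read count ({meth_count}/{unmeth_count})")
    if depth == 0:
        raise ValidationError("methylation fraction undefined at zero depth")
    return meth_count / depth


def amplicon_methylation(cpg_df: pd.DataFrame, amplicons: list[AmpliconDef]) -> pd.DataFrame:
    """Mean per-sample methylation percent over each amplicon's covered CpGs.

    Parameters
    ----------
    cpg_df
        Per-CpG counts for one or more samples (columns ``sample_id, chrom,
        pos, meth_count, unmeth_count``; 1-based positions).
    amplicons
        Amplicon intervals (0-based half-open).

    Returns
    -------
    DataFrame ``sample_id, amplicon_name, gene, percent, n_cpg_covered``
    with percent = 100 x unweighted mean of per-CpG fractions.  Samples with
    no covered CpG in an amplicon are excluded from that amplicon (logged).
    """
    depth = cpg_df["meth_count"] + cpg_df["unmeth_count"]
    if (depth == 0).any():
        raise ValidationError("zero-depth CpG record; filter by min_depth first")
    frac = cpg_df["meth_count"] / depth
    work = cpg_df.assign(fraction=frac)
    all_samples = set(cpg_df["sample_id"].unique())

    out = []
    for amp in amplicons:
        mask = (
            (work["chrom"] == amp.chrom)
            & (work["pos"] > amp.start)
            & (work["pos"] <= amp.end)
        )
        sub = work[mask]
        if sub.empty:
            logger.info("amplicon %s: no covered CpG in any sample", amp.amplicon_name)
            continue
        grouped = sub.groupby("sample_id")["fraction"].agg(["mean", "size"])
        missing = all_samples - set(grouped.index)
        if missing:
            logger.info("amplicon %s: no covered CpG for sample(s) %s",
                        amp.amplicon_name, sorted(missing))
        for sample_id, row in grouped.iterrows():
            out.append((sample_id, amp.amplicon_name, amp.gene,
                        100.0 * row["mean"], int(row["size"])))
    return pd.DataFrame(
        out, columns=["sample_id", "amplicon_name", "gene", "percent", "n_cpg_covered"]
    )


@dataclass(frozen=True)
class PairedTResult:
    """Paired t-test result: tumor - non-tumor differences d, t = mean(d) / (sd(d)/sqrt(n))."""

    mean_diff: float
    t_stat: float
    p: float
    n: int
    zero_variance: bool = False

    @property
    def df(self) -> int:
        return self.n - 1


def paired_t_arrays(tumor: np.ndarray, nontumor: np.ndarray, axis: int = -1):
    """Vectorized paired t along ``axis``; returns (mean_diff, t, two-sided p).

    Zero-variance differences give t = 0, p = 1 when the mean difference is
    also zero, otherwise t = +/-inf, p = 0.
    """
    d = np.asarray(tumor, dtype=float) - np.asarray(nontumor, dtype=float)
    n = d.shape[axis]
    if n < 2:
        raise InsufficientDataError(f"paired t-test requires >= 2 pairs, got {n}")
    mean = d.mean(axis=axis)
    sd = d.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return mean, t, p


def paired_t_test(values_tumor, values_nontumor) -> PairedTResult:
    """Two-sided paired Student's t-test on patient-aligned vectors.

    d = tumor - non-tumor, t = mean(d) / (sd(d)/sqrt(n)) with the n-1
    (sample) SD, df = n - 1.  A zero-variance d with nonzero mean reports
    p = 0 with ``zero_variance=True``.
    """
    tumor = np.asarray(values_tumor, dtype=float)
    nontumor = np.asarray(values_nontumor, dtype=float)
    if tumor.shape != nontumor.shape or tumor.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and patient-aligned")
    if np.isnan(tumor).any() or np.isnan(nontumor).any():
        raise ValidationError("paired t-test input contains missing values")
    mean, t, p = paired_t_arrays(tumor, nontumor)
    zero_var = bool((tumor - nontumor).std(ddof=1) == 0)
    return PairedTResult(mean_diff=float(mean), t_stat=float(t), p=float(p),
                         n=len(tumor), zero_variance=zero_var)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)


def differential_methylation(
    amplicon_meth: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Per-amplicon paired tumor vs non-tumor differential methylation.

    For each amplicon with >= 2 complete tumor/non-tumor pairs: group means
    and sample SDs (n-1), difference = tumor mean - non-tumor mean, paired
    two-sided t, Bonferroni adjustment over the family of tested amplicons
    (or ``family_size`` if given), significance at adjusted p <= ``alpha``.
    Amplicons with fewer than 2 complete pairs are dropped with a log entry.
    """
    pairs = paired_patients(manifest)
    if pairs.empty:
        raise InsufficientDataError("manifest contains no complete tumor/non-tumor pair")
    wide = amplicon_meth.pivot_table(index="sample_id", columns="amplicon_name",
                                     values="percent", aggfunc="mean")
    gene_of = dict(zip(amplicon_meth.amplicon_name, amplicon_meth.gene))
    ncpg_of = (amplicon_meth.groupby("amplicon_name")["n_cpg_covered"].max()
               .astype(int).to_dict())

    rows = []
    for amp in sorted(wide.columns):
        col = wide[amp]
        t_vals, n_vals = [], []
        for _, pr in pairs.iterrows():
            tv = col.get(pr.tumor_sample, np.nan)
            nv = col.get(pr.nontumor_sample, np.nan)
            if pd.notna(tv) and pd.notna(nv):
                t_vals.append(tv)
                n_vals.append(nv)
        if len(t_vals) < 2:
            logger.info("amplicon %s dropped: %d complete pair(s) < 2", amp, len(t_vals))
            continue
        t_arr, n_arr = np.array(t_vals), np.array(n_vals)
        res = paired_t_test(t_arr, n_arr)
        rows.append({
            "amplicon_name": amp,
            "gene": gene_of.get(amp, amp),
            "n_cpg": ncpg_of.get(amp, 0),
            "mean_nontumor": n_arr.mean(),
            "sd_nontumor": n_arr.std(ddof=1),
            "mean_tumor": t_arr.mean(),
            "sd_tumor": t_arr.std(ddof=1),
            "difference": res.mean_diff,
            "t_stat": res.t_stat,
            "p_raw": res.p,
            "n_pairs": res.n,
        })
    if not rows:
        raise InsufficientDataError("no amplicon had >= 2 complete pairs")
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bonferroni_adjust(table["p_raw"].to_numpy(), m=family_size)
    table["direction"] = np.where(table["difference"] > 0, "hyper", "hypo")
    table["significant"] = table["p_adjusted"] <= alpha
    return table[DIFFERENTIAL_COLUMNS + ["n_pairs"]]


def select_candidates(results: pd.DataFrame, min_abs_diff: float = 20.0,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Candidate-marker rule: |difference| > ``min_abs_diff`` points AND adjusted p < ``alpha``."""
    keep = (results["difference"].abs() > min_abs_diff) & (results["p_adjusted"] < alpha)
    return results[keep].reset_index(drop=True)


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples over significant amplicons."""

    leaf_order: list
    newick: str
    linkage: np.ndarray
    labels: list
    degenerate: bool = False

    def cut(self, k: int) -> dict:
        """Map sample -> cluster id at the k-cluster level."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))


def _newick(node: hierarchy.ClusterNode, labels: list, parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _newick(node.get_left(), labels, node.dist)
    right = _newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def cluster_samples(matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster samples (rows) by their amplicon methylation profile.

    Euclidean distance, average linkage; rows are sorted lexicographically by
    sample_id beforehand so equal-distance merges resolve identically under
    input permutation.  Missing cells are mean-imputed per amplicon (column).
    An all-constant matrix is flagged degenerate (all merge heights 0).
    """
    if matrix.shape[0] < 2:
        raise InsufficientDataError("clustering requires >= 2 samples")
    if matrix.shape[1] < 1:
        raise InsufficientDataError("clustering requires >= 1 amplicon")
    mat = matrix.sort_index().copy()
    mat = mat.apply(lambda col: col.fillna(col.mean()))
    if mat.isna().any().any():
        raise ValidationError("amplicon column with no observed value cannot be imputed")
    labels = [str(s) for s in mat.index]
    values = mat.to_numpy(dtype=float)
    link = hierarchy.linkage(values, method="average", metric="euclidean")
    degenerate = bool(np.allclose(link[:, 2], 0.0))
    if degenerate:
        logger.warning("degenerate clustering: all pairwise distances are 0")
    order = [labels[i] for i in hierarchy.leaves_list(link)]
    root = hierarchy.to_tree(link)
    newick = f"({_newick(root.get_left(), labels, root.dist)}," \
             f"{_newick(root.get_right(), labels, root.dist)});" if not root.is_leaf() \
             else f"{labels[root.id]};"
    return ClusterResult(leaf_order=order, newick=newick, linkage=link,
                         labels=labels, degenerate=degenerate)


class PairedMethylationModel:
    """Paired tumor/non-tumor differential methylation over targeted amplicons.

    Parameters
    ----------
    amplicon_meth
        Long-format per-sample amplicon methylation (from
        :func:`amplicon_methylation`).
    manifest
        Sample manifest with tumor/non-tumor pairing by patient.
    """

    def __init__(self, amplicon_meth: pd.DataFrame, manifest: pd.DataFrame):
        self.amplicon_meth = amplicon_meth
        self.manifest = manifest

    @classmethod
    def from_counts(cls, cpg_df: pd.DataFrame, amplicons: list[AmpliconDef],
                    manifest: pd.DataFrame) -> "PairedMethylationModel":
        """Build directly from per-CpG counts plus amplicon definitions."""
        return cls(amplicon_methylation(cpg_df, amplicons), manifest)

    def fit(self, alpha: float = 0.05,
            family_size: int | None = None) -> "DifferentialMethylationResults":
        table = differential_methylation(self.amplicon_meth, self.manifest,
                                         alpha=alpha, family_size=family_size)
        return DifferentialMethylationResults(table, self.amplicon_meth,
                                              self.manifest, alpha=alpha)


class DifferentialMethylationResults:
    """Fitted per-amplicon differential methylation (one row per amplicon)."""

    def __init__(self, table: pd.DataFrame, amplicon_meth: pd.DataFrame,
                 manifest: pd.DataFrame, alpha: float):
        self.table = table
        self.amplicon_meth = amplicon_meth
        self.manifest = manifest
        self.alpha = alpha

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def select_candidates(self, min_abs_diff: float = 20.0,
                          alpha: float = 0.05) -> pd.DataFrame:
        return select_candidates(self.table, min_abs_diff=min_abs_diff, alpha=alpha)

    def methylation_matrix(self, significant_only: bool = True) -> pd.DataFrame:
        """Samples x amplicons percent matrix, optionally restricted to significant amplicons."""
        wide = self.amplicon_meth.pivot_table(index="sample_id",
                                              columns="amplicon_name",
                                              values="percent", aggfunc="mean")
        if significant_only:
            keep = self.table.loc[self.table.significant, "amplicon_name"]
            wide = wide[[c for c in wide.columns if c in set(keep)]]
        return wide

    def cluster_samples(self, significant_only: bool = True) -> ClusterResult:
        return cluster_samples(self.methylation_matrix(significant_only))

    def summary(self) -> str:
        t = self.table
        lines = [
            "Paired differential methylation (tumor - non-tumor)",
            "=" * 66,
            f"amplicons tested: {len(t)}   significant at adjusted p <= "
            f"{self.alpha:g}: {self.n_significant}",
            f"|difference| range: {t.difference.abs().min():.2f} - "
            f"{t.difference.abs().max():.2f} percentage points",
            "-" * 66,
            f"{'amplicon':<14}{'diff':>8}{'p_adj':>11}  {'dir':<6}{'sig':<4}",
        ]
        for _, r in t.iterrows():
            lines.append(f"{r.amplicon_name:<14}{r.difference:>8.2f}"
                         f"{r.p_adjusted:>11.3g}  {r.direction:<6}"
                         f"{'*' if r.significant else '':<4}")
        return "\n".join(lines)
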