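"""Per-gene evidence assembly, the triage decision rule, and the pipeline driver.

The decision rule formalises the candidate-filtering narrative of the study
design: a gene survives as a methylation-regulated marker only if its
methylation change is validated, its expression moves the opposite way,
and neither copy-number loss nor a targeting miRNA offers a competing
explanation.  Rules fire in a fixed order (first match wins):

1. methylation not validated (not significant, or effect below the
   candidate threshold)                  -> excluded_methylation_not_validated
2. no expression data at all            -> no_expression_data
3. no significant expression difference -> excluded_no_expression_difference
4. expression significant but discordant
   with the methylation direction       -> inconsistent_expression
5. a targeting miRNA up in tumors       -> mirna_confounded
6. methylation lower in CNV-loss tumors -> dual_methylation_cnv
7. otherwise methylation_regulated when paired concordance is consistent
   (>= threshold percent and negative correlation); weak concordance falls
   back to inconsistent_expression; absent concordance data keeps
   methylation_regulated on tissue-level evidence alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .errors import MethTriageError, ValidationError
from .expression import (GroupComparison, PairedExpressionModel,
                         compare_tissue_groups, normalize_expression_matrix)
from .integration import (ChromatinAnnotation, CnvLossComparison, ConcordanceSummary,
                          GeneMirnaScreen, chromatin_state, cnv_expression_association,
                          concordance_classify, methylation_by_cnv_loss,
                          mirna_target_screen)
from .methylation import PairedMethylationModel

TRIAGE_LABELS = (
    "methylation_regulated",
    "dual_methylation_cnv",
    "excluded_methylation_not_validated",
    "excluded_no_expression_difference",
    "inconsistent_expression",
    "mirna_confounded",
    "no_expression_data",
)

DEFAULT_PARAMS = {
    "min_depth": 10,
    "alpha": 0.05,
    "min_abs_diff": 20.0,
    "concordance_threshold": 50.0,
    "detect_fraction": 0.5,
    "correlation_on": "differences",
}


@dataclass
class GeneEvidence:
    """All evidence assembled for one gene before the decision rule runs.

    ``methylation`` is the gene's best amplicon (largest |difference|) from
    the differential table, or None when the gene was never tested.
    """

    gene: str
    methylation: dict | None = None
    candidate: bool = False
    expression_tissue: str = "unavailable"  # consistent/partial/none/unavailable
    qpcr: GroupComparison | None = None
    concordance: ConcordanceSummary | None = None
    cnv_loss: CnvLossComparison | None = None
    cnv_loss_effect: bool = False
    mirna_screen: GeneMirnaScreen | None = None
    mirna_confounded: bool = False
    chromatin: list[ChromatinAnnotation] = field(default_factory=list)


@dataclass(frozen=True)
class TriageDecision:
    gene: str
    label: str
    reasons: tuple[str, ...]

    def __post_init__(self):
        if self.label not in TRIAGE_LABELS:
            raise ValidationError(f"unknown triage label {self.label!r}")
        if not self.reasons:
            raise ValidationError("a triage decision must carry at least one reason")


def triage_gene(evidence: GeneEvidence, alpha: float = 0.05,
                concordance_threshold: float = 50.0) -> TriageDecision:
    """Apply the ordered decision rule to one gene's evidence."""
    if evidence is None or not evidence.gene:
        raise ValidationError("empty evidence")
    g = evidence.gene
    reasons: list[str] = []

    # 1 — methylation gate
    if evidence.methylation is None:
        return TriageDecision(g, "excluded_methylation_not_validated",
                              ("no differential methylation result",))
    meth = evidence.methylation
    if not evidence.candidate:
        reasons.append(
            f"methylation not validated: difference {meth['difference']:+.2f} pp, "
            f"adjusted p {meth['p_adjusted']:.3g}")
        return TriageDecision(g, "excluded_methylation_not_validated", tuple(reasons))
    reasons.append(f"candidate: {meth['direction']}methylation "
                   f"{meth['difference']:+.2f} pp, adjusted p {meth['p_adjusted']:.3g}")

    # 2 — any expression data?
    if evidence.expression_tissue == "unavailable" and evidence.qpcr is None:
        reasons.append("no expression data in any assay")
        return TriageDecision(g, "no_expression_data", tuple(reasons))

    # 3 — any significant expression difference?
    tissue_sig = evidence.expression_tissue in ("consistent", "partial")
    qpcr_sig = evidence.qpcr is not None and evidence.qpcr.p <= alpha
    if not tissue_sig and not qpcr_sig:
        reasons.append("no significant expression difference in any tissue contrast")
        return TriageDecision(g, "excluded_no_expression_difference", tuple(reasons))
    if tissue_sig:
        reasons.append(f"tissue-level expression difference: {evidence.expression_tissue}")
    if qpcr_sig:
        reasons.append(f"qPCR {evidence.qpcr.direction}-expression fold "
                       f"{evidence.qpcr.fold_change:+.2f}, p {evidence.qpcr.p:.3g}")

    # 4 — direction concordant with methylation?  The qPCR test is one-sided
    # in the expected direction, so the opposite tail is 1 - p.
    if evidence.qpcr is not None and evidence.qpcr.direction in ("under", "over"):
        if (1.0 - evidence.qpcr.p) <= alpha:
            reasons.append("expression shifts opposite to the methylation call")
            return TriageDecision(g, "inconsistent_expression", tuple(reasons))

    # 5 — miRNA confounding
    if evidence.mirna_confounded:
        up = [r.mirna for r in (evidence.mirna_screen.results
                                if evidence.mirna_screen else [])
              if r.direction == "up"]
        reasons.append(f"targeting miRNA over-expressed in tumors: {', '.join(up) or '?'}")
        return TriageDecision(g, "mirna_confounded", tuple(reasons))
    reasons.append("no targeting miRNA over-expressed"
                   if evidence.mirna_screen is not None else "miRNA screen not run")

    # 6 — CNV loss as competing mechanism
    if evidence.cnv_loss_effect:
        c = evidence.cnv_loss
        reasons.append(
            f"methylation lower in CNV-loss tumors ({c.mean_loss:.2f} vs "
            f"{c.mean_noloss:.2f}, p {c.p:.3g})" if c is not None
            else "methylation differs by CNV-loss status")
        return TriageDecision(g, "dual_methylation_cnv", tuple(reasons))
    reasons.append("no CNV-loss effect on methylation"
                   if evidence.cnv_loss is not None else "CNV comparison not run")

    # 7 — paired concordance
    conc = evidence.concordance
    if conc is None:
        reasons.append("no paired concordance data; tissue-level evidence only")
        return TriageDecision(g, "methylation_regulated", tuple(reasons))
    if (not conc.undefined and conc.percent_concordant >= concordance_threshold
            and np.isfinite(conc.pearson_r) and conc.pearson_r < 0):
        reasons.append(
            f"concordant in {conc.percent_concordant:.1f}% of hypermethylated pairs, "
            f"r = {conc.pearson_r:.3f}")
        return TriageDecision(g, "methylation_regulated", tuple(reasons))
    reasons.append(
        f"weak methylation/expression concordance "
        f"({conc.percent_concordant if not conc.undefined else float('nan')}%, "
        f"r = {conc.pearson_r:.3f})")
    return TriageDecision(g, "inconsistent_expression", tuple(reasons))


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineInputs:
    """In-memory bundle of every input the pipeline can consume."""

    cpg: pd.DataFrame                      # per-CpG counts, all samples
    amplicons: list[io.AmpliconDef]
    manifest: pd.DataFrame
    ct_table: pd.DataFrame | None = None
    expression_matrix: pd.DataFrame | None = None   # linear, genes x arrays
    expression_groups: pd.Series | None = None      # array -> tissue
    cnv_calls: pd.DataFrame | None = None
    mirna_matrix: pd.DataFrame | None = None
    target_map: pd.DataFrame | None = None
    peak_sets: dict[str, list[io.PeakSet]] = field(default_factory=dict)


@dataclass
class PipelineReport:
    """All stage tables plus per-gene decisions and the run log."""

    differential: pd.DataFrame
    candidates: pd.DataFrame
    qpcr: pd.DataFrame
    tissue: pd.DataFrame
    concordance: pd.DataFrame
    cnv_loss: pd.DataFrame
    cnv_association: pd.DataFrame
    mirna: pd.DataFrame
    chromatin: pd.DataFrame
    decisions: pd.DataFrame
    newick: str
    evidence: dict[str, GeneEvidence]
    log: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("differential", "candidates", "qpcr", "tissue", "concordance",
                     "cnv_loss", "cnv_association", "mirna", "chromatin", "decisions"):
            io.write_report(getattr(self, name), outdir / f"{name}.tsv", format="tsv")
        io.write_report(self.decisions, outdir / "decisions.json", format="json")
        (outdir / "clustering.nwk").write_text(self.newick + "\n")
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MethTriageError:
                raise
            except Exception as exc:  # surface the failing stage
                raise MethTriageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline_frames(inputs: PipelineInputs, params: dict | None = None,
                        seed: int | None = None) -> PipelineReport:
    """Run methylation -> expression -> integration -> triage on in-memory inputs."""
    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    alpha = float(p["alpha"])

    # --- methylation ---
    meth_results = _stage("methylation")(
        lambda: PairedMethylationModel.from_counts(
            inputs.cpg, inputs.amplicons, inputs.manifest).fit(alpha=alpha))()
    diff = meth_results.table.sort_values("amplicon_name").reset_index(drop=True)
    candidates = meth_results.select_candidates(min_abs_diff=float(p["min_abs_diff"]),
                                                alpha=alpha)
    try:
        cluster = meth_results.cluster_samples(significant_only=True)
        newick = cluster.newick
    except MethTriageError:
        newick = ";"

    # best amplicon per gene by |difference|
    best = (diff.loc[diff.groupby("gene")["difference"]
                     .transform(lambda s: s.abs().rank(method="first", ascending=False)) == 1]
            .set_index("gene"))
    candidate_genes = set(candidates.gene)
    directions = {g: ("under" if row.direction == "hyper" else "over")
                  for g, row in best.iterrows()}

    pairs = io.paired_patients(inputs.manifest)
    meth_wide = meth_results.methylation_matrix(significant_only=False)

    # --- expression: qPCR ---
    qpcr_results = None
    if inputs.ct_table is not None and len(inputs.ct_table):
        qpcr_results = _stage("expression.qpcr")(
            lambda: PairedExpressionModel(inputs.ct_table, inputs.manifest)
            .fit(directions=directions))()
    qpcr_table = (qpcr_results.table if qpcr_results is not None
                  else pd.DataFrame(columns=["gene", "set_label", "n_pairs",
                                             "mean_tumor", "sd_tumor", "mean_nontumor",
                                             "sd_nontumor", "fold_change", "p",
                                             "direction"]))

    # --- expression: tissue groups ---
    tissue_table = pd.DataFrame(columns=["gene", "mean_tumor", "mean_precursor",
                                         "mean_normal", "p_vs_precursor",
                                         "p_vs_normal", "label"])
    if inputs.expression_matrix is not None and inputs.expression_groups is not None:
        def _tissue():
            norm = normalize_expression_matrix(inputs.expression_matrix)
            # contrasts only for genes with a methylation call; the remaining
            # rows still anchor the per-array normalization
            keep = [g for g in norm.index if g in directions]
            return compare_tissue_groups(norm.loc[keep], inputs.expression_groups,
                                         direction=directions, alpha=alpha)
        tissue_table = _stage("expression.tissue")(_tissue)()
    tissue_labels = dict(zip(tissue_table.gene, tissue_table.label))

    # --- integration: concordance ---
    expr_long = qpcr_results.expression if qpcr_results is not None else None
    concordance: dict[str, ConcordanceSummary] = {}
    if expr_long is not None:
        for gene in sorted(set(expr_long.gene) & set(best.index)):
            amp = best.loc[gene, "amplicon_name"]
            if amp not in meth_wide.columns:
                continue
            esub = expr_long[expr_long.gene == gene].set_index("sample_id")["log2_expr"]
            mt, mn, et, en = [], [], [], []
            for pr in pairs.itertuples():
                vals = (meth_wide[amp].get(pr.tumor_sample, np.nan),
                        meth_wide[amp].get(pr.nontumor_sample, np.nan),
                        esub.get(pr.tumor_sample, np.nan),
                        esub.get(pr.nontumor_sample, np.nan))
                if all(pd.notna(v) for v in vals):
                    mt.append(vals[0]); mn.append(vals[1])
                    et.append(vals[2]); en.append(vals[3])
            if len(mt) >= 3:
                concordance[gene] = concordance_classify(
                    gene, mt, mn, et, en, correlation_on=p["correlation_on"])

    # --- integration: CNV ---
    cnv_loss: dict[str, CnvLossComparison] = {}
    cnv_assoc_rows = []
    if inputs.cnv_calls is not None and len(inputs.cnv_calls):
        tumor_samples = set(inputs.manifest.loc[inputs.manifest.tissue == "tumor",
                                                "sample_id"])
        for gene in sorted(set(inputs.cnv_calls.gene) & set(best.index)):
            amp = best.loc[gene, "amplicon_name"]
            if amp not in meth_wide.columns:
                continue
            calls = inputs.cnv_calls[inputs.cnv_calls.gene == gene]
            calls = calls[calls.sample_id.isin(tumor_samples)]
            state = dict(zip(calls.sample_id, calls.state))
            loss_vals, noloss_vals = [], []
            for s, v in meth_wide[amp].items():
                if s in state and pd.notna(v):
                    (loss_vals if state[s] == "loss" else noloss_vals).append(v / 100.0)
            cnv_loss[gene] = methylation_by_cnv_loss(gene, loss_vals, noloss_vals)
            # CNV state x paired expression direction, when expression exists
            if expr_long is not None and gene in set(expr_long.gene):
                esub = expr_long[expr_long.gene == gene].set_index("sample_id")["log2_expr"]
                states, dirs = [], []
                for pr in pairs.itertuples():
                    tv, nv = esub.get(pr.tumor_sample, np.nan), esub.get(
                        pr.nontumor_sample, np.nan)
                    if pr.tumor_sample in state and pd.notna(tv) and pd.notna(nv):
                        states.append(state[pr.tumor_sample])
                        dirs.append("under" if tv < nv else "over")
                try:
                    res = cnv_expression_association(states, dirs)
                    cnv_assoc_rows.append({"gene": gene, "chi_square": res.chi_square,
                                           "df": res.df, "p": res.p,
                                           "low_expected": res.low_expected})
                except MethTriageError:
                    pass  # degenerate table for this gene; association not reportable

    # --- integration: miRNA screen ---
    mirna_screens: dict[str, GeneMirnaScreen] = {}
    if inputs.mirna_matrix is not None and inputs.target_map is not None:
        for gene in sorted(candidate_genes):
            mirna_screens[gene] = _stage("integration.mirna")(
                lambda g=gene: mirna_target_screen(
                    g, inputs.target_map, inputs.mirna_matrix, inputs.manifest,
                    detect_fraction=float(p["detect_fraction"]), alpha=alpha))()

    # --- integration: chromatin ---
    chromatin: dict[str, list[ChromatinAnnotation]] = {}
    amp_by_name = {a.amplicon_name: a for a in inputs.amplicons}
    for gene in sorted(candidate_genes):
        amp = amp_by_name.get(best.loc[gene, "amplicon_name"])
        if amp is None:
            continue
        annots = []
        for cell_line in sorted(inputs.peak_sets):
            annots.append(chromatin_state(amp, inputs.peak_sets[cell_line]))
        if annots:
            chromatin[gene] = annots

    # --- triage ---
    evidence: dict[str, GeneEvidence] = {}
    decisions = []
    for gene in sorted({a.gene for a in inputs.amplicons}):
        meth_row = best.loc[gene].to_dict() if gene in best.index else None
        qpcr = None
        if qpcr_results is not None:
            qpcr = next((c for c in qpcr_results.comparisons if c.gene == gene), None)
        screen = mirna_screens.get(gene)
        closs = cnv_loss.get(gene)
        ev = GeneEvidence(
            gene=gene,
            methylation=meth_row,
            candidate=gene in candidate_genes,
            expression_tissue=tissue_labels.get(gene, "unavailable"),
            qpcr=qpcr,
            concordance=concordance.get(gene),
            cnv_loss=closs,
            cnv_loss_effect=bool(closs is not None and not closs.skipped
                                 and closs.p <= alpha
                                 and closs.mean_loss < closs.mean_noloss),
            mirna_screen=screen,
            mirna_confounded=bool(screen is not None and screen.confounded),
            chromatin=chromatin.get(gene, []),
        )
        evidence[gene] = ev
        d = triage_gene(ev, alpha=alpha,
                        concordance_threshold=float(p["concordance_threshold"]))
        decisions.append({"gene": gene, "label": d.label,
                          "reasons": "; ".join(d.reasons)})

    conc_table = pd.DataFrame(
        [{"gene": c.gene, "n_pairs": c.n_pairs,
          "n_hypermethylated": c.n_hypermethylated,
          "n_under_expressed": c.n_under_expressed,
          "percent_concordant": c.percent_concordant,
          "pearson_r": c.pearson_r, "r_pvalue": c.r_pvalue}
         for c in concordance.values()],
        columns=["gene", "n_pairs", "n_hypermethylated", "n_under_expressed",
                 "percent_concordant", "pearson_r", "r_pvalue"])
    cnv_table = pd.DataFrame(
        [{"gene": c.gene, "n_loss": c.n_loss, "n_noloss": c.n_noloss,
          "mean_loss": c.mean_loss, "mean_noloss": c.mean_noloss,
          "t_stat": c.t_stat, "p": c.p, "skipped": c.skipped}
         for c in cnv_loss.values()],
        columns=["gene", "n_loss", "n_noloss", "mean_loss", "mean_noloss",
                 "t_stat", "p", "skipped"])
    mirna_frames = [s.table for s in mirna_screens.values() if len(s.table)]
    mirna_table = (pd.concat(mirna_frames, ignore_index=True) if mirna_frames
                   else pd.DataFrame(
                       columns=["gene", "mirna", "n_pairs", "mean_tumor",
                                "mean_nontumor", "log2_fc", "p_raw", "p_adjusted",
                                "direction"]))
    chrom_rows = []
    for gene, annots in chromatin.items():
        for a in annots:
            row = {"gene": gene, "amplicon_name": a.amplicon_name,
                   "cell_line": a.cell_line, "state": a.state,
                   "incomplete": a.incomplete}
            for mark in io.CHROMATIN_MARKS:
                v = a.overlaps.get(mark)
                row[mark] = "NA" if v is None else bool(v)
            chrom_rows.append(row)
    chrom_table = pd.DataFrame(
        chrom_rows, columns=["gene", "amplicon_name", "cell_line",
                             *io.CHROMATIN_MARKS, "state", "incomplete"])

    log = {
        "package": "methtriage",
        "version": __import__("methtriage").__version__,
        "seed": seed,
        "params": p,
        "n_samples": int(inputs.manifest.shape[0]),
        "n_pairs": int(pairs.shape[0]),
        "n_amplicons_tested": int(diff.shape[0]),
        "n_significant": int(diff.significant.sum()),
        "n_candidates": int(candidates.shape[0]),
        "labels": {lab: int((pd.DataFrame(decisions).label == lab).sum())
                   for lab in TRIAGE_LABELS},
    }
    return PipelineReport(
        differential=diff, candidates=candidates, qpcr=qpcr_table,
        tissue=tissue_table, concordance=conc_table, cnv_loss=cnv_table,
        cnv_association=pd.DataFrame(cnv_assoc_rows,
                                     columns=["gene", "chi_square", "df", "p",
                                              "low_expected"]),
        mirna=mirna_table, chromatin=chrom_table,
        decisions=pd.DataFrame(decisions, columns=["gene", "label", "reasons"]),
        newick=newick, evidence=evidence, log=log,
    )


def load_inputs(config: dict, base: Path | None = None) -> PipelineInputs:
    """Materialise a :class:`PipelineInputs` bundle from a config's file paths."""
    inp = config.get("inputs", {})
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    base = Path(base) if base is not None else Path(".")

    def _p(x):
        q = Path(x)
        return q if q.is_absolute() else base / q

    reports = inp.get("cytosine_reports")
    if reports is None:
        raise ValidationError("config.inputs.cytosine_reports is required")
    frames = []
    if isinstance(reports, dict):
        items = sorted(reports.items())
    else:
        items = sorted((f.stem, f) for f in _p(reports).glob("*.tsv"))
    for sample_id, path in items:
        frames.append(io.read_cytosine_report(_p(path), min_depth=int(params["min_depth"]),
                                              sample_id=sample_id))
    if not frames:
        raise ValidationError("no cytosine reports found")
    cpg = pd.concat(frames, ignore_index=True)

    amplicons = io.read_amplicon_bed(_p(inp["amplicons"]))
    manifest = io.read_sample_manifest(_p(inp["manifest"]))

    def _opt(key, kind):
        return (io.read_tabular_inputs(_p(inp[key]), kind) if inp.get(key) else None)

    groups = None
    if inp.get("expression_groups"):
        gdf = io._read_header_tsv(_p(inp["expression_groups"]), {"sample_id", "tissue"})
        groups = pd.Series(dict(zip(gdf.sample_id, gdf.tissue)))

    peak_sets: dict[str, list[io.PeakSet]] = {}
    for spec in inp.get("peaks", []) or []:
        ps = io.read_peak_bed(_p(spec["path"]), mark=spec["mark"],
                              cell_line=spec["cell_line"])
        peak_sets.setdefault(spec["cell_line"], []).append(ps)

    return PipelineInputs(
        cpg=cpg, amplicons=amplicons, manifest=manifest,
        ct_table=_opt("ct_table", "ct_table"),
        expression_matrix=_opt("expression_matrix", "expression_matrix"),
        expression_groups=groups,
        cnv_calls=_opt("cnv_calls", "cnv_calls"),
        mirna_matrix=_opt("mirna_matrix", "mirna_matrix"),
        target_map=_opt("target_map", "target_map"),
        peak_sets=peak_sets,
    )


def run_pipeline(config, output_dir=None) -> PipelineReport:
    """Run the full pipeline from a config mapping or YAML/JSON file path.

    Writes every stage report (TSV), the decisions (TSV + JSON), the sample
    dendrogram (newick) and a run log to ``output_dir`` (or
    ``config['output_dir']``).  Re-running with identical inputs and seed
    yields byte-identical TSV outputs.
    """
    base = Path(".")
    if not isinstance(config, dict):
        cfg_path = Path(config)
        base = cfg_path.parent
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
    inputs = load_inputs(config, base=base)
    report = run_pipeline_frames(inputs, params=config.get("params"),
                                 seed=config.get("seed"))
    outdir = output_dir or config.get("output_dir")
    if outdir is not None:
        report.write(outdir)
    return report
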