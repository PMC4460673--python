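"""Decision-rule ordering, totality over the evidence lattice, pipeline behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest

import methtriage as mt
from methtriage.errors import ValidationError
from methtriage.expression import GroupComparison
from methtriage.integration import CnvLossComparison, ConcordanceSummary, GeneMirnaScreen
from methtriage.triage import GeneEvidence, TRIAGE_LABELS, triage_gene


def _meth(diff=29.79, p_adj=3.92e-4):
    return {"amplicon_name": "G.a", "gene": "G", "difference": diff,
            "p_adjusted": p_adj, "direction": "hyper" if diff > 0 else "hypo",
            "significant": p_adj <= 0.05}


def _qpcr(fold=-1.96, p=1.53e-3, direction="under"):
    return GroupComparison(gene="G", set_label="24 pairs", n_pairs=24,
                           mean_tumor=-7.49, sd_tumor=1.41, mean_nontumor=-6.52,
                           sd_nontumor=1.26, fold_change=fold, p=p,
                           direction=direction)


def _conc(pct=69.2, r=-0.394):
    return ConcordanceSummary(gene="G", n_pairs=66, n_hypermethylated=65,
                              n_under_expressed=45, percent_concordant=pct,
                              pearson_r=r, r_pvalue=0.007)


def _cnv(p=0.02, lower=True):
    return CnvLossComparison(gene="G", n_loss=10, n_noloss=14,
                             mean_loss=0.41 if lower else 0.60, mean_noloss=0.54,
                             t_stat=-2.5 if lower else 1.0, p=p)


class TestRuleOrder:
    def test_nonsignificant_methylation_excluded_first(self):
        ev = GeneEvidence(gene="G", methylation=_meth(diff=20.05, p_adj=0.277),
                          candidate=False, expression_tissue="consistent",
                          qpcr=_qpcr(), concordance=_conc())
        d = triage_gene(ev)
        assert d.label == "excluded_methylation_not_validated"
        assert "0.277" in d.reasons[0]

    def test_no_expression_data(self):
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True)
        assert triage_gene(ev).label == "no_expression_data"

    def test_no_expression_difference(self):
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True,
                          expression_tissue="none")
        assert triage_gene(ev).label == "excluded_no_expression_difference"

    def test_discordant_expression(self):
        # one-sided under-expression p near 1 <=> significant over-expression
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True,
                          expression_tissue="partial",
                          qpcr=_qpcr(fold=+1.9, p=0.995))
        assert triage_gene(ev).label == "inconsistent_expression"

    def test_mirna_confounded_beats_cnv(self):
        screen = GeneMirnaScreen(gene="G", confounded=True)
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True,
                          expression_tissue="consistent", mirna_screen=screen,
                          mirna_confounded=True, cnv_loss=_cnv(),
                          cnv_loss_effect=True)
        assert triage_gene(ev).label == "mirna_confounded"

    def test_cnv_loss_beats_concordance(self):
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True,
                          expression_tissue="consistent", qpcr=_qpcr(),
                          concordance=_conc(), cnv_loss=_cnv(),
                          cnv_loss_effect=True)
        assert triage_gene(ev).label == "dual_methylation_cnv"

    def test_full_evidence_methylation_regulated(self):
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True,
                          expression_tissue="consistent", qpcr=_qpcr(),
                          concordance=_conc(), cnv_loss=_cnv(p=0.8, lower=False))
        d = triage_gene(ev)
        assert d.label == "methylation_regulated"
        assert any("69.2" in r for r in d.reasons)

    def test_weak_concordance_is_inconsistent(self):
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True,
                          expression_tissue="consistent", qpcr=_qpcr(),
                          concordance=_conc(pct=30.0, r=-0.1))
        assert triage_gene(ev).label == "inconsistent_expression"

    def test_positive_correlation_is_inconsistent(self):
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True,
                          expression_tissue="consistent", qpcr=_qpcr(),
                          concordance=_conc(pct=80.0, r=+0.3))
        assert triage_gene(ev).label == "inconsistent_expression"

    def test_missing_concordance_keeps_tissue_level_call(self):
        ev = GeneEvidence(gene="G", methylation=_meth(), candidate=True,
                          expression_tissue="consistent")
        d = triage_gene(ev)
        assert d.label == "methylation_regulated"
        assert any("tissue-level evidence only" in r for r in d.reasons)

    def test_empty_evidence_rejected(self):
        with pytest.raises(ValidationError):
            triage_gene(GeneEvidence(gene=""))


class TestTotality:
    @pytest.mark.parametrize("candidate", [True, False])
    @pytest.mark.parametrize("tissue", ["consistent", "partial", "none", "unavailable"])
    @pytest.mark.parametrize("qpcr", [None, "sig", "nonsig", "opposite"])
    @pytest.mark.parametrize("mirna_up,cnv_loss", [(False, False), (True, False),
                                                   (False, True)])
    def test_every_lattice_point_gets_exactly_one_label(self, candidate, tissue,
                                                        qpcr, mirna_up, cnv_loss):
        qp = {None: None, "sig": _qpcr(), "nonsig": _qpcr(fold=-1.1, p=0.4),
              "opposite": _qpcr(fold=+2.0, p=0.999)}[qpcr]
        for conc in (None, _conc(), _conc(pct=20.0, r=0.2)):
            ev = GeneEvidence(gene="G", methylation=_meth(), candidate=candidate,
                              expression_tissue=tissue, qpcr=qp, concordance=conc,
                              cnv_loss=_cnv() if cnv_loss else None,
                              cnv_loss_effect=cnv_loss,
                              mirna_screen=GeneMirnaScreen(gene="G",
                                                           confounded=mirna_up),
                              mirna_confounded=mirna_up)
            d = triage_gene(ev)
            assert d.label in TRIAGE_LABELS
            assert len(d.reasons) >= 1


class TestPipeline:
    def test_paper_like_scenario_yields_expected_labels(self, paper_scenario,
                                                        paper_report):
        got = dict(zip(paper_report.decisions.gene, paper_report.decisions.label))
        for gene, label in paper_scenario.expected_labels.items():
            assert got[gene] == label, gene
        assert paper_report.log["n_amplicons_tested"] == 31

    def test_missing_ct_table_degrades_gracefully(self, paper_cohort):
        inputs = paper_cohort.to_pipeline_inputs()
        inputs.ct_table = None
        inputs.expression_matrix = None
        inputs.expression_groups = None
        rep = mt.run_pipeline_frames(inputs)
        labels = set(rep.decisions.label)
        assert labels <= {"no_expression_data", "excluded_methylation_not_validated"}
        assert len(rep.decisions) == 22

    def test_same_inputs_same_report(self, paper_cohort, paper_report):
        rep2 = mt.run_pipeline_frames(paper_cohort.to_pipeline_inputs(), seed=0)
        pd.testing.assert_frame_equal(rep2.decisions, paper_report.decisions)
        pd.testing.assert_frame_equal(rep2.differential, paper_report.differential)
        assert rep2.newick == paper_report.newick

    def test_stage_reports_present_and_consistent(self, paper_report):
        assert not paper_report.differential.empty
        assert not paper_report.candidates.empty
        assert (paper_report.candidates.difference.abs() > 20).all()
        assert (paper_report.candidates.p_adjusted < 0.05).all()
        assert set(paper_report.decisions.gene) == set(
            paper_report.differential.gene)
        # concordance counts bounded by pair count
        c = paper_report.concordance
        assert (c.n_under_expressed <= c.n_hypermethylated).all()
        assert (c.n_hypermethylated <= c.n_pairs).all()

    def test_report_written_files_round_trip(self, paper_report, tmp_path):
        paper_report.write(tmp_path)
        back = mt.read_report(tmp_path / "decisions.tsv")
        assert list(back.gene) == list(paper_report.decisions.gene)
        assert (tmp_path / "run_log.json").exists()
        assert (tmp_path / "clustering.nwk").read_text().strip().endswith(";")
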