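"""Concordance, correlation, CNV association, miRNA screen, chromatin states."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methtriage as mt
from methtriage.errors import InsufficientDataError, ValidationError
from methtriage.io import AmpliconDef, PeakSet

AMP = AmpliconDef("G", "G.a", "chr1", 1000, 2000)


def _peaks(mark, intervals, cell_line="HepG2"):
    return PeakSet(mark, cell_line, intervals)


class TestConcordance:
    def _vectors(self, n_pairs, n_hyper, n_under):
        """Construct paired vectors realising exact hyper/under counts."""
        rng = np.random.default_rng(0)
        mt_, mn, et, en = [], [], [], []
        for i in range(n_pairs):
            hyper = i < n_hyper
            under = i < n_under          # under-expressed pairs nest in hyper pairs
            mn.append(30.0 + rng.normal(0, 1))
            mt_.append(mn[-1] + (10.0 + 0.5 * i) * (1 if hyper else -1))
            en.append(-6.0 + rng.normal(0, 0.1))
            et.append(en[-1] + (1.0 + 0.1 * i) * (-1 if under else 1))
        return mt_, mn, et, en

    def test_published_counts_reproduce_percentages(self):
        s = mt.concordance_classify("GRASP", *self._vectors(66, 65, 45))
        assert (s.n_hypermethylated, s.n_under_expressed) == (65, 45)
        assert s.percent_concordant == 69.2
        s2 = mt.concordance_classify("TSPYL5", *self._vectors(66, 64, 47))
        assert s2.percent_concordant == 73.4

    def test_all_concordant(self):
        s = mt.concordance_classify("G", *self._vectors(10, 10, 10))
        assert s.percent_concordant == 100.0 and s.pearson_r < 0

    def test_exact_linear_anticorrelation(self):
        d_meth = np.array([1.0, 2.0, 5.0, 3.0])
        mt_, mn = 30 + d_meth, np.full(4, 30.0)
        et, en = -6 - 0.5 * d_meth, np.full(4, -6.0)
        s = mt.concordance_classify("G", mt_, mn, et, en)
        assert s.pearson_r == pytest.approx(-1.0)

    def test_no_hypermethylated_pairs_flagged_undefined(self):
        s = mt.concordance_classify("G", [1.0, 2.0, 3.0], [5.0, 6.0, 7.0],
                                    [0.0, 0.1, -0.1], [0.0, 0.0, 0.0])
        assert s.undefined and np.isnan(s.percent_concordant)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 999))
    def test_pair_classification_is_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        mt_, mn = rng.normal(40, 10, n), rng.normal(40, 10, n)
        et, en = rng.normal(-6, 1, n), rng.normal(-6, 1, n)
        s = mt.concordance_classify("G", mt_, mn, et, en)
        n_hypo_or_tied = int((np.array(mt_) <= np.array(mn)).sum())
        assert s.n_hypermethylated + n_hypo_or_tied == s.n_pairs == n
        assert 0 <= s.n_under_expressed <= s.n_hypermethylated


class TestPearson:
    def test_identity(self):
        r, _ = mt.pearson_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)

    def test_hand_example(self):
        r, p = mt.pearson_correlation([1.0, 2.0, 3.0], [6.0, 4.0, 5.0])
        assert r == pytest.approx(-0.5)

    def test_agrees_with_brute_force_covariance(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            r, _ = mt.pearson_correlation(x, y)
            brute = (np.mean((x - x.mean()) * (y - y.mean()))
                     / (x.std() * y.std()))
            assert r == pytest.approx(brute, abs=1e-12)

    def test_negative_regime_recovered(self):
        """Bivariate noise at rho = -0.4, n = 66 recovers the correlation on average."""
        rng = np.random.default_rng(10)
        rs = []
        for _ in range(300)  :
            x = rng.normal(size=66)
            y = -0.4 * x + np.sqrt(1 - 0.16) * rng.normal(size=66)
            rs.append(mt.pearson_correlation(x, y)[0])
        assert -0.46 < np.mean(rs) < -0.34

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            mt.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_needs_three_points(self):
        with pytest.raises(InsufficientDataError):
            mt.pearson_correlation([1.0, 2.0], [2.0, 1.0])


class TestChiSquare:
    def test_perfect_association(self):
        res = mt.cnv_expression_association(table=pd.DataFrame([[10, 0], [0, 10]]))
        assert res.chi_square == pytest.approx(20.0) and res.df == 1

    def test_homogeneous_table(self):
        res = mt.cnv_expression_association(table=pd.DataFrame([[5, 5], [5, 5]]))
        assert res.chi_square == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_matches_independent_oe_sum(self):
        rng = np.random.default_rng(12)
        obs = pd.DataFrame(rng.integers(3, 30, size=(3, 2)))
        res = mt.cnv_expression_association(table=obs)
        expected = (obs.sum(1).to_numpy()[:, None] * obs.sum(0).to_numpy()[None, :]
                    / obs.to_numpy().sum())
        brute = float(((obs.to_numpy() - expected) ** 2 / expected).sum())
        assert res.chi_square == pytest.approx(brute, abs=1e-10)

    def test_label_vectors_build_table(self):
        res = mt.cnv_expression_association(
            ["loss", "loss", "none", "none"], ["under", "under", "over", "over"])
        assert res.df == 1 and res.low_expected

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            mt.cnv_expression_association(table=pd.DataFrame([[5, 5]]))


class TestCnvLossComparison:
    def test_identical_groups(self):
        r = mt.methylation_by_cnv_loss("G", [0.5, 0.6, 0.4], [0.5, 0.6, 0.4])
        assert r.t_stat == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_swapped_labels_negate_t(self):
        a, b = [0.41, 0.39, 0.44], [0.54, 0.52, 0.58]
        r1 = mt.methylation_by_cnv_loss("G", a, b)
        r2 = mt.methylation_by_cnv_loss("G", b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p == pytest.approx(r2.p)

    def test_published_effect_regime_is_detectable(self):
        """Loss tumors at 0.41 vs 0.54, SD 0.1, n = 15/15: mostly significant."""
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(200):
            loss = rng.normal(0.41, 0.1, 15)
            noloss = rng.normal(0.54, 0.1, 15)
            r = mt.methylation_by_cnv_loss("RGS17", loss, noloss)
            hits += (r.p <= 0.05) and (r.mean_loss < r.mean_noloss)
        assert hits >= 180

    def test_empty_group_skipped_with_flag(self):
        r = mt.methylation_by_cnv_loss("G", [], [0.5, 0.6])
        assert r.skipped and "loss=0" in r.reason


class TestMirnaScreen:
    def _cohort(self, shift, n_pairs=20, seed=0, detect=1.0):
        rng = np.random.default_rng(seed)
        manifest = mt.simulate.make_manifest(n_pairs)
        cols = {}
        for r in manifest.itertuples():
            v = -6.0 + (shift if r.tissue == "tumor" else 0.0) + rng.normal(0, 0.7)
            cols[r.sample_id] = [v if rng.random() < detect else np.nan]
        matrix = pd.DataFrame(cols, index=["miR-X"])
        matrix.index.name = "mirna"
        tmap = pd.DataFrame({"mirna": ["miR-X"], "gene": ["G"]})
        return manifest, matrix, tmap

    def test_planted_up_mirna_flags_gene(self):
        manifest, matrix, tmap = self._cohort(+1.0)
        res = mt.mirna_target_screen("G", tmap, matrix, manifest)
        assert res.confounded and res.results[0].direction == "up"
        assert res.results[0].log2_fc > 0

    def test_down_mirna_does_not_flag(self):
        manifest, matrix, tmap = self._cohort(-1.0)
        res = mt.mirna_target_screen("G", tmap, matrix, manifest)
        assert not res.confounded and res.results[0].direction == "down"

    def test_null_mirna_direction_none(self):
        manifest, matrix, tmap = self._cohort(0.0, seed=3)
        res = mt.mirna_target_screen("G", tmap, matrix, manifest)
        assert res.results[0].direction == "none" and not res.confounded

    def test_undetectable_mirna_not_tested(self):
        manifest, matrix, tmap = self._cohort(+1.0, detect=0.2, seed=1)
        res = mt.mirna_target_screen("G", tmap, matrix, manifest,
                                     detect_fraction=0.5)
        assert not res.confounded and res.reason == "no detectable targeting miRNA"

    def test_gene_absent_from_map(self):
        manifest, matrix, tmap = self._cohort(+1.0)
        res = mt.mirna_target_screen("OTHER", tmap, matrix, manifest)
        assert not res.confounded and "absent" in res.reason

    def test_bonferroni_within_gene(self):
        manifest, matrix, tmap = self._cohort(+1.0)
        extra = matrix.copy()
        for i in range(4):
            extra.loc[f"miR-null{i}"] = matrix.loc["miR-X"].to_numpy()[::-1]
        tmap = pd.DataFrame({"mirna": list(extra.index), "gene": "G"})
        res = mt.mirna_target_screen("G", tmap, extra, manifest)
        tab = res.table.set_index("mirna")
        assert (tab.p_adjusted >= tab.p_raw).all()


class TestChromatinState:
    def test_dnase_plus_active_mark_is_active(self):
        peaks = [_peaks("DNase", [("chr1", 900, 1100)]),
                 _peaks("H3K27ac", [("chr1", 1500, 1600)])]
        ann = mt.chromatin_state(AMP, peaks)
        assert ann.state == "active" and ann.incomplete

    def test_h3k27me3_only_is_repressed(self):
        peaks = [_peaks(m, [("chr1", 900, 2100)] if m == "H3K27me3" else [])
                 for m in mt.io.CHROMATIN_MARKS]
        ann = mt.chromatin_state(AMP, peaks)
        assert ann.state == "repressed" and not ann.incomplete

    def test_no_overlap_anywhere_is_ambiguous(self):
        peaks = [_peaks(m, [("chr9", 0, 10)]) for m in mt.io.CHROMATIN_MARKS]
        ann = mt.chromatin_state(AMP, peaks)
        assert ann.state == "ambiguous"
        assert not any(ann.overlaps.values())

    def test_state_invariants(self):
        peaks = [_peaks(m, [("chr1", 900, 2100)]) for m in mt.io.CHROMATIN_MARKS]
        ann = mt.chromatin_state(AMP, peaks)   # everything overlaps
        if ann.state == "active":
            assert ann.overlaps["DNase"]
        assert ann.state != "repressed" or not ann.overlaps["DNase"]

    def test_monotone_adding_active_marks(self):
        """Adding an active-mark overlap never demotes an active annotation."""
        base = [_peaks("DNase", [("chr1", 900, 2100)]),
                _peaks("H3K4me3", [("chr1", 900, 2100)])]
        assert mt.chromatin_state(AMP, base).state == "active"
        for extra_mark in ("H3K4me1", "H3K27ac"):
            more = base + [_peaks(extra_mark, [("chr1", 900, 2100)])]
            assert mt.chromatin_state(AMP, more).state == "active"

    def test_mixed_cell_lines_rejected(self):
        peaks = [_peaks("DNase", [("chr1", 0, 10)], "HepG2"),
                 _peaks("H3K27ac", [("chr1", 0, 10)], "K562")]
        with pytest.raises(ValidationError, match="cell line"):
            mt.chromatin_state(AMP, peaks)

    def test_planted_states_all_realised(self, paper_cohort, paper_report):
        states = set(paper_report.chromatin.state)
        assert {"active", "repressed", "ambiguous"} <= states
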