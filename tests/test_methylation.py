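"""Amplicon methylation quantification, paired testing, candidate selection, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methtriage as mt
from methtriage import refdata
from methtriage.errors import InsufficientDataError, ValidationError
from methtriage.io import AmpliconDef


class TestCpgFraction:
    @pytest.mark.parametrize("meth,unmeth,expected",
                             [(0, 10, 0.0), (5, 5, 0.5), (7, 3, 0.7)])
    def test_fraction(self, meth, unmeth, expected):
        assert mt.cpg_fraction(meth, unmeth) == pytest.approx(expected)

    def test_zero_depth_undefined(self):
        with pytest.raises(ValidationError, match="zero depth"):
            mt.cpg_fraction(0, 0)


class TestAmpliconMethylation:
    def _frame(self, fractions, depth=10):
        rows = [("S1", "chr1", 101 + 10 * i, int(round(f * depth)),
                 depth - int(round(f * depth))) for i, f in enumerate(fractions)]
        return pd.DataFrame(rows, columns=mt.io.CPG_COLUMNS)

    @pytest.mark.parametrize("fractions,expected", [
        ([0.5, 0.5, 0.5], 50.0),
        ([0.0, 1.0], 50.0),
        ([0.1, 0.2, 0.6], 30.0),
    ])
    def test_unweighted_mean_of_cpg_fractions(self, fractions, expected):
        amp = AmpliconDef("G", "G.a", "chr1", 100, 200)
        out = mt.amplicon_methylation(self._frame(fractions), [amp])
        assert out.percent.iloc[0] == pytest.approx(expected)
        assert out.n_cpg_covered.iloc[0] == len(fractions)

    def test_sample_without_coverage_excluded(self):
        amp_far = AmpliconDef("G", "G.far", "chr2", 100, 200)
        out = mt.amplicon_methylation(self._frame([0.5]), [amp_far])
        assert out.empty

    def test_half_open_boundaries(self):
        # 1-based position p lies in [start, end) iff start < p <= end
        df = self._frame([1.0])         # single CpG at 1-based pos 101
        inside = AmpliconDef("G", "G.in", "chr1", 100, 101)
        outside = AmpliconDef("G", "G.out", "chr1", 101, 200)
        assert len(mt.amplicon_methylation(df, [inside])) == 1
        assert mt.amplicon_methylation(df, [outside]).empty


class TestPairedT:
    def test_identical_vectors(self):
        r = mt.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_stat == 0.0 and r.p == 1.0 and r.mean_diff == 0.0

    def test_hand_computed_example(self):
        # d = {1,2,3}: mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.4641, df 2
        r = mt.paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.t_stat == pytest.approx(3.4641, abs=1e-4)
        assert r.p == pytest.approx(0.0742, abs=1e-4)
        assert r.mean_diff == pytest.approx(2.0)

    def test_zero_variance_nonzero_mean(self):
        r = mt.paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.p == 0.0 and r.zero_variance

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            mt.paired_t_test([1.0], [2.0])

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = rng.normal(size=(2, 12))
            r = mt.paired_t_test(a, b)
            ref = stats.ttest_rel(a, b)
            assert r.t_stat == pytest.approx(ref.statistic, rel=1e-12)
            assert r.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_agrees_with_exact_sign_flip_permutation(self):
        """The t p-value tracks the exact sign-flip null for small n."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 8
            d = rng.normal(0.6, 1.0, size=n)
            r = mt.paired_t_test(d, np.zeros(n))
            # enumerate all 2^n sign flips of d (exact permutation null)
            flips = np.array(list(itertools.product([1, -1], repeat=n)))
            perm = flips * d
            t_perm = perm.mean(1) / (perm.std(1, ddof=1) / np.sqrt(n))
            p_exact = np.mean(np.abs(t_perm) >= abs(r.t_stat) - 1e-12)
            assert r.p == pytest.approx(p_exact, abs=0.05)


class TestBonferroni:
    def test_examples(self):
        assert mt.bonferroni_adjust([0.01], m=29)[0] == pytest.approx(0.29)
        assert mt.bonferroni_adjust([0.5], m=29)[0] == 1.0
        assert mt.bonferroni_adjust([0.03], m=1)[0] == pytest.approx(0.03)

    def test_never_decreases_and_order_preserving(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = mt.bonferroni_adjust(p, m=60)
        assert (adj >= p).all() and (adj <= 1).all()
        # monotone: a smaller raw p never gets a larger adjusted p
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= 0).all()

    def test_rejects_invalid(self):
        with pytest.raises(ValidationError):
            mt.bonferroni_adjust([1.2])
        with pytest.raises(ValidationError):
            mt.bonferroni_adjust([0.1, 0.2], m=1)


class TestDifferential:
    def test_published_significance_rule_gives_28_of_29(self):
        """On the published amplicon table, 28/29 amplicons pass adjusted p <= 0.05."""
        sig = refdata.AMPLICON_TABLE.p_adjusted <= 0.05
        assert int(sig.sum()) == 28
        assert refdata.AMPLICON_TABLE.loc[~sig, "gene"].tolist() == ["DUOX1"]

    def test_single_amplicon_family_leaves_p_unchanged(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(1, 6):
            rows += [(f"T{i:02d}", "A", "G", 50 + rng.normal(), 3),
                     (f"N{i:02d}", "A", "G", 30 + rng.normal(), 3)]
        amp = pd.DataFrame(rows, columns=["sample_id", "amplicon_name", "gene",
                                          "percent", "n_cpg_covered"])
        res = mt.differential_methylation(amp, mt.simulate.make_manifest(5))
        assert res.p_adjusted.iloc[0] == pytest.approx(res.p_raw.iloc[0])
        assert res.difference.iloc[0] == pytest.approx(
            res.mean_tumor.iloc[0] - res.mean_nontumor.iloc[0])

    def test_difference_equals_mean_gap_exactly(self, paper_report):
        t = paper_report.differential
        assert np.allclose(t.difference, t.mean_tumor - t.mean_nontumor, atol=1e-12)
        assert ((t.direction == "hyper") == (t.difference > 0)).all()


class TestSelectCandidates:
    def _row(self, diff, p):
        return {"amplicon_name": "A", "gene": "G", "n_cpg": 5, "mean_nontumor": 10.0,
                "sd_nontumor": 1.0, "mean_tumor": 10.0 + diff, "sd_tumor": 1.0,
                "difference": diff, "t_stat": 1.0, "p_raw": p, "p_adjusted": p,
                "direction": "hyper" if diff > 0 else "hypo", "significant": p <= 0.05}

    @pytest.mark.parametrize("diff,p,kept", [
        (20.05, 0.277, False),   # significance gate fails
        (19.9, 0.001, False),    # effect-size gate fails
        (27.4, 8.09e-4, True),   # both gates pass
    ])
    def test_selection_gates(self, diff, p, kept):
        res = pd.DataFrame([self._row(diff, p)])
        out = mt.select_candidates(res, min_abs_diff=20.0, alpha=0.05)
        assert (len(out) == 1) is kept


class TestClustering:
    def test_identical_samples_merge_at_height_zero(self):
        m = pd.DataFrame([[10.0, 20.0], [10.0, 20.0]], index=["a", "b"])
        res = mt.cluster_samples(m)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert res.degenerate

    def test_closest_pair_merges_first(self):
        m = pd.DataFrame({"amp": [0.0, 10.0, 11.0]}, index=["s0", "s10", "s11"])
        res = mt.cluster_samples(m)
        first = {res.labels[int(res.linkage[0, 0])], res.labels[int(res.linkage[0, 1])]}
        assert first == {"s10", "s11"}

    def test_first_split_recovers_two_separated_groups(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            np.vstack([rng.normal(10, 1, (2, 3)), rng.normal(60, 1, (2, 3))]),
            index=["a1", "a2", "b1", "b2"])
        # brute-force best 2-partition by summed within-group squared distance
        pts = m.to_numpy()
        best = min(
            ([i for i in range(4) if mask & (1 << i)] for mask in range(1, 8)),
            key=lambda g: sum(np.sum((pts[i] - pts[j]) ** 2)
                              for grp in (g, [i for i in range(4) if i not in g])
                              for i in grp for j in grp))
        cut = mt.cluster_samples(m).cut(2)
        groups = {}
        for s, c in cut.items():
            groups.setdefault(c, set()).add(s)
        assert set(map(frozenset, groups.values())) == {
            frozenset(m.index[i] for i in best),
            frozenset(m.index[i] for i in range(4) if i not in best)}

    def test_leaf_order_stable_under_row_permutation(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(6, 4)),
                         index=[f"s{i}" for i in range(6)])
        res1 = mt.cluster_samples(m)
        res2 = mt.cluster_samples(m.sample(frac=1, random_state=1))
        assert res1.leaf_order == res2.leaf_order
        assert res1.newick == res2.newick

    def test_newick_contains_all_leaves(self, paper_report):
        nwk = paper_report.newick
        for sample in ("T01", "N01", "T24", "N24"):
            assert sample in nwk
        assert nwk.endswith(";")

    def test_requires_two_samples(self):
        with pytest.raises(InsufficientDataError):
            mt.cluster_samples(pd.DataFrame({"a": [1.0]}, index=["s"]))
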