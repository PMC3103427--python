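import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import mtrc
from mtrc.errors import DomainError


def pairwise_auc_oracle(tp, tn):
    """Exhaustive Mann-Whitney pair counting with ties scored 1/2."""
    tp = np.asarray(tp, float)[:, None]
    tn = np.asarray(tn, float)[None, :]
    wins = (tp > tn).sum() + 0.5 * (tp == tn).sum()
    return wins / (tp.size * tn.size)


class TestRocAuc:
    def test_tied_pair_example(self):
        r = mtrc.roc_auc([2.0, 1.0], [1.0, 0.0])
        assert r.auc == pytest.approx(0.875)  # (1 + 1 + 0.5 + 1) / 4

    def test_perfect_separation_and_inversion(self):
        assert mtrc.roc_auc([3, 4], [1, 2]).auc == 1.0
        assert mtrc.roc_auc([1, 2], [3, 4]).auc == 0.0

    def test_curve_starts_and_ends_at_corners_and_is_monotone(self):
        rng = np.random.default_rng(0)
        r = mtrc.roc_auc(rng.normal(1, 1, 30), rng.normal(0, 1, 40))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_empty_class_rejected(self):
        with pytest.raises(DomainError):
            mtrc.roc_auc([], [1.0])

    @given(
        tp=st.lists(st.integers(0, 8), min_size=1, max_size=30),
        tn=st.lists(st.integers(0, 8), min_size=1, max_size=30),
    )
    def test_matches_pairwise_oracle_with_heavy_ties(self, tp, tn):
        assert mtrc.roc_auc(tp, tn).auc == pytest.approx(pairwise_auc_oracle(tp, tn))

    @given(
        tp=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=25),
        tn=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=25),
    )
    def test_invariant_under_strictly_increasing_transform(self, tp, tn):
        base = mtrc.roc_auc(tp, tn).auc
        f = lambda x: np.asarray(x) ** 3 + 2.0 * np.asarray(x)
        assert mtrc.roc_auc(f(tp), f(tn)).auc == pytest.approx(base)

    def test_complement_rule_for_tie_free_scores(self):
        rng = np.random.default_rng(1)
        tp, tn = rng.normal(1, 1, 50), rng.normal(0, 1, 60)
        assert mtrc.roc_auc(tp, tn).auc + mtrc.roc_auc(-tp, -tn).auc == pytest.approx(1.0)

    def test_null_scores_center_on_half(self):
        rng = np.random.default_rng(2)
        aucs = [
            mtrc.roc_auc(rng.normal(size=500), rng.normal(size=500)).auc
            for _ in range(50)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestAucSe:
    def test_perfect_auc_has_zero_se(self):
        assert mtrc.auc_se(1.0, 7, 13) == 0.0
        assert mtrc.auc_se(0.0, 7, 13) == 0.0

    def test_null_value_small_samples(self):
        # closed form at A = 0.5: Q1 = Q2 = 1/3
        assert mtrc.auc_se(0.5, 10, 10) == pytest.approx(math.sqrt(0.0175), abs=1e-12)
        assert mtrc.auc_se(0.5, 10, 10) == pytest.approx(0.132, abs=5e-4)

    def test_matches_monte_carlo_sd_under_null(self):
        """Hanley-McNeil SE at A=0.5 vs the simulated SD of trapezoidal AUC."""
        rng = np.random.default_rng(3)
        n = 10
        scores = rng.standard_normal((10_000, 2 * n))
        ranks = scores.argsort(axis=1).argsort(axis=1) + 1
        auc = (ranks[:, :n].sum(axis=1) - n * (n + 1) / 2) / (n * n)
        assert mtrc.auc_se(0.5, n, n) == pytest.approx(auc.std(ddof=1), rel=0.10)

    def test_monotone_decreasing_in_class_sizes(self):
        for a in (0.5, 0.8, 0.95):
            ses = [mtrc.auc_se(a, n, 50) for n in (5, 10, 50, 200)]
            assert ses == sorted(ses, reverse=True)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            mtrc.auc_se(1.2, 5, 5)


class TestCompareAucs:
    def _roc(self, auc, se, label="x"):
        return mtrc.RocResult(label, 10, 10, np.array([0, 1.0]), np.array([0, 1.0]),
                              auc, se)

    def test_identical_results(self):
        r = self._roc(0.9, 0.01)
        c = mtrc.compare_aucs(r, r)
        assert (c.z, c.p) == (0.0, 1.0)

    def test_worked_z_example(self):
        c = mtrc.compare_aucs(self._roc(0.99, 0.004), self._roc(0.95, 0.012))
        assert c.z == pytest.approx(3.16, abs=5e-3)
        assert c.p == pytest.approx(2 * stats.norm.sf(c.z))
        assert c.significant_01

    def test_antisymmetry(self):
        a, b = self._roc(0.97, 0.01, "a"), self._roc(0.93, 0.02, "b")
        fwd, rev = mtrc.compare_aucs(a, b), mtrc.compare_aucs(b, a)
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.p == pytest.approx(rev.p)

    def test_degenerate_zero_se_with_different_aucs_warns(self):
        with pytest.warns(UserWarning):
            c = mtrc.compare_aucs(self._roc(1.0, 0.0), self._roc(0.0, 0.0))
        assert c.p == 0.0


class TestPairedTScores:
    def _frames(self, diffs, base=10.0):
        diffs = np.atleast_2d(np.asarray(diffs, float))
        probes = [f"p{i}" for i in range(diffs.shape[0])]
        m1 = pd.DataFrame(base + diffs, index=probes)
        m2 = pd.DataFrame(np.full_like(diffs, base), index=probes)
        analytes = mtrc.AnalyteTable.from_records(
            [(p, "liver", 5.0, 0.585) for p in probes]
        )
        return m1, m2, analytes

    def test_against_t_distribution_oracle(self):
        scores = mtrc.paired_t_scores(*self._frames([[1.0, 1.1, 0.9]]))
        t = 1.0 / (np.std([1.0, 1.1, 0.9], ddof=1) / math.sqrt(3))
        assert t == pytest.approx(17.32, abs=5e-3)
        expected_p = 2 * stats.t.sf(t, df=2)
        assert -scores.scores.iloc[0] == pytest.approx(expected_p)
        assert expected_p == pytest.approx(0.0033, abs=2e-4)

    def test_all_zero_differences_give_p_one(self):
        scores = mtrc.paired_t_scores(*self._frames([[0.0, 0.0, 0.0]]))
        assert scores.scores.iloc[0] == -1.0

    def test_constant_nonzero_differences_give_p_zero(self):
        scores = mtrc.paired_t_scores(*self._frames([[0.4, 0.4, 0.4]]))
        assert scores.scores.iloc[0] == 0.0

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(DomainError):
            mtrc.paired_t_scores(*self._frames([[1.0]]))


class TestSubsets:
    def test_mtrc4_subsets(self, mtrc4_design):
        analytes = mtrc.AnalyteTable.from_records(
            [("p1", "UHRR", 4.0, 0.0), ("p2", "liver", 4.0, math.log2(1.5)),
             ("p3", "HBRR", 4.0, 1.0), ("p4", "skeletal muscle", 4.0, -2.0)]
        )
        labels = [s.label for s in mtrc.fold_subsets(analytes)]
        assert labels == ["4-fold", "2-fold", "1.5-fold"]

    def test_mtrc3_reciprocal_subsets_combined_and_split(self):
        analytes = mtrc.AnalyteTable.from_records(
            [("p1", "HBRR", 4.0, 0.0),
             ("p2", "liver", 4.0, math.log2(1.5)),
             ("p3", "skeletal muscle", 4.0, -math.log2(1.5))]
        )
        subsets = mtrc.fold_subsets(analytes)
        assert [s.label for s in subsets] == [
            "1.5-fold", "1.5-fold up", "1.5-fold down"
        ]
        assert set(subsets[0].probes) == {"p2", "p3"}

    def test_signed_direction_flips_down_regulated_scores(self):
        # a 4-fold-down analyte measured at its target must outrank TNs
        analytes = mtrc.AnalyteTable.from_records(
            [("tn", "UHRR", 4.0, 0.0), ("tp", "skeletal muscle", 4.0, -2.0)]
        )
        mix1 = pd.Series({"tn": 8.0, "tp": 8.0})
        mix2 = pd.Series({"tn": 8.0, "tp": 10.0})  # observed ratio -2
        scores = mtrc.singlicate_scores(mix1, mix2, analytes)
        subset = mtrc.fold_subsets(analytes)[0]
        roc = mtrc.subset_roc(scores, subset, ["tn"])
        assert roc.auc == 1.0


class TestConcordance:
    def test_identical_vectors(self):
        v = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]})
        c = mtrc.replicate_concordance(v)
        assert c.mean == 1.0 and c.sd == 0.0

    def test_reversal_gives_minus_one(self):
        v = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1]})
        assert mtrc.replicate_concordance(v).mean == -1.0

    def test_rank_formula_example(self):
        v = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 3, 2]})
        assert mtrc.replicate_concordance(v).mean == pytest.approx(0.5)

    def test_needs_two_vectors(self):
        with pytest.raises(DomainError):
            mtrc.replicate_concordance(pd.DataFrame({"a": [1.0, 2]}))
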