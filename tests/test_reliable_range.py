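import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import mtrc
from mtrc.errors import DomainError
from mtrc.reliable_range import LrdBin, LrdBinSet, _bin_sizes

from conftest import make_matrix


def _mix_matrix(mix1_cols, mix2_cols, probes=None):
    values = np.column_stack(list(mix1_cols) + list(mix2_cols))
    roles = {}
    samples = []
    for i in range(len(mix1_cols)):
        samples.append(f"m1r{i+1}")
        roles[f"m1r{i+1}"] = ("Mix1", i + 1)
    for i in range(len(mix2_cols)):
        samples.append(f"m2r{i+1}")
        roles[f"m2r{i+1}"] = ("Mix2", i + 1)
    return make_matrix(values, probes=probes, samples=samples, roles=roles)


class TestRatioIntensity:
    def test_ma_convention(self):
        m = _mix_matrix([[10.0, 7.3]], [[8.0, 7.3]])
        ri = mtrc.ratio_intensity(m)
        assert ri.ratio.tolist() == [2.0, 0.0]
        assert ri.intensity.tolist() == [9.0, 7.3]

    def test_replicate_averaging(self):
        m = _mix_matrix(
            [[9.9], [10.0], [10.1]], [[8.0], [8.1], [7.9]]
        )
        # columns built per replicate: transpose layout via explicit arrays
        m = _mix_matrix(
            [np.array([9.9]), np.array([10.0]), np.array([10.1])],
            [np.array([8.0]), np.array([8.1]), np.array([7.9])],
        )
        ri = mtrc.ratio_intensity(m)
        assert ri.ratio.iloc[0] == pytest.approx(2.0)
        assert ri.intensity.iloc[0] == pytest.approx(9.0)

    def test_requires_both_mixes(self):
        m = make_matrix([[1.0]], samples=["a"], roles={"a": ("Mix1", 1)})
        with pytest.raises(DomainError):
            mtrc.ratio_intensity(m)


LIVER_TARGET = math.log2(1.5)


def _ri(r_values, i_values, probes=None):
    probes = probes or [f"p{i}" for i in range(len(r_values))]
    return mtrc.RatioIntensity(
        pd.DataFrame({"R": r_values, "I": i_values}, index=pd.Index(probes))
    )


class TestLrd:
    def test_on_target_and_compressed_examples(self):
        analytes = mtrc.AnalyteTable.from_records(
            [("p0", "liver", 5.0, LIVER_TARGET), ("p1", "skeletal muscle", 5.0, -2.0)]
        )
        out = mtrc.lrd(_ri([LIVER_TARGET, -1.2], [9.0, 8.0]), analytes)
        assert out["p0"] == 0.0
        assert out["p1"] == pytest.approx(0.8)  # compression shows as positive LRD

    def test_missing_analyte_is_coverage_error(self):
        analytes = mtrc.AnalyteTable.from_records([("missing", "liver", 5.0, 0.585)])
        with pytest.raises(mtrc.CoverageError):
            mtrc.lrd(_ri([0.0], [8.0]), analytes)


class TestGlobalRatioSd:
    def test_constant_ratios_rejected(self):
        with pytest.raises(DomainError):
            mtrc.global_ratio_sd(_ri([0.3] * 10, list(range(10))))

    def test_recovers_simulated_sd(self):
        rng = np.random.default_rng(0)
        r = rng.normal(0, 0.3, 10_000)
        assert mtrc.global_ratio_sd(_ri(r, np.zeros_like(r))) == pytest.approx(
            0.30, abs=0.01
        )

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        r = rng.normal(0, 0.4, 500)
        a = mtrc.global_ratio_sd(_ri(r, np.zeros_like(r)))
        b = mtrc.global_ratio_sd(_ri(r + 2.5, np.zeros_like(r)))
        assert a == pytest.approx(b)


class TestBinning:
    @pytest.mark.parametrize(
        "n, n_bins, policy, sizes, omitted",
        [
            (838, 20, "merge_low", [40] + [42] * 19, 0),
            (565, 20, "omit_low", [28] * 20, 5),
            (100, 10, "merge_low", [10] * 10, 0),
            (100, 10, "omit_low", [10] * 10, 0),
        ],
    )
    def test_bin_size_rules(self, n, n_bins, policy, sizes, omitted):
        got_sizes, got_omit = _bin_sizes(n, n_bins, policy)
        assert got_sizes == sizes
        assert got_omit == omitted

    def test_too_few_analytes_rejected(self):
        with pytest.raises(DomainError):
            _bin_sizes(5, 20, "merge_low")

    def test_bins_partition_non_reference_analytes(self):
        rng = np.random.default_rng(2)
        n = 113
        probes = [f"p{i}" for i in range(n)]
        records = [("ref0", "UHRR", 5.0, 0.0)] + [
            (p, "liver", 5.0, LIVER_TARGET) for p in probes
        ]
        analytes = mtrc.AnalyteTable(
            pd.DataFrame(records, columns=["probe_id", "component", "mean_tsi",
                                           "target_log2_ratio"])
        )
        ri = _ri(
            rng.normal(0.5, 0.1, n + 1), rng.uniform(6, 14, n + 1),
            probes=["ref0"] + probes,
        )
        binset = mtrc.bin_analytes(ri, analytes, n_bins=10, remainder_policy="omit_low")
        members = [p for b in binset.bins for p in b.probes]
        assert sorted(members + list(binset.omitted_probes)) == sorted(probes)
        assert "ref0" not in members
        # contiguous, ascending intensity spans
        for left, right in zip(binset.bins, binset.bins[1:]):
            assert left.intensity_max <= right.intensity_min


class TestBinChisq:
    def _bin(self, lrd_values):
        arr = np.asarray(lrd_values, float)
        return LrdBin(tuple(f"p{i}" for i in range(arr.size)), arr, np.zeros_like(arr))

    def test_zero_deviation_always_passes(self):
        chi2, passed = mtrc.bin_chisq(self._bin([0.0] * 10), s=0.3, alpha=0.01)
        assert chi2 == 0.0 and passed

    def test_deviation_equal_to_s_passes_at_df_n(self):
        s = 0.31
        chi2, passed = mtrc.bin_chisq(self._bin([s] * 42), s=s, alpha=0.01)
        assert chi2 == pytest.approx(42.0)
        assert stats.chi2.ppf(0.99, 42) == pytest.approx(66.2, abs=0.05)
        assert passed

    def test_deviation_twice_s_fails(self):
        s = 0.31
        chi2, passed = mtrc.bin_chisq(self._bin([2 * s] * 42), s=s, alpha=0.01)
        assert chi2 == pytest.approx(168.0)
        assert not passed

    def test_nonpositive_s_rejected(self):
        with pytest.raises(DomainError):
            mtrc.bin_chisq(self._bin([0.1]), s=0.0)

    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        lrds=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=30),
    )
    def test_scale_consistency(self, scale, lrds):
        s = 0.25
        base, _ = mtrc.bin_chisq(self._bin(lrds), s=s)
        scaled, _ = mtrc.bin_chisq(
            self._bin([x * scale for x in lrds]), s=s * scale
        )
        assert scaled == pytest.approx(base, rel=1e-9)


def _binset_with(flags, spans):
    """Bin set with prescribed pass/fail flags and intensity spans."""
    bins = []
    intensities = []
    for passed, (lo, hi) in zip(flags, spans):
        member_i = np.array([lo, (lo + hi) / 2, hi])
        b = LrdBin(tuple(f"b{lo}_{i}" for i in range(3)), np.zeros(3), member_i)
        b.chi2, b.passed = 0.0, passed
        bins.append(b)
        intensities.extend(member_i)
    index = pd.Index([p for b in bins for p in b.probes])
    series = pd.Series(intensities, index=index)
    return LrdBinSet(bins, series, pd.Series(np.zeros(len(series)), index=index),
                     (), "merge_low", s=0.3, alpha=0.01)


class TestReliableRange:
    def test_interior_passing_run(self):
        binset = _binset_with(
            [False, True, True, True, False],
            [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10)],
        )
        rr = mtrc.reliable_range(binset)
        assert (rr.lower, rr.upper, rr.length) == (2.0, 8.0, 6.0)
        assert rr.n_passing_bins == 3

    def test_all_bins_pass_spans_full_intensity_range(self):
        binset = _binset_with([True] * 4, [(1, 3), (3, 5), (5, 7), (7, 9)])
        rr = mtrc.reliable_range(binset)
        assert (rr.lower, rr.upper) == (1.0, 9.0)
        assert rr.coverage == 1.0

    def test_no_passing_bin_gives_empty_range(self):
        rr = mtrc.reliable_range(_binset_with([False, False], [(0, 2), (2, 4)]))
        assert rr.is_empty and rr.length == 0.0 and rr.coverage == 0.0

    def test_tie_prefers_higher_intensity_run(self):
        binset = _binset_with(
            [True, True, False, True, True],
            [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10)],
        )
        rr = mtrc.reliable_range(binset)
        assert (rr.lower, rr.upper) == (6.0, 10.0)

    def test_range_length_non_increasing_in_alpha(self, noisy_run):
        """Stricter critical values can only shrink the passing run."""
        _, _, results = noisy_run
        lengths = []
        for alpha in (0.001, 0.01, 0.05):
            binset = mtrc.bin_analytes(results.ri, results.model.analytes)
            mtrc.evaluate_bins(binset, results.s, alpha=alpha)
            lengths.append(mtrc.reliable_range(binset).length)
        assert lengths == sorted(lengths, reverse=True)
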