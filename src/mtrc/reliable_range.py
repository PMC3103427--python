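"""Reliable range of comparative measurement from binned log2 ratio deviations.

Per probe, the observed log2 ratio R is the difference of the replicate-
averaged normalized Mix1 and Mix2 signals and I is their mean (the MA-plot
convention). For each MTRC analyte the log2 ratio deviation (LRD) is
R - target log2 ratio: zero for a perfectly measured analyte, pushed toward
-target near the background floor and the saturation ceiling where ratios
compress.

Analytes (excluding the 1:1 reference component) are rank-ordered by I and
cut into bins of approximately equal size. Each bin is tested for goodness of
fit against the array-wide ratio noise with

    chi2 = sum_i LRD_i^2 / s^2,

where s is the sample standard deviation of R over *all* probe sets on the
array, compared to the upper chi-square quantile at significance alpha
(default 0.01) with df = n (the bin size; df = n - 1 selectable). The longest
run of contiguous passing bins defines the reliable range; its limits are the
minimum and maximum member intensities of the first and last passing bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, DomainError
from .io import MIX1, MIX2, AnalyteTable, ExpressionMatrix


@dataclass(frozen=True)
class RatioIntensity:
    """Per-probe observed log2 ratio (R) and mean log2 intensity (I)."""

    table: pd.DataFrame  # columns: R, I; index: probe id

    @property
    def ratio(self) -> pd.Series:
        return self.table["R"]

    @property
    def intensity(self) -> pd.Series:
        return self.table["I"]


def ratio_intensity(matrix: ExpressionMatrix) -> RatioIntensity:
    """R = mean(Mix1) - mean(Mix2), I = their midpoint, per probe."""
    labels1 = matrix.labels_for(MIX1)
    labels2 = matrix.labels_for(MIX2)
    if not labels1 or not labels2:
        raise DomainError("matrix needs >= 1 replicate for each of Mix1 and Mix2")
    m1 = matrix.data[labels1].mean(axis=1)
    m2 = matrix.data[labels2].mean(axis=1)
    return RatioIntensity(pd.DataFrame({"R": m1 - m2, "I": (m1 + m2) / 2.0}))


def lrd(ri: RatioIntensity, analytes: AnalyteTable) -> pd.Series:
    """Log2 ratio deviation per analyte: observed R minus target log2 ratio."""
    targets = analytes.targets
    if targets.isna().any():
        raise DomainError("analyte table has NaN targets; join a design first")
    missing = [p for p in targets.index if p not in ri.table.index]
    if missing:
        raise CoverageError(f"analytes absent from ratio table: {missing[:10]}")
    return ri.ratio.loc[targets.index] - targets


def global_ratio_sd(ri: RatioIntensity) -> float:
    """Sample sd (n-1 denominator) of R over every probe set on the array."""
    r = ri.ratio.to_numpy(dtype=float)
    if r.size < 2:
        raise DomainError("global ratio sd needs >= 2 probes")
    if np.all(r == r[0]):
        raise DomainError("all log2 ratios identical: global sd is 0")
    return float(r.std(ddof=1))


@dataclass
class LrdBin:
    """One intensity-rank bin of analytes and (after evaluation) its chi2 test."""

    probes: tuple[str, ...]
    lrd: np.ndarray
    intensity: np.ndarray
    chi2: float | None = None
    passed: bool | None = None

    @property
    def n(self) -> int:
        return len(self.probes)

    @property
    def mean_lrd(self) -> float:
        return float(self.lrd.mean())

    @property
    def lrd_sd(self) -> float:
        return float(self.lrd.std(ddof=1)) if self.n > 1 else 0.0

    @property
    def intensity_min(self) -> float:
        return float(self.intensity.min())

    @property
    def intensity_max(self) -> float:
        return float(self.intensity.max())

    @property
    def intensity_mean(self) -> float:
        return float(self.intensity.mean())


@dataclass
class LrdBinSet:
    """Ordered (ascending intensity) bins plus the global test parameters."""

    bins: list[LrdBin]
    intensity: pd.Series          # I per analyte, including omitted probes
    lrd_values: pd.Series         # LRD per binned analyte
    omitted_probes: tuple[str, ...]
    remainder_policy: str
    s: float | None = None
    alpha: float | None = None
    df_mode: str = "n"

    @property
    def evaluated(self) -> bool:
        return all(b.passed is not None for b in self.bins)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.bins, start=1):
            rows.append(
                {
                    "bin": i,
                    "n": b.n,
                    "mean_lrd": b.mean_lrd,
                    "lrd_sd": b.lrd_sd,
                    "intensity_min": b.intensity_min,
                    "intensity_mean": b.intensity_mean,
                    "intensity_max": b.intensity_max,
                    "chi2": b.chi2,
                    "passed": b.passed,
                }
            )
        return pd.DataFrame(rows)


def _bin_sizes(n: int, n_bins: int, remainder_policy: str) -> tuple[list[int], int]:
    """Bin sizes (ascending intensity order) and the number of omitted analytes."""
    if n_bins < 2:
        raise DomainError("need at least 2 bins")
    if n < n_bins:
        raise DomainError(f"cannot distribute {n} analytes into {n_bins} bins")
    if remainder_policy == "merge_low":
        # equal-size upper bins; the lowest-intensity bin absorbs the deficit
        # or surplus (e.g. 838 -> 19 bins of 42 plus a low bin of 40)
        size = math.floor(n / n_bins + 0.5)
        if n - (n_bins - 1) * size < 1:
            size = n // n_bins
        low = n - (n_bins - 1) * size
        return [low] + [size] * (n_bins - 1), 0
    if remainder_policy == "omit_low":
        size = n // n_bins
        omit = n - size * n_bins
        return [size] * n_bins, omit
    raise DomainError(f"unknown remainder policy {remainder_policy!r}")


def bin_analytes(
    ri: RatioIntensity,
    analytes: AnalyteTable,
    n_bins: int = 20,
    remainder_policy: str = "merge_low",
    include_reference: bool = False,
) -> LrdBinSet:
    """Rank non-reference analytes by intensity and cut them into bins.

    ``merge_low`` keeps every analyte, letting the lowest-intensity bin hold
    the remainder; ``omit_low`` drops the lowest-intensity remainder so all
    bins are exactly equal. Ties in intensity are broken by probe id for
    determinism. The returned bin set has no chi-square results yet; call
    :func:`evaluate_bins`.
    """
    working = analytes if include_reference else analytes.non_reference()
    deviations = lrd(ri, working)
    intensity = ri.intensity.loc[deviations.index]
    order = sorted(deviations.index, key=lambda p: (intensity.loc[p], p))
    sizes, n_omit = _bin_sizes(len(order), n_bins, remainder_policy)
    omitted = tuple(order[:n_omit])
    ranked = order[n_omit:]
    bins: list[LrdBin] = []
    start = 0
    for size in sizes:
        members = ranked[start : start + size]
        start += size
        bins.append(
            LrdBin(
                probes=tuple(members),
                lrd=deviations.loc[members].to_numpy(dtype=float),
                intensity=intensity.loc[members].to_numpy(dtype=float),
            )
        )
    return LrdBinSet(
        bins=bins,
        intensity=intensity,
        lrd_values=deviations.loc[ranked],
        omitted_probes=omitted,
        remainder_policy=remainder_policy,
    )


def bin_chisq(
    lrd_bin: LrdBin, s: float, alpha: float = 0.01, df_mode: str = "n"
) -> tuple[float, bool]:
    """chi2 = sum(LRD^2) / s^2 against the upper chi-square quantile at alpha."""
    if not s > 0:
        raise DomainError(f"s must be > 0, got {s}")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if lrd_bin.n == 0:
        raise DomainError("empty bin")
    if df_mode not in ("n", "n-1"):
        raise DomainError(f"df_mode must be 'n' or 'n-1', got {df_mode!r}")
    chi2 = float(np.sum(lrd_bin.lrd**2) / s**2)
    df = lrd_bin.n if df_mode == "n" else lrd_bin.n - 1
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    return chi2, chi2 <= critical


def evaluate_bins(
    binset: LrdBinSet, s: float, alpha: float = 0.01, df_mode: str = "n"
) -> LrdBinSet:
    """Run the per-bin chi-square test in place and record s, alpha, df."""
    for b in binset.bins:
        b.chi2, b.passed = bin_chisq(b, s, alpha, df_mode)
    binset.s = s
    binset.alpha = alpha
    binset.df_mode = df_mode
    return binset


@dataclass(frozen=True)
class ReliableRange:
    """Contiguous log2-intensity span whose LRD bins pass the chi-square test."""

    lower: float
    upper: float
    length: float
    coverage: float
    n_passing_bins: int
    is_empty: bool = False


def reliable_range(binset: LrdBinSet, intensities: pd.Series | None = None) -> ReliableRange:
    """Longest run of contiguous passing bins (ties -> higher intensity).

    The limits are the min/max member intensities of the run's first and last
    bin. Coverage is the fraction of analytes in the LRD analysis (binned plus
    omitted) whose intensity falls inside the limits; a different population
    can be supplied via `intensities`. If no bin passes, an empty range of
    length 0 is returned.
    """
    if not binset.evaluated:
        raise DomainError("bin set has no chi-square results; call evaluate_bins first")
    flags = [bool(b.passed) for b in binset.bins]
    runs: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(flags + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i - 1))
            start = None
    if not runs:
        return ReliableRange(math.nan, math.nan, 0.0, 0.0, 0, is_empty=True)
    best = runs[0]
    for run in runs[1:]:
        if run[1] - run[0] >= best[1] - best[0]:  # ties prefer the higher-intensity run
            best = run
    lower = binset.bins[best[0]].intensity_min
    upper = binset.bins[best[1]].intensity_max
    pop = binset.intensity if intensities is None else intensities
    inside = (pop >= lower) & (pop <= upper)
    coverage = float(inside.mean()) if len(pop) else 0.0
    return ReliableRange(lower, upper, upper - lower, coverage, best[1] - best[0] + 1)
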