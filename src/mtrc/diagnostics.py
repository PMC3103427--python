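"""Diagnostic-performance metrics: analyte ranking, ROC/AUC, AUC comparison.

The MTRC turns diagnostic accuracy into a benchmark number: the analytes of
the 1:1 reference component are true negatives, and each fold-change subset
(1.5-, 2-, 4-fold, ...) supplies true positives for its own ROC plot. Two
ranking modes are supported:

``singlicate``
    One array pair; analytes are ranked by their normalized log2 ratio. By
    default ("signed" direction) a true positive's ratio is multiplied by the
    sign of its target so down-regulated subsets rank correctly; true
    negatives keep the raw ratio. An "absolute" mode ranks |ratio| for both
    classes.

``replicate``
    >= 2 paired technical replicates; analytes are ranked by the two-sided
    paired t-test p-value of the Mix1 - Mix2 log2 signal differences (smaller
    p ranks higher; the score is -p). Degenerate probes are given sentinel
    p-values: all-zero differences -> p = 1 (no evidence), constant nonzero
    differences -> p = 0 (infinite t).

AUC is computed by the trapezoidal rule on the threshold-swept ROC curve
(ties collapsed into a single step), which equals the Mann-Whitney statistic
U / (n_tp * n_tn) with tied pairs counted 1/2. Standard errors follow Hanley
& McNeil; AUC differences are tested with a z statistic assuming independent
curves (the correlated variant needs rank correlations that are not part of
this procedure).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, DomainError
from .io import AnalyteTable


# ---------------------------------------------------------------------------
# ranking scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankingScores:
    """Per-analyte evidence-of-change scores (higher = more evidence).

    For method ``singlicate-log2ratio`` the stored scores are the raw
    normalized log2 ratios; direction handling happens when a subset ROC is
    built. For ``replicate-paired-t`` the scores are -p and are used as-is.
    """

    scores: pd.Series
    method: str
    direction: str = "signed"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise DomainError("ranking scores must be finite")


def _require_probes(series_index, probes: Sequence[str], what: str) -> None:
    missing = [p for p in probes if p not in series_index]
    if missing:
        raise CoverageError(f"{what}: probes missing: {missing[:10]}")


def log2_ratios(mix1: pd.Series, mix2: pd.Series, probes: Sequence[str] | None = None) -> pd.Series:
    """Mix1 - Mix2 log2 ratios, optionally restricted to `probes`."""
    ratios = mix1 - mix2
    if probes is not None:
        _require_probes(ratios.index, probes, "log2 ratios")
        ratios = ratios.loc[list(probes)]
    return ratios


def singlicate_scores(
    mix1: pd.Series,
    mix2: pd.Series,
    analytes: AnalyteTable,
    direction: str = "signed",
) -> RankingScores:
    """Log2-ratio ranking scores for a single array pair."""
    if direction not in ("signed", "absolute"):
        raise DomainError(f"direction must be 'signed' or 'absolute', got {direction!r}")
    ratios = log2_ratios(mix1, mix2, analytes.probes)
    return RankingScores(ratios, "singlicate-log2ratio", direction)


def paired_t_scores(
    mix1_reps: pd.DataFrame,
    mix2_reps: pd.DataFrame,
    analytes: AnalyteTable,
) -> RankingScores:
    """-p of the two-sided paired t-test on replicate-paired log2 differences.

    `mix1_reps` and `mix2_reps` are probes x replicates frames whose columns
    are aligned by replicate index.
    """
    if mix1_reps.shape[1] != mix2_reps.shape[1]:
        raise DomainError("mix1 and mix2 must have the same number of replicates")
    k = mix1_reps.shape[1]
    if k < 2:
        raise DomainError("paired t ranking needs >= 2 replicates")
    probes = analytes.probes
    _require_probes(mix1_reps.index, probes, "paired t scores (Mix1)")
    _require_probes(mix2_reps.index, probes, "paired t scores (Mix2)")
    d = mix1_reps.loc[probes].to_numpy(dtype=float) - mix2_reps.loc[probes].to_numpy(dtype=float)
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.empty(len(probes))
    regular = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean[regular] / (sd[regular] / math.sqrt(k))
    p[regular] = 2.0 * stats.t.sf(np.abs(t), df=k - 1)
    p[~regular & (mean == 0)] = 1.0
    p[~regular & (mean != 0)] = 0.0
    return RankingScores(pd.Series(-p, index=pd.Index(probes)), "replicate-paired-t")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """One ROC curve: swept (FPR, TPR) points, trapezoidal AUC and its SE."""

    label: str
    n_tp: int
    n_tn: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def roc_auc(tp_scores, tn_scores, label: str = "") -> RocResult:
    """ROC by threshold sweep (tied scores collapsed) and trapezoidal AUC."""
    tp = np.asarray(tp_scores, dtype=float)
    tn = np.asarray(tn_scores, dtype=float)
    if tp.size == 0 or tn.size == 0:
        raise DomainError("ROC needs non-empty true-positive and true-negative sets")
    if not (np.isfinite(tp).all() and np.isfinite(tn).all()):
        raise DomainError("ROC scores must be finite")
    scores = np.concatenate([tp, tn])
    truth = np.concatenate([np.ones(tp.size, dtype=bool), np.zeros(tn.size, dtype=bool)])
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = truth[order]
    # one ROC step per distinct score value
    last_of_tie = np.r_[s[1:] != s[:-1], True]
    cum_tp = np.cumsum(y)[last_of_tie]
    cum_fp = np.cumsum(~y)[last_of_tie]
    tpr = np.r_[0.0, cum_tp / tp.size]
    fpr = np.r_[0.0, cum_fp / tn.size]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(label, tp.size, tn.size, fpr, tpr, auc, auc_se(auc, tp.size, tn.size))


def auc_se(auc: float, n_tp: int, n_tn: int) -> float:
    """Hanley-McNeil standard error of a trapezoidal AUC.

    With A the AUC, Q1 = A / (2 - A) and Q2 = 2 A^2 / (1 + A):
    SE^2 = [A(1-A) + (n_tp - 1)(Q1 - A^2) + (n_tn - 1)(Q2 - A^2)] / (n_tp n_tn).
    """
    if not 0.0 <= auc <= 1.0:
        raise DomainError(f"AUC must lie in [0, 1], got {auc}")
    if n_tp < 1 or n_tn < 1:
        raise DomainError("class counts must be >= 1")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_tp - 1) * (q1 - auc * auc)
        + (n_tn - 1) * (q2 - auc * auc)
    ) / (n_tp * n_tn)
    return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class AucComparison:
    """z test for the difference of two AUCs treated as independent."""

    label_1: str
    label_2: str
    z: float
    p: float

    @property
    def significant_05(self) -> bool:
        return self.p < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p < 0.01


def compare_aucs(r1: RocResult, r2: RocResult) -> AucComparison:
    """z = (A1 - A2) / sqrt(SE1^2 + SE2^2), two-sided normal p."""
    denom = math.sqrt(r1.se**2 + r2.se**2)
    diff = r1.auc - r2.auc
    if denom == 0.0:
        if diff == 0.0:
            return AucComparison(r1.label, r2.label, 0.0, 1.0)
        warnings.warn(
            "both AUC standard errors are zero but the AUCs differ; "
            "reporting a p = 0 sentinel",
            UserWarning,
            stacklevel=2,
        )
        return AucComparison(r1.label, r2.label, math.copysign(math.inf, diff), 0.0)
    z = diff / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return AucComparison(r1.label, r2.label, float(z), float(p))


# ---------------------------------------------------------------------------
# fold-change subsets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldSubset:
    """One true-positive subset: its label, member probes and per-probe targets."""

    label: str
    probes: tuple[str, ...]
    targets: Mapping[str, float]
    target_values: tuple[float, ...]


def _fold_label(target: float) -> str:
    return f"{2.0 ** abs(target):.3g}-fold"


def fold_subsets(analytes: AnalyteTable, combine_reciprocal: bool = True) -> list[FoldSubset]:
    """Group non-reference analytes into true-positive subsets by target ratio.

    Subsets are ordered by descending fold magnitude. When reciprocal targets
    (+-tau) coexist (as in the three-component design) and
    ``combine_reciprocal`` is true, a combined subset containing both
    directions is emitted first, followed by the per-direction subsets.
    """
    records = analytes.non_reference().records
    if records["target_log2_ratio"].isna().any():
        raise DomainError("analyte table has NaN targets; join a design first")
    by_target: dict[float, list[str]] = {}
    exact: dict[float, float] = {}
    for probe, target in zip(records["probe_id"], records["target_log2_ratio"]):
        key = round(float(target), 9)  # reciprocal targets agree only to rounding
        by_target.setdefault(key, []).append(probe)
        exact[key] = float(target)

    magnitudes = sorted({abs(t) for t in by_target}, reverse=True)
    subsets: list[FoldSubset] = []
    for mag in magnitudes:
        directions = sorted([t for t in by_target if abs(t) == mag], reverse=True)
        base = _fold_label(mag)
        if len(directions) == 2 and combine_reciprocal:
            probes = tuple(itertools.chain.from_iterable(by_target[t] for t in directions))
            targets = {p: exact[t] for t in directions for p in by_target[t]}
            subsets.append(
                FoldSubset(base, probes, targets, tuple(exact[t] for t in directions))
            )
        for t in directions:
            label = base if len(directions) == 1 else f"{base} {'up' if t > 0 else 'down'}"
            probes = tuple(by_target[t])
            subsets.append(
                FoldSubset(label, probes, {p: exact[t] for p in probes}, (exact[t],))
            )
    return subsets


def subset_roc(
    scores: RankingScores,
    subset: FoldSubset,
    tn_probes: Sequence[str],
) -> RocResult:
    """ROC of one true-positive subset against the shared true-negative set."""
    _require_probes(scores.scores.index, list(subset.probes) + list(tn_probes), "subset ROC")
    if scores.method == "singlicate-log2ratio":
        ratios = scores.scores
        if scores.direction == "absolute":
            tp_s = ratios.loc[list(subset.probes)].abs().to_numpy()
            tn_s = ratios.loc[list(tn_probes)].abs().to_numpy()
        else:
            sign = np.array([math.copysign(1.0, subset.targets[p]) for p in subset.probes])
            tp_s = ratios.loc[list(subset.probes)].to_numpy() * sign
            tn_s = ratios.loc[list(tn_probes)].to_numpy()
    else:
        tp_s = scores.scores.loc[list(subset.probes)].to_numpy()
        tn_s = scores.scores.loc[list(tn_probes)].to_numpy()
    return roc_auc(tp_s, tn_s, label=subset.label)


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Concordance:
    """Mean +- sd of pairwise Spearman rank correlations between replicates."""

    mean: float
    sd: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def replicate_concordance(ratio_vectors: pd.DataFrame) -> Concordance:
    """All C(k, 2) pairwise Spearman rho between per-replicate ratio vectors.

    `ratio_vectors` is analytes x replicates; ranks use average ranking for
    ties (the scipy default).
    """
    cols = list(ratio_vectors.columns)
    if len(cols) < 2:
        raise DomainError("concordance needs >= 2 replicate ratio vectors")
    if ratio_vectors.isna().to_numpy().any():
        raise DomainError("ratio vectors contain missing values")
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(cols, 2):
        rho = stats.spearmanr(ratio_vectors[a], ratio_vectors[b]).statistic
        pairwise[(str(a), str(b))] = float(rho)
    values = np.array(list(pairwise.values()))
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return Concordance(float(values.mean()), sd, pairwise)
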