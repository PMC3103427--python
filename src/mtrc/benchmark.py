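"""End-to-end MTRC benchmark: a model object and its fitted results.

:class:`MtrcBenchmark` is built from an expression matrix, an analyte table
and (optionally) the mixture design; ``fit()`` normalizes the mixes, ranks
the analytes, computes one ROC/AUC per fold-change subset with Hanley-McNeil
standard errors and pairwise AUC-difference tests, measures replicate ratio
concordance, and derives the reliable range of measurement from binned log2
ratio deviations. The returned :class:`BenchmarkResults` carries every
intermediate product, a ``summary()`` table, TSV/JSON report writers and
RI-/LRD-plot methods.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .design import MixtureDesign
from .diagnostics import (
    AucComparison,
    Concordance,
    FoldSubset,
    RankingScores,
    RocResult,
    compare_aucs,
    fold_subsets,
    log2_ratios,
    paired_t_scores,
    replicate_concordance,
    singlicate_scores,
    subset_roc,
)
from .errors import DomainError
from .io import MIX1, MIX2, AnalyteTable, ExpressionMatrix, FLOAT_FORMAT
from .normalization import NormalizationResult, normalize_mixes
from .reliable_range import (
    LrdBinSet,
    RatioIntensity,
    ReliableRange,
    bin_analytes,
    evaluate_bins,
    global_ratio_sd,
    ratio_intensity,
    reliable_range,
)

_COMPONENT_COLORS = ("tab:red", "tab:green", "tab:blue", "black", "tab:orange", "tab:purple")


class MtrcBenchmark:
    """Benchmark model over one MTRC dataset.

    Parameters
    ----------
    matrix:
        Expression matrix with paired Mix1/Mix2 technical replicates
        (normalized log2 signals; normalization is applied as the first fit
        stage and is idempotent, so pre-normalized input is fine).
    analytes:
        Tissue-selective analytes with target log2 ratios.
    design:
        Optional mixture design (used for naming and the reference lookup).
    mode:
        ``"replicate"`` (paired-t ranking, needs >= 2 replicate pairs) or
        ``"singlicate"`` (log2-ratio ranking on one pair).
    direction:
        Singlicate ranking direction, ``"signed"`` or ``"absolute"``.
    n_bins, remainder_policy, alpha, df_mode:
        Reliable-range parameters. The default remainder policy follows the
        design type: designs with >= 4 components merge the remainder into
        the lowest bin, smaller designs omit the lowest-intensity remainder.
    combine_reciprocal:
        Combine reciprocal (+-tau) subsets into one ROC in addition to the
        per-direction breakdown.
    trim_fraction:
        Trimming fraction for the normalization trimmed mean.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        analytes: AnalyteTable,
        design: MixtureDesign | None = None,
        *,
        mode: str = "replicate",
        direction: str = "signed",
        n_bins: int = 20,
        remainder_policy: str | None = None,
        alpha: float = 0.01,
        df_mode: str = "n",
        combine_reciprocal: bool = True,
        trim_fraction: float = 0.10,
        reference_component: str | None = None,
    ):
        if mode not in ("replicate", "singlicate"):
            raise DomainError(f"mode must be 'replicate' or 'singlicate', got {mode!r}")
        self.matrix = matrix
        self.analytes = analytes
        self.design = design
        self.mode = mode
        self.direction = direction
        self.n_bins = n_bins
        if remainder_policy is None:
            n_components = len(design.components) if design else len(analytes.components)
            remainder_policy = "merge_low" if n_components >= 4 else "omit_low"
        self.remainder_policy = remainder_policy
        self.alpha = alpha
        self.df_mode = df_mode
        self.combine_reciprocal = combine_reciprocal
        self.trim_fraction = trim_fraction
        self.reference_component = reference_component or analytes.reference_component
        if self.reference_component is None:
            raise DomainError("no unique reference (1:1) component; pass reference_component")

    @classmethod
    def from_files(
        cls,
        matrix_path,
        roles_path,
        analytes_path,
        design_path=None,
        **options,
    ) -> "MtrcBenchmark":
        from .io import read_expression_matrix, read_role_map

        roles = read_role_map(roles_path)
        matrix = read_expression_matrix(matrix_path, roles)
        analytes = AnalyteTable.from_tsv(analytes_path)
        design = MixtureDesign.from_toml(design_path) if design_path else None
        return cls(matrix, analytes, design, **options)

    # ------------------------------------------------------------------

    def fit(self) -> "BenchmarkResults":
        normalization = normalize_mixes(
            self.matrix, self.analytes, self.reference_component, self.trim_fraction
        )
        normalized = normalization.matrix
        pairs = normalized.paired_replicates(MIX1, MIX2)
        tn_probes = self.analytes.probes_for(self.reference_component)

        scores = self._scores(normalized, pairs)
        subsets = fold_subsets(self.analytes, self.combine_reciprocal)
        rocs = {sub.label: subset_roc(scores, sub, tn_probes) for sub in subsets}
        comparisons = {
            (a, b): compare_aucs(rocs[a], rocs[b])
            for a, b in itertools.combinations(rocs, 2)
        }

        concordance = None
        if len(pairs) >= 2:
            vectors = pd.DataFrame(
                {
                    f"rep{rep}": log2_ratios(
                        normalized.data[l1], normalized.data[l2], self.analytes.probes
                    )
                    for rep, l1, l2 in pairs
                }
            )
            concordance = replicate_concordance(vectors)

        ri = ratio_intensity(normalized)
        s = global_ratio_sd(ri)
        binset = bin_analytes(ri, self.analytes, self.n_bins, self.remainder_policy)
        evaluate_bins(binset, s, self.alpha, self.df_mode)
        rng = reliable_range(binset)

        provenance = {
            "package_version": __version__,
            "design": self.design.name if self.design else None,
            "mode": self.mode,
            "direction": self.direction,
            "n_probes": self.matrix.shape[0],
            "n_samples": self.matrix.shape[1],
            "n_analytes": len(self.analytes),
            "analyte_counts": self.analytes.counts(),
            "reference_component": self.reference_component,
            "n_replicate_pairs": len(pairs),
            "n_bins": self.n_bins,
            "remainder_policy": self.remainder_policy,
            "alpha": self.alpha,
            "df_mode": self.df_mode,
            "trim_fraction": self.trim_fraction,
        }
        return BenchmarkResults(
            model=self,
            normalization=normalization,
            scores=scores,
            subsets=subsets,
            rocs=rocs,
            comparisons=comparisons,
            concordance=concordance,
            ri=ri,
            s=s,
            binset=binset,
            reliable_range=rng,
            provenance=provenance,
        )

    def _scores(self, normalized: ExpressionMatrix, pairs) -> RankingScores:
        if self.mode == "replicate":
            if len(pairs) < 2:
                raise DomainError("replicate mode needs >= 2 replicate pairs")
            m1 = normalized.data[[l1 for _, l1, _ in pairs]]
            m2 = normalized.data[[l2 for _, _, l2 in pairs]]
            return paired_t_scores(m1, m2, self.analytes)
        if len(pairs) > 1:
            warnings.warn(
                "singlicate mode with multiple replicate pairs: using replicate 1",
                UserWarning,
                stacklevel=2,
            )
        _, l1, l2 = pairs[0]
        return singlicate_scores(
            normalized.data[l1], normalized.data[l2], self.analytes, self.direction
        )


def run_benchmark(
    matrix: ExpressionMatrix,
    analytes: AnalyteTable,
    design: MixtureDesign | None = None,
    **options,
) -> "BenchmarkResults":
    """One-call convenience wrapper: build the model and fit it."""
    return MtrcBenchmark(matrix, analytes, design, **options).fit()


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkResults:
    """Everything :meth:`MtrcBenchmark.fit` computed, with report writers."""

    model: MtrcBenchmark
    normalization: NormalizationResult
    scores: RankingScores
    subsets: list[FoldSubset]
    rocs: dict[str, RocResult]
    comparisons: dict[tuple[str, str], AucComparison]
    concordance: Concordance | None
    ri: RatioIntensity
    s: float
    binset: LrdBinSet
    reliable_range: ReliableRange
    provenance: dict[str, Any] = field(default_factory=dict)

    # -- tabular views -------------------------------------------------

    def auc_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": r.label, "n_tp": r.n_tp, "n_tn": r.n_tn, "auc": r.auc, "se": r.se}
            for r in self.rocs.values()
        ]
        return pd.DataFrame(rows)

    def comparison_frame(self) -> pd.DataFrame:
        rows = [
            {"subset_1": a, "subset_2": b, "z": c.z, "p": c.p,
             "significant_0.05": c.significant_05, "significant_0.01": c.significant_01}
            for (a, b), c in self.comparisons.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.provenance
        rr = self.reliable_range
        lines = [
            "MTRC benchmark results",
            "======================",
            f"design: {p.get('design') or '(unnamed)'}    mode: {p['mode']}    "
            f"probes: {p['n_probes']}    analytes: {p['n_analytes']}",
            f"reference component: {p['reference_component']}    "
            f"replicate pairs: {p['n_replicate_pairs']}",
            "",
            "Normalization offsets (log2, added to Mix2):",
        ]
        for rep, off in sorted(self.normalization.offsets.items()):
            lines.append(f"  replicate {rep}: {off:+.4f}")
        lines += ["", "Diagnostic performance (ROC AUC vs the 1:1 reference analytes):",
                  f"  {'subset':<18}{'n_tp':>6}{'n_tn':>6}{'AUC':>8}{'SE':>8}"]
        for r in self.rocs.values():
            lines.append(f"  {r.label:<18}{r.n_tp:>6}{r.n_tn:>6}{r.auc:>8.3f}{r.se:>8.4f}")
        if self.comparisons:
            lines += ["", "Pairwise AUC comparisons (independent z test):"]
            for (a, b), c in self.comparisons.items():
                flag = "**" if c.significant_01 else "*" if c.significant_05 else ""
                lines.append(f"  {a} vs {b}: z = {c.z:+.2f}, p = {c.p:.3g} {flag}")
        if self.concordance is not None:
            lines += ["", f"Replicate ratio concordance (Spearman rho): "
                          f"{self.concordance.mean:.3f} +- {self.concordance.sd:.3f}"]
        lines += ["", f"Global log2-ratio sd over all probe sets: s = {self.s:.3f}"]
        if rr.is_empty:
            lines.append("Reliable range: EMPTY (no bin passed the chi-square test)")
        else:
            lines.append(
                f"Reliable range: [{rr.lower:.2f}, {rr.upper:.2f}] log2 units "
                f"(length {rr.length:.2f}, {rr.n_passing_bins} bins, "
                f"analyte coverage {rr.coverage:.1%})"
            )
        return "\n".join(lines)

    # -- report files ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        rr = self.reliable_range
        return {
            "provenance": self.provenance,
            "offsets": {str(k): v for k, v in self.normalization.offsets.items()},
            "aucs": {
                label: {"n_tp": r.n_tp, "n_tn": r.n_tn, "auc": r.auc, "se": r.se}
                for label, r in self.rocs.items()
            },
            "comparisons": {
                f"{a} vs {b}": {"z": c.z, "p": c.p} for (a, b), c in self.comparisons.items()
            },
            "concordance": (
                None
                if self.concordance is None
                else {"mean": self.concordance.mean, "sd": self.concordance.sd}
            ),
            "s": self.s,
            "reliable_range": {
                "lower": rr.lower,
                "upper": rr.upper,
                "length": rr.length,
                "coverage": rr.coverage,
                "n_passing_bins": rr.n_passing_bins,
                "is_empty": rr.is_empty,
            },
            "bins": self.binset.to_frame().to_dict(orient="records"),
        }

    def save_report(self, directory, plots: bool = False) -> None:
        """Write report.tsv (sections), report.json and optionally the plots."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "report.tsv", "w", encoding="utf-8") as fh:
            fh.write("# MTRC benchmark report\n# section: aucs\n")
            self.auc_frame().to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)
            if self.comparisons:
                fh.write("# section: auc_comparisons\n")
                self.comparison_frame().to_csv(fh, sep="\t", index=False,
                                               float_format=FLOAT_FORMAT)
            fh.write("# section: bins\n")
            self.binset.to_frame().to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)
            rr = self.reliable_range
            fh.write("# section: reliable_range\n")
            fh.write("lower\tupper\tlength\tcoverage\n")
            fh.write(f"{rr.lower:.6f}\t{rr.upper:.6f}\t{rr.length:.6f}\t{rr.coverage:.6f}\n")
        with open(directory / "report.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")
        if plots:
            try:
                self.plot_ri(path=directory / "ri_plot.png")
                self.plot_lrd(path=directory / "lrd_plot.png")
            except Exception as exc:  # plotting must never abort an analysis
                warnings.warn(f"plot rendering failed: {exc}", UserWarning, stacklevel=2)

    # -- plots ----------------------------------------------------------

    def plot_ri(self, ax=None, path=None):
        """RI-plot: observed log2 ratio vs mean log2 intensity per analyte."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        targets = self.model.analytes.targets
        for color, component in zip(
            itertools.cycle(_COMPONENT_COLORS), self.model.analytes.components
        ):
            probes = self.model.analytes.probes_for(component)
            sub = self.ri.table.loc[probes]
            target = targets.loc[probes[0]]
            ax.scatter(sub["I"], sub["R"], s=12, facecolors="none", edgecolors=color,
                       linewidths=0.7, label=f"{component} (target {target:+.3g})")
            ax.axhline(target, color=color, linewidth=0.6, linestyle=":")
        rr = self.reliable_range
        if not rr.is_empty:
            ax.axvspan(rr.lower, rr.upper, color="0.92", zorder=0)
        ax.set_xlabel("mean log2 intensity (I)")
        ax.set_ylabel("log2 ratio (R)")
        ax.set_title("RI-plot")
        ax.legend(fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=150)
            plt.close(ax.figure)
        return ax

    def plot_lrd(self, ax=None, path=None):
        """LRD-plot: binned mean deviations, chi-square pass/fail, reliable range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        rr = self.reliable_range
        frame = self.binset.to_frame()
        if not rr.is_empty:
            lo = min(frame["intensity_min"].min(), rr.lower)
            hi = max(frame["intensity_max"].max(), rr.upper)
            ax.axvspan(lo, rr.lower, color="0.82", zorder=0)
            ax.axvspan(rr.upper, hi, color="0.82", zorder=0)
        for _, row in frame.iterrows():
            color = "tab:green" if row["passed"] else "tab:red"
            ax.errorbar(
                row["intensity_mean"], row["mean_lrd"],
                yerr=row["lrd_sd"],
                xerr=[[row["intensity_mean"] - row["intensity_min"]],
                      [row["intensity_max"] - row["intensity_mean"]]],
                fmt="o", color=color, markersize=5, capsize=2, linewidth=0.8,
            )
        ax.axhline(self.s, color="k", linestyle="--", linewidth=0.8,
                   label=f"s = {self.s:.3f}")
        ax.axhline(-self.s, color="k", linestyle="--", linewidth=0.8)
        ax.axhline(0.0, color="k", linewidth=0.6)
        ax.set_xlabel("mean log2 intensity of bin")
        ax.set_ylabel("mean log2 ratio deviation (LRD)")
        ax.set_title("LRD-plot")
        ax.legend(fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=150)
            plt.close(ax.figure)
        return ax
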