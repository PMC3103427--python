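"""Tissue-selective index (TSI) computation and MTRC analyte selection.

For a probe p and tissue t, the TSI is the probe's log2 signal in t minus its
maximum log2 signal across the remaining tissues. A probe is selected as an
analyte for tissue t when its mean TSI across replicate datasets is strictly
greater than a cutoff (3.22 log2 units by default, i.e. roughly ten-fold).
Because the TSI compares each tissue against the maximum of the others, at
most one tissue per probe can exceed any positive cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import MixtureDesign
from .errors import DomainError, ConfigError
from .io import AnalyteTable, ExpressionMatrix

DEFAULT_TSI_CUTOFF = 3.22


@dataclass(frozen=True)
class TissueProfileSet:
    """Replicate single-array profiles of the individual tissue components.

    Each replicate is an :class:`ExpressionMatrix` with one sample (column)
    per tissue; all replicates must cover the identical probe and tissue sets.
    """

    replicates: tuple[ExpressionMatrix, ...]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise DomainError("profile set needs at least one replicate")
        first = self.replicates[0]
        for rep in self.replicates[1:]:
            if list(rep.data.index) != list(first.data.index):
                raise ConfigError("replicate profiles cover different probe sets")
            if list(rep.data.columns) != list(first.data.columns):
                raise ConfigError("replicate profiles cover different tissue sets")

    @property
    def tissues(self) -> list[str]:
        return [str(c) for c in self.replicates[0].data.columns]

    @property
    def probe_ids(self) -> list[str]:
        return self.replicates[0].probe_ids

    def drop_tissue(self, tissue: str) -> "TissueProfileSet":
        if tissue not in self.tissues:
            raise KeyError(f"no tissue {tissue!r} in profile set")
        if len(self.tissues) < 3:
            raise DomainError("at least 2 tissues must remain after omission")
        reps = tuple(
            ExpressionMatrix(rep.data.drop(columns=[tissue])) for rep in self.replicates
        )
        return TissueProfileSet(reps)


@dataclass(frozen=True)
class TsiTable:
    """Per-replicate and mean TSI, each a probes x tissues DataFrame."""

    per_replicate: tuple[pd.DataFrame, ...]
    mean: pd.DataFrame


def tsi(profile: ExpressionMatrix) -> pd.DataFrame:
    """TSI for one replicate profile: signal in t minus max over the other tissues."""
    values = profile.data.to_numpy(dtype=float)
    n, k = values.shape
    if k < 2:
        raise DomainError("TSI requires at least 2 tissues")
    top = values.max(axis=1)
    second = np.partition(values, k - 2, axis=1)[:, k - 2]
    argmax = values.argmax(axis=1)
    out = values - top[:, None]
    out[np.arange(n), argmax] = values[np.arange(n), argmax] - second
    return pd.DataFrame(out, index=profile.data.index, columns=profile.data.columns)


def tsi_table(profiles: TissueProfileSet) -> TsiTable:
    """TSI per replicate plus the arithmetic mean TSI across replicates."""
    per_rep = tuple(tsi(rep) for rep in profiles.replicates)
    mean = sum(df for df in per_rep) / len(per_rep)
    return TsiTable(per_rep, mean)


def select_analytes(
    mean_tsi: pd.DataFrame,
    design: MixtureDesign | None,
    cutoff: float = DEFAULT_TSI_CUTOFF,
) -> AnalyteTable:
    """Select tissue-selective analytes from a probes x tissues mean-TSI table.

    A probe is assigned to tissue t iff ``mean_tsi[p, t] > cutoff`` (strict
    inequality); probes with no qualifying tissue are omitted. When a design
    is given, each record is joined with the tissue's target log2 ratio
    (tissues must be a subset of the design's components); with ``design=None``
    the target column is NaN.
    """
    if not cutoff > 0:
        raise DomainError(f"TSI cutoff must be > 0, got {cutoff}")
    tissues = [str(c) for c in mean_tsi.columns]
    if design is not None:
        unknown = set(tissues) - set(design.component_names)
        if unknown:
            raise ConfigError(f"tissues not in design {design.name!r}: {sorted(unknown)}")
        targets = {t: design.target_log2_ratio(t) for t in tissues}
    else:
        targets = {t: float("nan") for t in tissues}

    values = mean_tsi.to_numpy(dtype=float)
    best = values.argmax(axis=1)
    best_tsi = values[np.arange(len(values)), best]
    keep = best_tsi > cutoff
    rows = [
        (str(probe), tissues[b], float(v), targets[tissues[b]])
        for probe, b, v, k in zip(mean_tsi.index, best, best_tsi, keep)
        if k
    ]
    return AnalyteTable.from_records(rows)


def select_from_profiles(
    profiles: TissueProfileSet,
    design: MixtureDesign | None = None,
    cutoff: float = DEFAULT_TSI_CUTOFF,
) -> AnalyteTable:
    """Convenience composition: mean TSI over replicates, then selection."""
    return select_analytes(tsi_table(profiles).mean, design, cutoff)


def reduce_design(
    profiles: TissueProfileSet,
    omit: str,
    cutoff: float = DEFAULT_TSI_CUTOFF,
    design: MixtureDesign | None = None,
) -> AnalyteTable:
    """Re-select analytes after omitting one tissue from the comparison.

    The TSI is recomputed among the remaining tissues only, so the selected
    set is always a superset of the full-design selection restricted to those
    tissues (dropping a competitor can only raise a probe's TSI). `design`,
    if given, should describe the reduced mixture so targets can be joined.
    """
    reduced = profiles.drop_tissue(omit)
    return select_from_profiles(reduced, design, cutoff)
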