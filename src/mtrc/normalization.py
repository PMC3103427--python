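"""Ratiometric normalization of Mix2 against Mix1.

For each technical replicate, the offset between the 10% trimmed mean of the
reference (1:1) component's analytes in Mix1 and in Mix2 is added to every
Mix2 probe of that replicate. After correction the trimmed-mean difference
over the reference analytes is exactly zero per replicate, which makes the
operation idempotent.

"10% trimmed mean" is interpreted as trimming floor(0.10 * n) observations
from each tail (the most common convention); pass ``per_tail=False`` to trim
10% of observations in total (floor(0.05 * n) per tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .io import MIX1, MIX2, AnalyteTable, ExpressionMatrix


def trimmed_mean(values, trim_fraction: float = 0.10, per_tail: bool = True) -> float:
    """Mean after removing the k smallest and k largest values.

    k = floor(trim_fraction * n) when trimming per tail (default), or
    floor(trim_fraction / 2 * n) when `trim_fraction` is the total fraction.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise DomainError("trimmed mean of empty input")
    if not 0.0 <= trim_fraction < 0.5:
        raise DomainError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    frac = trim_fraction if per_tail else trim_fraction / 2.0
    k = math.floor(frac * n)
    return float(arr[k : n - k].mean())


@dataclass(frozen=True)
class NormalizationResult:
    """Per-replicate log2 offsets applied to Mix2, and the corrected matrix."""

    offsets: dict[int, float]
    matrix: ExpressionMatrix


def normalize_mixes(
    matrix: ExpressionMatrix,
    analytes: AnalyteTable,
    reference_component: str | None = None,
    trim_fraction: float = 0.10,
    per_tail: bool = True,
) -> NormalizationResult:
    """Shift each Mix2 replicate so reference-analyte trimmed means match Mix1.

    Parameters
    ----------
    matrix:
        Expression matrix with paired (Mix1, Mix2) technical replicates.
    analytes:
        Analyte table providing the reference component's probes. Only those
        probes influence the offsets; the shift is applied to every probe.
    reference_component:
        Name of the 1:1 component; defaults to the table's unique zero-ratio
        component.
    """
    if reference_component is None:
        reference_component = analytes.reference_component
        if reference_component is None:
            raise DomainError(
                "analyte table has no unique zero-ratio component; "
                "pass reference_component explicitly"
            )
    ref_probes = analytes.probes_for(reference_component)
    if not ref_probes:
        raise DomainError(f"no analytes for reference component {reference_component!r}")
    matrix.require_probes(ref_probes, context="reference analytes")

    pairs = matrix.paired_replicates(MIX1, MIX2)
    corrected = matrix.data.copy()
    offsets: dict[int, float] = {}
    for rep, label1, label2 in pairs:
        m1 = trimmed_mean(matrix.data.loc[ref_probes, label1], trim_fraction, per_tail)
        m2 = trimmed_mean(matrix.data.loc[ref_probes, label2], trim_fraction, per_tail)
        offset = m1 - m2
        offsets[rep] = offset
        corrected[label2] = corrected[label2] + offset
    return NormalizationResult(offsets, ExpressionMatrix(corrected, dict(matrix.roles)))
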