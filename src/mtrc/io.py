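"""Readers, writers and in-memory containers for expression data.

The on-disk formats are deliberately plain: UTF-8, tab-delimited text with a
``.`` decimal separator and six decimal places for numeric values, so that a
write/read cycle is value-exact. An expression matrix is probes x samples of
log2 signal intensities (RMA-level output); sample roles (which mix a column
belongs to and its technical-replicate index) are supplied separately via a
TOML config rather than parsed out of column names.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError, FormatError, PairingError

MIX1 = "Mix1"
MIX2 = "Mix2"

#: numeric formatting used for every TSV this package writes
FLOAT_FORMAT = "%.6f"

ANALYTE_COLUMNS = ("probe_id", "component", "mean_tsi", "target_log2_ratio")


@dataclass(frozen=True, order=True)
class SampleRole:
    """Role of one array: which mix (or tissue) it measures and its replicate index."""

    mix: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ConfigError(f"replicate index must be >= 1, got {self.replicate}")


def _as_role(value) -> SampleRole:
    if isinstance(value, SampleRole):
        return value
    if isinstance(value, Mapping):
        return SampleRole(str(value["mix"]), int(value.get("replicate", 1)))
    mix, rep = value
    return SampleRole(str(mix), int(rep))


class ExpressionMatrix:
    """Probe-by-sample table of log2 signal intensities with sample roles.

    Parameters
    ----------
    data:
        DataFrame indexed by probe id, one column per sample, float values on
        the log2 scale. Probe order is preserved.
    roles:
        Optional mapping from sample label to :class:`SampleRole` (or a
        ``(mix, replicate)`` tuple / ``{"mix": ..., "replicate": ...}`` dict).
        Labels not present in the mapping simply have no role.
    """

    def __init__(self, data: pd.DataFrame, roles: Mapping[str, object] | None = None):
        self.data = data
        self.roles: dict[str, SampleRole] = {
            str(k): _as_role(v) for k, v in (roles or {}).items()
        }
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        idx = self.data.index
        if len(idx) == 0:
            raise FormatError("expression matrix has no probes")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at probe {idx[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        missing = set(self.roles) - set(map(str, self.data.columns))
        if missing:
            raise ConfigError(f"role labels absent from matrix header: {sorted(missing)}")
        seen: dict[tuple[str, int], str] = {}
        for label, role in self.roles.items():
            key = (role.mix, role.replicate)
            if key in seen:
                raise ConfigError(
                    f"samples {seen[key]!r} and {label!r} share role (mix={role.mix!r}, "
                    f"replicate={role.replicate})"
                )
            seen[key] = label

    # -- basic accessors ----------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return [str(p) for p in self.data.index]

    @property
    def sample_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def labels_for(self, mix: str) -> list[str]:
        """Sample labels measuring `mix`, sorted by replicate index."""
        pairs = [(r.replicate, l) for l, r in self.roles.items() if r.mix == mix]
        return [l for _, l in sorted(pairs)]

    def paired_replicates(self, a: str = MIX1, b: str = MIX2) -> list[tuple[int, str, str]]:
        """(replicate, label_a, label_b) for every paired technical replicate.

        Raises :class:`PairingError` if the replicate indices of the two mixes
        do not match exactly, or if no pair exists.
        """
        ra = {r.replicate: l for l, r in self.roles.items() if r.mix == a}
        rb = {r.replicate: l for l, r in self.roles.items() if r.mix == b}
        if set(ra) != set(rb):
            raise PairingError(
                f"unpaired replicates between {a!r} and {b!r}: "
                f"{sorted(set(ra) ^ set(rb))}"
            )
        if not ra:
            raise PairingError(f"no ({a!r}, {b!r}) replicate pairs in matrix")
        return [(i, ra[i], rb[i]) for i in sorted(ra)]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), dict(self.roles))

    def require_probes(self, probes: Iterable[str], context: str = "") -> None:
        missing = [p for p in probes if p not in self.data.index]
        if missing:
            where = f" ({context})" if context else ""
            raise CoverageError(f"probes missing from matrix{where}: {missing[:10]}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ExpressionMatrix {self.shape[0]} probes x {self.shape[1]} samples>"


# -- matrix I/O -------------------------------------------------------------


def read_expression_matrix(path, role_map: Mapping[str, object] | None = None) -> ExpressionMatrix:
    """Read a tab-delimited matrix (first column probe ids, header of labels)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate probe id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at probe {df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"missing value at probe {df.index[r]!r}, sample {df.columns[c]!r}")
    numeric.columns = [str(c) for c in numeric.columns]
    if role_map is not None:
        absent = set(map(str, role_map)) - set(numeric.columns)
        if absent:
            raise ConfigError(f"role_map labels absent from header: {sorted(absent)}")
    return ExpressionMatrix(numeric.astype(float), role_map)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="probe_id")


# -- sample-role config -----------------------------------------------------


def read_role_map(path) -> dict[str, SampleRole]:
    """Read sample roles from TOML: ``[samples]`` table of label -> {mix, replicate}."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    if "samples" not in doc:
        raise ConfigError(f"role config {path} lacks a [samples] table")
    return {str(label): _as_role(spec) for label, spec in doc["samples"].items()}


def write_role_map(roles: Mapping[str, SampleRole], path) -> None:
    lines = ["[samples]"]
    for label, role in roles.items():
        lines.append(f'"{label}" = {{ mix = "{role.mix}", replicate = {role.replicate} }}')
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- analyte tables ---------------------------------------------------------


class AnalyteTable:
    """Probe -> (component, mean TSI, target log2 ratio) records.

    The table partitions analytes into the true-negative set (the reference,
    1:1 component, target log2 ratio 0) and true-positive fold-change subsets.
    ``mean_tsi`` and ``target_log2_ratio`` may be NaN for tables that were not
    derived from replicate profiles or a full design (e.g. reduced designs).
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing = set(ANALYTE_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"analyte table lacks columns: {sorted(missing)}")
        extra = set(df.columns) - set(ANALYTE_COLUMNS)
        if extra:
            raise FormatError(f"analyte table has unknown columns: {sorted(extra)}")
        df = df.loc[:, list(ANALYTE_COLUMNS)]
        df["probe_id"] = df["probe_id"].astype(str)
        df["component"] = df["component"].astype(str)
        df["mean_tsi"] = pd.to_numeric(df["mean_tsi"])
        df["target_log2_ratio"] = pd.to_numeric(df["target_log2_ratio"])
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe id {dup!r} in analyte table")
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, float, float]]) -> "AnalyteTable":
        return cls(pd.DataFrame(rows, columns=list(ANALYTE_COLUMNS)))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def probes(self) -> list[str]:
        return list(self.records["probe_id"])

    @property
    def components(self) -> list[str]:
        return list(dict.fromkeys(self.records["component"]))

    @property
    def targets(self) -> pd.Series:
        """Per-probe target log2 ratio, indexed by probe id."""
        return self.records.set_index("probe_id")["target_log2_ratio"]

    @property
    def reference_component(self) -> str | None:
        """The unique component with target log2 ratio 0, if there is one."""
        zero = self.records.loc[self.records["target_log2_ratio"] == 0.0, "component"]
        names = list(dict.fromkeys(zero))
        return names[0] if len(names) == 1 else None

    def probes_for(self, component: str) -> list[str]:
        return list(self.records.loc[self.records["component"] == component, "probe_id"])

    def subset(self, components: Iterable[str]) -> "AnalyteTable":
        wanted = set(components)
        return AnalyteTable(self.records[self.records["component"].isin(wanted)])

    def non_reference(self) -> "AnalyteTable":
        ref = self.reference_component
        if ref is None:
            return AnalyteTable(self.records)
        return AnalyteTable(self.records[self.records["component"] != ref])

    def counts(self) -> dict[str, int]:
        return self.records["component"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)

    @classmethod
    def from_tsv(cls, path) -> "AnalyteTable":
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
        table = cls(df)
        if table.reference_component is None and len(table):
            warnings.warn(
                f"analyte table {path} has no unique zero-ratio (reference) component",
                UserWarning,
                stacklevel=2,
            )
        return table

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        counts = ", ".join(f"{c}={n}" for c, n in self.counts().items())
        return f"<AnalyteTable {len(self)} analytes: {counts}>"
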