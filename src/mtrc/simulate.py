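"""Ground-truthed synthetic tissue profiles and MTRC mix experiments.

The generator emulates the data-generating structure of a mixed-tissue
ratiometric control study on a high-density expression array:

* every probe has a baseline log2 abundance drawn uniformly from
  ``baseline_range`` (an RMA-like intensity scale);
* each tissue contributes a planted set of selective probes. In *tissue
  profiles* a selective probe sits ``delta`` log2 units above its level in
  every other tissue, so its tissue-selective index equals ``delta`` exactly.
  In *mix experiments* the planted analytes are perfectly tissue-selective
  (expressed in a single component), so with no compression the observed
  log2 ratio equals the design target identically;
* mixes combine the component abundances linearly with mRNA-weighted mass
  fractions, so the mix abundance vector is a convex combination of the
  tissue vectors;
* detection is compressed by an additive background floor and a hard
  saturation ceiling applied to the linear signal:
  ``observed = min(ceiling, floor + abundance)``;
* technical replicates add independent Normal(0, sd^2) noise on the log2
  scale. Noise is drawn as ``sd * z`` with z from a per-replicate stream, so
  runs with the same seed and different sd share the same noise shape, and
  adding replicates never changes earlier ones.

The optional ``broad_tissue`` flag marks one component (a UHRR analog whose
pooled cell lines cover much of the transcriptome) as broadly expressed: for
each other tissue, ``n_masked`` additional would-be-selective probes are
also expressed in the broad tissue just ``broad_margin`` log2 units below
their selective level. These probes fail selection while the broad tissue is
in the comparison and become selective once it is omitted, reproducing the
observation that dropping the broad component yields the largest analyte set.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import MixtureDesign
from .errors import ConfigError
from .io import MIX1, MIX2, AnalyteTable, ExpressionMatrix, SampleRole
from .selection import TissueProfileSet

#: HG-U133A 2.0-like probe-set count and the per-tissue selective-analyte
#: counts of the four-component human control this package emulates.
DEFAULT_TISSUES = ("UHRR", "HBRR", "liver", "skeletal muscle")
DEFAULT_SELECTIVE = {"HBRR": 429, "liver": 255, "UHRR": 197, "skeletal muscle": 154}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Attributes
    ----------
    n_probes:
        Probe sets on the array (default emulates a 22,277-probe design).
    tissues:
        Component names; must match the mixture design when simulating mixes.
    n_selective:
        Planted selective probes per tissue: a mapping, or one int for all.
    delta:
        Log2 elevation of a selective probe over the other tissues (> 0).
    baseline_range:
        (lo, hi) of the uniform baseline log2 abundance.
    background_floor, saturation_ceiling:
        Log2 of the additive background level and of the linear saturation
        cap; ``None`` disables either. Together they set the compression
        boundaries of the dynamic range.
    noise_sd:
        Replicate noise sd in log2 units (>= 0).
    broad_tissue, n_masked, broad_margin:
        Broad-coverage component option, see module docstring.
    seed:
        Master seed; identical configs produce identical data.
    """

    n_probes: int = 22277
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_selective: Mapping[str, int] | int = field(
        default_factory=lambda: dict(DEFAULT_SELECTIVE)
    )
    delta: float = 5.0
    baseline_range: tuple[float, float] = (4.0, 17.0)
    background_floor: float | None = 6.0
    saturation_ceiling: float | None = 14.0
    noise_sd: float = 0.15
    broad_tissue: str | None = None
    n_masked: int = 100
    broad_margin: float = 1.0
    seed: int | None = None

    def selective_counts(self) -> dict[str, int]:
        if isinstance(self.n_selective, int):
            return {t: self.n_selective for t in self.tissues}
        return {t: int(self.n_selective.get(t, 0)) for t in self.tissues}

    def __post_init__(self) -> None:
        lo, hi = self.baseline_range
        if not lo < hi:
            raise ConfigError(f"baseline range must satisfy lo < hi, got {self.baseline_range}")
        if not self.delta > 0:
            raise ConfigError("delta must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise sd must be >= 0")
        if len(self.tissues) < 2 or len(set(self.tissues)) != len(self.tissues):
            raise ConfigError("tissues must be >= 2 unique names")
        if self.background_floor is not None and self.saturation_ceiling is not None:
            if not self.background_floor < self.saturation_ceiling:
                raise ConfigError("background floor must lie below the saturation ceiling")
        counts = self.selective_counts()
        if any(c < 0 for c in counts.values()):
            raise ConfigError("selective counts must be >= 0")
        total = sum(counts.values())
        if self.broad_tissue is not None:
            if self.broad_tissue not in self.tissues:
                raise ConfigError(f"broad tissue {self.broad_tissue!r} not in tissues")
            total += self.n_masked * (len(self.tissues) - 1)
        if not 0 < total <= self.n_probes:
            raise ConfigError(
                f"planted probes ({total}) must be between 1 and n_probes ({self.n_probes})"
            )

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_toml(cls, path) -> "SimulationConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        section = doc.get("simulation", doc)
        kwargs = dict(section)
        if "tissues" in kwargs:
            kwargs["tissues"] = tuple(kwargs["tissues"])
        if "baseline_range" in kwargs:
            kwargs["baseline_range"] = tuple(kwargs["baseline_range"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# internal structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Structure:
    probe_ids: list[str]
    baseline: np.ndarray                  # (n_probes,) log2 baseline
    component: np.ndarray                 # (n_probes,) tissue index or -1
    masked_for: np.ndarray                # (n_probes,) tissue index or -1


def _streams(seed: int | None, n_replicates: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n_replicates + 1)
    return [np.random.default_rng(c) for c in children]


def _structure(config: SimulationConfig, rng: np.random.Generator) -> _Structure:
    n = config.n_probes
    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=n)
    component = np.full(n, -1, dtype=int)
    masked_for = np.full(n, -1, dtype=int)
    perm = rng.permutation(n)
    pos = 0
    counts = config.selective_counts()
    for ti, tissue in enumerate(config.tissues):
        k = counts[tissue]
        component[perm[pos : pos + k]] = ti
        pos += k
    if config.broad_tissue is not None:
        broad = config.tissues.index(config.broad_tissue)
        for ti in range(len(config.tissues)):
            if ti == broad:
                continue
            masked_for[perm[pos : pos + config.n_masked]] = ti
            pos += config.n_masked
    probe_ids = [f"probe_{i:05d}" for i in range(n)]
    return _Structure(probe_ids, baseline, component, masked_for)


def _compress_linear(linear: np.ndarray, config: SimulationConfig) -> np.ndarray:
    out = linear
    if config.background_floor is not None:
        out = out + 2.0 ** config.background_floor
    if config.saturation_ceiling is not None:
        out = np.minimum(out, 2.0 ** config.saturation_ceiling)
    return out


# ---------------------------------------------------------------------------
# tissue profiles
# ---------------------------------------------------------------------------


def _profile_log2_abundance(config: SimulationConfig, st: _Structure) -> np.ndarray:
    """(n_probes, n_tissues) log2 abundance for single-tissue arrays."""
    n_t = len(config.tissues)
    levels = np.tile(st.baseline[:, None], (1, n_t))
    planted = st.component >= 0
    levels[planted] -= config.delta  # suppress the non-selective tissues
    levels[planted, st.component[planted]] = st.baseline[planted]
    if config.broad_tissue is not None:
        broad = config.tissues.index(config.broad_tissue)
        masked = st.masked_for >= 0
        levels[masked] -= config.delta
        levels[masked, st.masked_for[masked]] = st.baseline[masked]
        levels[masked, broad] = st.baseline[masked] - config.broad_margin
    return levels


def simulate_tissue_profiles(
    config: SimulationConfig, n_replicates: int = 3
) -> tuple[TissueProfileSet, AnalyteTable]:
    """Replicate single-tissue arrays plus the planted ground-truth analytes.

    The truth table assigns each planted selective probe to its tissue with
    ``mean_tsi = delta``; targets are NaN (no mixture design is involved at
    the profiling stage). Probes masked by the broad tissue are *not* in the
    truth table: they are only selective once the broad tissue is omitted.
    """
    if n_replicates < 1:
        raise ConfigError("need >= 1 replicate")
    streams = _streams(config.seed, n_replicates)
    st = _structure(config, streams[0])
    log2_levels = _profile_log2_abundance(config, st)
    observed = np.log2(_compress_linear(np.exp2(log2_levels), config))
    reps = []
    for r in range(n_replicates):
        noise = config.noise_sd * streams[r + 1].standard_normal(observed.shape)
        data = pd.DataFrame(
            observed + noise, index=pd.Index(st.probe_ids, name="probe_id"),
            columns=list(config.tissues),
        )
        roles = {t: SampleRole(t, r + 1) for t in config.tissues}
        reps.append(ExpressionMatrix(data, roles))
    planted = st.component >= 0
    rows = [
        (st.probe_ids[i], config.tissues[st.component[i]], config.delta, float("nan"))
        for i in np.flatnonzero(planted)
    ]
    return TissueProfileSet(tuple(reps)), AnalyteTable.from_records(rows)


# ---------------------------------------------------------------------------
# mix experiments
# ---------------------------------------------------------------------------


def _mix_linear_abundance(config: SimulationConfig, st: _Structure) -> np.ndarray:
    """(n_probes, n_tissues) linear abundance with perfectly selective analytes."""
    linear = np.tile(np.exp2(st.baseline)[:, None], (1, len(config.tissues)))
    planted = st.component >= 0
    linear[planted] = 0.0
    linear[planted, st.component[planted]] = np.exp2(st.baseline[planted])
    if config.broad_tissue is not None:
        broad = config.tissues.index(config.broad_tissue)
        masked = st.masked_for >= 0
        linear[masked] = 0.0
        linear[masked, st.masked_for[masked]] = np.exp2(st.baseline[masked])
        linear[masked, broad] = np.exp2(st.baseline[masked] - config.broad_margin)
    return linear


def simulate_mix_experiment(
    config: SimulationConfig,
    design: MixtureDesign,
    n_replicates: int = 3,
) -> tuple[ExpressionMatrix, AnalyteTable]:
    """Paired Mix1/Mix2 replicate arrays plus the ground-truth analyte table.

    Per probe, each mix's abundance is the mass-fraction-weighted sum of the
    component abundances in linear space; the observed signal is compressed
    (floor + ceiling), log2-transformed and perturbed by replicate noise.
    The truth table carries each planted analyte's design target log2 ratio.
    """
    if n_replicates < 1:
        raise ConfigError("need >= 1 replicate")
    if set(config.tissues) != set(design.component_names):
        raise ConfigError(
            f"config tissues {sorted(config.tissues)} do not match design "
            f"components {sorted(design.component_names)}"
        )
    streams = _streams(config.seed, n_replicates)
    st = _structure(config, streams[0])
    linear = _mix_linear_abundance(config, st)
    signals: dict[int, np.ndarray] = {}
    for mix in (1, 2):
        fractions = design.mass_fractions(mix)
        f = np.array([fractions[t] for t in config.tissues])
        mixed = linear @ f
        signals[mix] = np.log2(_compress_linear(mixed, config))
    columns: dict[str, np.ndarray] = {}
    roles: dict[str, SampleRole] = {}
    for r in range(n_replicates):
        noise = config.noise_sd * streams[r + 1].standard_normal((config.n_probes, 2))
        for j, (mix_name, mix) in enumerate(((MIX1, 1), (MIX2, 2))):
            label = f"{mix_name}_r{r + 1}"
            columns[label] = signals[mix] + noise[:, j]
            roles[label] = SampleRole(mix_name, r + 1)
    data = pd.DataFrame(columns, index=pd.Index(st.probe_ids, name="probe_id"))
    matrix = ExpressionMatrix(data, roles)
    planted = np.flatnonzero(st.component >= 0)
    rows = [
        (
            st.probe_ids[i],
            config.tissues[st.component[i]],
            float("nan"),
            design.target_log2_ratio(config.tissues[st.component[i]]),
        )
        for i in planted
    ]
    return matrix, AnalyteTable.from_records(rows)
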