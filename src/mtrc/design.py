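"""Mixture designs: component masses per mix and the target log2 ratios.

A mixed-tissue ratiometric control (MTRC) consists of two mixes of the same
RNA components combined in different masses. Each component's mass ratio
Mix1:Mix2 fixes the expected ("target") log2 ratio of its tissue-selective
analytes; exactly one component is mixed 1:1 and serves as the true-negative
set and the normalization anchor.

The canonical designs studied here are available as
:meth:`MixtureDesign.mtrc4` (UHRR 20/20, liver 30/20, HBRR 40/20, skeletal
muscle 10/40 ug per 100 ug mix) and :meth:`MixtureDesign.mtrc3` (HBRR 25/25,
liver 45/30, skeletal muscle 30/45).

An optional per-component ``mrna_fraction`` weight adjusts for components
whose total RNA carries a different mRNA fraction (cell-line pools such as
UHRR are mRNA-richer than tissue RNA). With non-unit weights the target ratio
is computed on the weighted mass fraction of the component within each mix;
with the default weights of 1 it reduces to the plain mass ratio, which is
how the published target values (0.585, -2, ...) are defined.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import DesignError


@dataclass(frozen=True)
class Component:
    name: str
    mass_mix1: float
    mass_mix2: float
    mrna_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mass_mix1 > 0 and self.mass_mix2 > 0):
            raise DesignError(f"component {self.name!r}: masses must be > 0")
        if not self.mrna_fraction > 0:
            raise DesignError(f"component {self.name!r}: mrna_fraction must be > 0")

    @property
    def is_reference(self) -> bool:
        return self.mass_mix1 == self.mass_mix2


@dataclass(frozen=True)
class DesignReport:
    """Outcome of :func:`validate_design`: per-component ratios plus the reference."""

    name: str
    reference: str
    rows: tuple[tuple[str, float, float], ...]  # (component, ratio, target log2 ratio)

    def __str__(self) -> str:
        lines = [f"design {self.name}: reference component = {self.reference}"]
        for comp, ratio, target in self.rows:
            lines.append(f"  {comp}: mass ratio {ratio:g}, target log2 ratio {target:+.3f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class MixtureDesign:
    name: str
    components: tuple[Component, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise DesignError("a mixture design needs at least 2 components")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate component names in design {self.name!r}")

    # -- lookups ------------------------------------------------------------

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"no component {name!r} in design {self.name!r}")

    @property
    def reference_component(self) -> str:
        refs = [c.name for c in self.components if c.is_reference]
        if len(refs) != 1:
            raise DesignError(
                f"design {self.name!r} must have exactly one 1:1 component, found {refs or 'none'}"
            )
        return refs[0]

    # -- ratios -------------------------------------------------------------

    def component_ratio(self, name: str) -> float:
        """Mass ratio Mix1:Mix2 for one component (e.g. 1.5 for 30 ug : 20 ug)."""
        c = self.component(name)
        return c.mass_mix1 / c.mass_mix2

    def mass_fractions(self, mix: int) -> dict[str, float]:
        """mRNA-weighted mass fraction of each component within one mix (1 or 2)."""
        if mix not in (1, 2):
            raise ValueError("mix must be 1 or 2")
        masses = {
            c.name: c.mrna_fraction * (c.mass_mix1 if mix == 1 else c.mass_mix2)
            for c in self.components
        }
        total = sum(masses.values())
        return {name: m / total for name, m in masses.items()}

    def target_log2_ratio(self, name: str) -> float:
        """Expected log2 ratio of this component's analytes between Mix1 and Mix2.

        With unit mRNA weights this is the plain mass ratio, log2(m1/m2).
        With non-unit weights the ratio is computed on the mRNA-weighted mass
        of the component relative to the reference component, which keeps the
        reference target at exactly 0 and agrees with reference-anchored
        normalization of the observed signals.
        """
        c = self.component(name)
        if all(comp.mrna_fraction == 1.0 for comp in self.components):
            return math.log2(c.mass_mix1 / c.mass_mix2)
        ref = self.component(self.reference_component)
        w1 = (c.mrna_fraction * c.mass_mix1) / (ref.mrna_fraction * ref.mass_mix1)
        w2 = (c.mrna_fraction * c.mass_mix2) / (ref.mrna_fraction * ref.mass_mix2)
        return math.log2(w1 / w2)

    def targets(self) -> dict[str, float]:
        return {c.name: self.target_log2_ratio(c.name) for c in self.components}

    def scaled(self, factor: float) -> "MixtureDesign":
        """Same design with all masses in both mixes multiplied by `factor`."""
        comps = tuple(
            replace(c, mass_mix1=c.mass_mix1 * factor, mass_mix2=c.mass_mix2 * factor)
            for c in self.components
        )
        return replace(self, components=comps)

    # -- canonical designs --------------------------------------------------

    @classmethod
    def mtrc4(cls) -> "MixtureDesign":
        """Four-component human MTRC: per 100 ug, Mix1 = 20/30/40/10 and Mix2 = 20/20/20/40 ug."""
        return cls(
            "MTRC-4",
            (
                Component("UHRR", 20.0, 20.0),
                Component("liver", 30.0, 20.0),
                Component("HBRR", 40.0, 20.0),
                Component("skeletal muscle", 10.0, 40.0),
            ),
        )

    @classmethod
    def mtrc3(cls) -> "MixtureDesign":
        """Three-component variant: HBRR 1:1 and reciprocal 1.5:1 liver/muscle ratios."""
        return cls(
            "MTRC-3",
            (
                Component("HBRR", 25.0, 25.0),
                Component("liver", 45.0, 30.0),
                Component("skeletal muscle", 30.0, 45.0),
            ),
        )

    # -- TOML ---------------------------------------------------------------

    @classmethod
    def from_toml(cls, path) -> "MixtureDesign":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        name = doc.get("design", {}).get("name", Path(path).stem)
        comps = []
        for entry in doc.get("component", []):
            comps.append(
                Component(
                    str(entry["name"]),
                    float(entry["mass_mix1"]),
                    float(entry["mass_mix2"]),
                    float(entry.get("mrna_fraction", 1.0)),
                )
            )
        return cls(name, tuple(comps))

    def to_toml(self, path) -> None:
        lines = ["[design]", f'name = "{self.name}"', ""]
        for c in self.components:
            lines += ["[[component]]", f'name = "{c.name}"',
                      f"mass_mix1 = {c.mass_mix1!r}", f"mass_mix2 = {c.mass_mix2!r}"]
            if c.mrna_fraction != 1.0:
                lines.append(f"mrna_fraction = {c.mrna_fraction!r}")
            lines.append("")
        Path(path).write_text("\n".join(lines), encoding="utf-8")


def validate_design(design: MixtureDesign) -> DesignReport:
    """Check the single-reference invariant and tabulate per-component ratios."""
    reference = design.reference_component  # raises DesignError if not unique
    rows = tuple(
        (c.name, design.component_ratio(c.name), design.target_log2_ratio(c.name))
        for c in design.components
    )
    return DesignReport(design.name, reference, rows)
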