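"""Serotype definitions, VP/variant sequence derivation and component libraries.

A serotype is defined by its VP1 sequence (initiator Met included) and the
1-based start positions, in mature (Met-cleaved) numbering, of VP2, VP3 and any
additional variant chains.  VP2 and VP3 are C-terminal sub-sequences of VP1;
chains whose own translation starts with Met (VP1, VP3 and VP3 variants) are
subject to N-terminal Met excision followed by acetylation of the exposed
residue, while internal-start chains such as VP2 are left untouched.

The component library built here is the target list used for identity testing:
one entry per (VP, modification set) with a theoretical average mass and an
expected retention-time window.  Theoretical masses normally come from the
sequence, but can be pinned per VP with ``mass_overrides`` — the same move as
replacing imported observed masses with curated theoretical ones in a
quantitative processing method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from . import masscalc
from .masscalc import CANONICAL_RESIDUES, DEFAULT_MASS_TABLE, ResidueMassTable

__all__ = [
    "SerotypeDefinition",
    "PTMDelta",
    "ProteoformComponent",
    "ComponentLibrary",
    "DEFAULT_PTM_TABLE",
    "DEFAULT_NTERM_RULE",
    "SMALL_POSITION2_RESIDUES",
    "derive_vp_sequences",
    "apply_nterm_processing",
    "build_component_library",
    "load_serotype_definitions",
    "dump_serotype_definitions",
]


class DefinitionError(ValueError):
    """Raised when a serotype definition violates its invariants."""


class ConfigurationError(ValueError):
    """Raised for unknown VP or PTM names when building a library."""


#: Residues at position 2 that permit initiator-Met excision (small side chains).
SMALL_POSITION2_RESIDUES = frozenset("AVSTCGP")

#: Default N-terminal processing: excise Met, then acetylate the new terminus.
DEFAULT_NTERM_RULE = frozenset({"cleave_met", "acetylate"})

_CORE_VPS = ("VP1", "VP2", "VP3")


@dataclass(frozen=True)
class PTMDelta:
    """A named modification with its average/monoisotopic mass shifts."""

    name: str
    delta_avg: float
    delta_mono: float
    allowed_residues: str = ""

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.delta_avg) and math.isfinite(self.delta_mono)):
            raise ConfigurationError(f"PTM {self.name!r}: non-finite delta")


# Default deltas; the source study names the modifications but prints no delta
# table, so these are standard values and each is overridable via config.
DEFAULT_PTM_TABLE: tuple[PTMDelta, ...] = (
    PTMDelta("acetylation", 42.037, 42.010565, "A"),
    PTMDelta("oxidation", 15.999, 15.994915, "MW"),
    PTMDelta("deamidation", 0.985, 0.984016, "NQ"),
    PTMDelta("nh3_loss", -17.031, -17.026549, "Q"),
    PTMDelta("succinimide_d", -18.015, -18.010565, "D"),
    PTMDelta("phosphorylation", 79.980, 79.966331, "STY"),
    PTMDelta("kynurenine", 3.995, 3.994915, "W"),
)


@dataclass(frozen=True)
class SerotypeDefinition:
    """A serotype's VP1 sequence plus chain start offsets in mature numbering.

    ``met_initiated_starts`` lists the start positions (among ``vp3_start`` and
    ``variant_starts``) whose chain begins at its own Met codon, i.e. the
    mature residue immediately before the start is that chain's initiator Met.
    ``None`` auto-detects: VP3 and every variant start preceded by ``M`` in the
    mature sequence.  VP2 is never Met-initiated.
    """

    name: str
    vp1_sequence: str
    vp2_start: int
    vp3_start: int
    variant_starts: tuple[int, ...] = ()
    nterm_rule: frozenset[str] = DEFAULT_NTERM_RULE
    met_initiated_starts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_starts", tuple(self.variant_starts))
        object.__setattr__(self, "nterm_rule", frozenset(self.nterm_rule))
        if self.met_initiated_starts is not None:
            object.__setattr__(
                self, "met_initiated_starts", tuple(self.met_initiated_starts)
            )
        bad = set(self.vp1_sequence) - CANONICAL_RESIDUES
        if bad:
            raise DefinitionError(
                f"{self.name}: non-canonical residues {sorted(bad)} in vp1_sequence"
            )
        mature = self.mature_sequence
        starts = [self.vp2_start, self.vp3_start, *self.variant_starts]
        if not self.vp2_start < self.vp3_start:
            raise DefinitionError(f"{self.name}: vp2_start must precede vp3_start")
        if self.variant_starts and not self.vp3_start < min(self.variant_starts):
            raise DefinitionError(
                f"{self.name}: variant starts must follow vp3_start"
            )
        for s in starts:
            if not 1 <= s <= len(mature):
                raise DefinitionError(
                    f"{self.name}: start position {s} beyond mature length "
                    f"{len(mature)}"
                )

    @property
    def mature_sequence(self) -> str:
        """VP1 after N-terminal processing; defines residue numbering (A1...)."""
        processed, _ = apply_nterm_processing(self.vp1_sequence, self.nterm_rule)
        return processed

    def _met_starts(self) -> frozenset[int]:
        if self.met_initiated_starts is not None:
            return frozenset(self.met_initiated_starts)
        mature = self.mature_sequence
        auto = set()
        for s in (self.vp3_start, *self.variant_starts):
            if s >= 2 and mature[s - 2] == "M":
                auto.add(s)
        return frozenset(auto)

    def variant_name(self, start: int) -> str:
        """Display name of a variant chain, e.g. ``A211-VP3``."""
        return f"{self.mature_sequence[start - 1]}{start}-VP3"

    @property
    def vp_names(self) -> tuple[str, ...]:
        return (*_CORE_VPS, *(self.variant_name(s) for s in self.variant_starts))

    def chain_start(self, vp_name: str) -> int:
        """1-based mature start position of a chain's first mature residue."""
        if vp_name == "VP1":
            return 1
        if vp_name == "VP2":
            return self.vp2_start
        if vp_name == "VP3":
            return self.vp3_start
        for s in self.variant_starts:
            if self.variant_name(s) == vp_name:
                return s
        raise ConfigurationError(f"{self.name}: unknown VP name {vp_name!r}")


def apply_nterm_processing(
    sequence: str, rule: Iterable[str] = DEFAULT_NTERM_RULE
) -> tuple[str, bool]:
    """Apply initiator-Met excision and N-terminal acetylation to one chain.

    The Met is removed only when the chain starts with ``M``, the second
    residue has a small side chain (A/V/S/T/C/G/P) and ``cleave_met`` is in
    the rule set.  The acetyl flag is raised when ``acetylate`` is set and the
    cleavage fired, or unconditionally under ``acetylate_always``.  The
    operation is idempotent.
    """
    rule = frozenset(rule)
    if not sequence:
        raise DefinitionError("empty sequence")
    cleaved = (
        "cleave_met" in rule
        and sequence[0] == "M"
        and len(sequence) > 1
        and sequence[1] in SMALL_POSITION2_RESIDUES
    )
    processed = sequence[1:] if cleaved else sequence
    acetyl = ("acetylate" in rule and cleaved) or "acetylate_always" in rule
    return processed, acetyl


def derive_vp_sequences(definition: SerotypeDefinition) -> dict[str, str]:
    """Translated chain sequences (pre-processing) for every VP and variant.

    VP1 is the full sequence with its initiator Met; Met-initiated chains
    (VP3, variants) include their own initiator Met, which sits at mature
    position ``start - 1``; VP2 starts directly at its mature position.
    """
    mature = definition.mature_sequence
    met_starts = definition._met_starts()

    def chain(start: int, met_ok: bool) -> str:
        if met_ok and start in met_starts:
            if mature[start - 2] != "M":
                raise DefinitionError(
                    f"{definition.name}: start {start} declared Met-initiated "
                    f"but mature residue {start - 1} is {mature[start - 2]!r}"
                )
            return mature[start - 2 :]
        return mature[start - 1 :]

    out = {
        "VP1": definition.vp1_sequence,
        "VP2": chain(definition.vp2_start, met_ok=False),
        "VP3": chain(definition.vp3_start, met_ok=True),
    }
    for s in definition.variant_starts:
        out[definition.variant_name(s)] = chain(s, met_ok=True)
    return out


@dataclass(frozen=True)
class ProteoformComponent:
    """One target-list entry: a VP plus a modification set, with mass and RT."""

    label: str
    serotype: str
    base_vp: str
    ptm_counts: Mapping[str, int]
    theoretical_mass: float
    expected_rt: float
    rt_window: float
    nterm_acetyl: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "ptm_counts", dict(self.ptm_counts))
        if self.theoretical_mass <= 0:
            raise ConfigurationError(f"{self.label}: non-positive mass")
        if any(c < 0 for c in self.ptm_counts.values()):
            raise ConfigurationError(f"{self.label}: negative PTM count")
        if self.rt_window <= 0:
            raise ConfigurationError(f"{self.label}: rt_window must be > 0")

    @property
    def is_core_unmodified(self) -> bool:
        """True for the unmodified VP1/VP2/VP3 entries a serotype call rests on."""
        return self.base_vp in _CORE_VPS and not any(self.ptm_counts.values())


@dataclass
class ComponentLibrary:
    """Per-serotype proteoform component lists plus provenance metadata."""

    entries: dict[str, list[ProteoformComponent]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for serotype, comps in self.entries.items():
            labels = [c.label for c in comps]
            if len(labels) != len(set(labels)):
                raise ConfigurationError(
                    f"duplicate component labels for serotype {serotype}"
                )

    def all_components(self) -> list[ProteoformComponent]:
        return [c for comps in self.entries.values() for c in comps]

    def serotypes(self) -> list[str]:
        return list(self.entries)

    def core_labels(self, serotype: str) -> set[str]:
        """Labels of the unmodified VP1/VP2/VP3 components of one serotype."""
        return {
            c.label for c in self.entries.get(serotype, []) if c.is_core_unmodified
        }

    def find(self, label: str) -> ProteoformComponent:
        for c in self.all_components():
            if c.label == label:
                return c
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "provenance": dict(self.provenance),
            "serotypes": {
                serotype: [
                    {
                        "label": c.label,
                        "base_vp": c.base_vp,
                        "ptm_counts": dict(c.ptm_counts),
                        "theoretical_mass": c.theoretical_mass,
                        "expected_rt": c.expected_rt,
                        "rt_window": c.rt_window,
                        "nterm_acetyl": c.nterm_acetyl,
                    }
                    for c in comps
                ]
                for serotype, comps in self.entries.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ComponentLibrary":
        entries = {
            serotype: [
                ProteoformComponent(serotype=serotype, **comp)
                for comp in comps
            ]
            for serotype, comps in data.get("serotypes", {}).items()
        }
        return cls(entries=entries, provenance=dict(data.get("provenance", {})))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ComponentLibrary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _component_label(
    definition: SerotypeDefinition,
    vp_name: str,
    acetyl: bool,
    ptm_counts: Mapping[str, int],
) -> str:
    start = definition.chain_start(vp_name)
    end = len(definition.mature_sequence)
    # serotype prefix keeps labels unique across the whole multi-serotype list
    label = f"{definition.name} {vp_name} ({start}-{end})" + ("Ac" if acetyl else "")
    for name in sorted(ptm_counts):
        count = ptm_counts[name]
        if count:
            label += f" + {count}x {name}"
    return label


def build_component_library(
    definitions: Sequence[SerotypeDefinition],
    ptm_table: Iterable[PTMDelta] = DEFAULT_PTM_TABLE,
    rt_calibration: Mapping | None = None,
    proteoform_specs: Sequence[tuple[str, Mapping[str, int]]] = (),
    mass_overrides: Mapping | None = None,
    rt_windows: Mapping[str, float] | None = None,
    mass_table: ResidueMassTable = DEFAULT_MASS_TABLE,
    provenance: Mapping[str, str] | None = None,
) -> ComponentLibrary:
    """Build the proteoform target list for a set of serotypes.

    Parameters
    ----------
    definitions:
        Serotype definitions; every spec VP must exist in each.
    rt_calibration:
        ``{vp_name: rt}`` applied to all serotypes, or nested
        ``{serotype: {vp_name: rt}}``.  Missing entries default to 0.0 (to be
        calibrated later).
    proteoform_specs:
        ``(vp_name, ptm_counts)`` pairs, instantiated per serotype.
    mass_overrides:
        ``{vp_name: mass}`` or ``{(serotype, vp_name): mass}`` pinning a
        chain's base theoretical mass (PTM deltas still apply on top).
    rt_windows:
        Per-VP-name window override; defaults are +/-1.00 min for VP3-class
        chains and +/-0.60 min for VP1/VP2.
    """
    ptm_table = tuple(ptm_table)
    known_ptms = {p.name for p in ptm_table}
    rt_calibration = rt_calibration or {}
    mass_overrides = mass_overrides or {}
    rt_windows = rt_windows or {}

    entries: dict[str, list[ProteoformComponent]] = {}
    for definition in definitions:
        chains = derive_vp_sequences(definition)
        comps: list[ProteoformComponent] = []
        for vp_name, ptm_counts in proteoform_specs:
            if vp_name not in chains:
                raise ConfigurationError(
                    f"unknown VP {vp_name!r} for serotype {definition.name}; "
                    f"available: {sorted(chains)}"
                )
            unknown = set(ptm_counts) - known_ptms
            if unknown:
                raise ConfigurationError(
                    f"unknown PTM names {sorted(unknown)} in spec for {vp_name}"
                )
            processed, acetyl = apply_nterm_processing(
                chains[vp_name], definition.nterm_rule
            )
            override = mass_overrides.get(
                (definition.name, vp_name), mass_overrides.get(vp_name)
            )
            if override is not None:
                base = float(override)
            else:
                base = masscalc.average_mass(processed, acetyl, mass_table)
            mass = masscalc.apply_ptm_deltas(base, ptm_counts, ptm_table)

            cal = rt_calibration.get(definition.name, rt_calibration)
            expected_rt = float(cal.get(vp_name, 0.0)) if isinstance(cal, Mapping) else 0.0
            window = rt_windows.get(
                vp_name, 0.60 if vp_name in ("VP1", "VP2") else 1.00
            )
            comps.append(
                ProteoformComponent(
                    label=_component_label(definition, vp_name, acetyl, ptm_counts),
                    serotype=definition.name,
                    base_vp=vp_name,
                    ptm_counts=dict(ptm_counts),
                    theoretical_mass=mass,
                    expected_rt=expected_rt,
                    rt_window=window,
                    nterm_acetyl=acetyl,
                )
            )
        entries[definition.name] = comps
    return ComponentLibrary(
        entries=entries, provenance=dict(provenance or {"mass_table": "default"})
    )


def load_serotype_definitions(path) -> list[SerotypeDefinition]:
    """Read serotype definitions from a YAML/JSON config file.

    The file holds a list (or a single mapping) with fields ``name``,
    ``vp1_sequence``, ``vp2_start``, ``vp3_start`` and optionally
    ``variant_starts``, ``nterm_rule``, ``met_initiated_starts``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, Mapping):
        data = [data]
    out = []
    for item in data:
        out.append(
            SerotypeDefinition(
                name=item["name"],
                vp1_sequence=item["vp1_sequence"].replace("\n", "").replace(" ", ""),
                vp2_start=int(item["vp2_start"]),
                vp3_start=int(item["vp3_start"]),
                variant_starts=tuple(item.get("variant_starts", ())),
                nterm_rule=frozenset(item.get("nterm_rule", DEFAULT_NTERM_RULE)),
                met_initiated_starts=(
                    tuple(item["met_initiated_starts"])
                    if item.get("met_initiated_starts") is not None
                    else None
                ),
            )
        )
    return out


def dump_serotype_definitions(definitions: Sequence[SerotypeDefinition], path) -> None:
    data = [
        {
            "name": d.name,
            "vp1_sequence": d.vp1_sequence,
            "vp2_start": d.vp2_start,
            "vp3_start": d.vp3_start,
            "variant_starts": list(d.variant_starts),
            "nterm_rule": sorted(d.nterm_rule),
            "met_initiated_starts": (
                list(d.met_initiated_starts)
                if d.met_initiated_starts is not None
                else None
            ),
        }
        for d in definitions
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
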