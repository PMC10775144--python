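"""Mass arithmetic for intact viral-protein chains and their proteoforms.

Average masses drive all intact-level work (the deconvolved masses of 60-82 kDa
chains are isotope-unresolved); monoisotopic masses are carried alongside for
peptide-level use.  All operations are plain functions over a
:class:`ResidueMassTable` so a laboratory can swap in its own constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ResidueMassTable",
    "MassError",
    "DEFAULT_MASS_TABLE",
    "WATER_AVG",
    "WATER_MONO",
    "PROTON_MASS",
    "average_mass",
    "monoisotopic_mass",
    "apply_ptm_deltas",
    "truncation_mass",
    "ppm_error",
]

#: Average mass of H2O in Da.
WATER_AVG = 18.0153
#: Monoisotopic mass of H2O in Da.
WATER_MONO = 18.0105646863
#: Mass of a proton in Da, used for m/z <-> neutral-mass conversion.
PROTON_MASS = 1.00728

# residue letter -> (average Da, monoisotopic Da); standard IUPAC values
_RESIDUES = {
    "A": (71.0788, 71.03711),
    "R": (156.1875, 156.10111),
    "N": (114.1038, 114.04293),
    "D": (115.0886, 115.02694),
    "C": (103.1388, 103.00919),
    "E": (129.1155, 129.04259),
    "Q": (128.1307, 128.05858),
    "G": (57.0519, 57.02146),
    "H": (137.1411, 137.05891),
    "I": (113.1594, 113.08406),
    "L": (113.1594, 113.08406),
    "K": (128.1741, 128.09496),
    "M": (131.1926, 131.04049),
    "F": (147.1766, 147.06841),
    "P": (97.1167, 97.05276),
    "S": (87.0782, 87.03203),
    "T": (101.1051, 101.04768),
    "W": (186.2132, 186.07931),
    "Y": (163.1760, 163.06333),
    "V": (99.1326, 99.06841),
}

#: Average-mass shift of N-terminal acetylation in Da.
ACETYL_AVG = 42.0367
#: Monoisotopic shift of N-terminal acetylation in Da.
ACETYL_MONO = 42.0105646863

CANONICAL_RESIDUES = frozenset(_RESIDUES)


class MassCalcError(ValueError):
    """Raised for invalid sequences or unknown modification names."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue and constant masses used by every mass computation.

    ``residues`` maps each canonical one-letter code to an
    ``(average, monoisotopic)`` pair in Da.
    """

    residues: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_RESIDUES)
    )
    water_avg: float = WATER_AVG
    water_mono: float = WATER_MONO
    proton: float = PROTON_MASS
    acetyl_avg: float = ACETYL_AVG
    acetyl_mono: float = ACETYL_MONO

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - set(self.residues)
        if missing:
            raise MassCalcError(f"mass table missing residues: {sorted(missing)}")
        for letter, (avg, mono) in self.residues.items():
            if avg < mono:
                raise MassCalcError(
                    f"residue {letter}: average mass {avg} < monoisotopic {mono}"
                )

    def average(self, letter: str) -> float:
        return self.residues[letter][0]

    def monoisotopic(self, letter: str) -> float:
        return self.residues[letter][1]


DEFAULT_MASS_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class MassError:
    """Observed vs theoretical mass with the signed ppm difference."""

    observed: float
    theoretical: float
    ppm: float

    @property
    def ppm_magnitude(self) -> float:
        """|ppm| rounded to one decimal, the conventional reporting form."""
        return round(abs(self.ppm), 1)


def _check_sequence(sequence: str) -> None:
    for i, letter in enumerate(sequence):
        if letter not in CANONICAL_RESIDUES:
            raise MassCalcError(
                f"non-canonical residue {letter!r} at position {i + 1}"
            )


def _residue_sum(sequence: str, table: ResidueMassTable, mono: bool) -> float:
    idx = 1 if mono else 0
    return sum(table.residues[r][idx] for r in sequence)


def average_mass(
    sequence: str,
    nterm_acetyl: bool = False,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Average mass in Da of a peptide/protein chain.

    Sum of residue average masses plus one water, plus the acetyl delta when
    ``nterm_acetyl`` is set.  An empty sequence yields the water mass alone
    (degenerate but allowed).
    """
    _check_sequence(sequence)
    mass = _residue_sum(sequence, table, mono=False) + table.water_avg
    if nterm_acetyl:
        mass += table.acetyl_avg
    return mass


def monoisotopic_mass(
    sequence: str,
    nterm_acetyl: bool = False,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Monoisotopic counterpart of :func:`average_mass`."""
    _check_sequence(sequence)
    mass = _residue_sum(sequence, table, mono=True) + table.water_mono
    if nterm_acetyl:
        mass += table.acetyl_mono
    return mass


def apply_ptm_deltas(
    base_mass: float,
    ptm_counts: Mapping[str, int],
    ptm_table: Iterable,
    mono: bool = False,
) -> float:
    """Shift ``base_mass`` by the summed deltas of the named modifications.

    ``ptm_table`` is any iterable of objects exposing ``name``, ``delta_avg``
    and ``delta_mono`` (see :class:`capsidms.capsid_model.PTMDelta`).
    """
    deltas = {
        p.name: (p.delta_mono if mono else p.delta_avg) for p in ptm_table
    }
    mass = base_mass
    for name, count in ptm_counts.items():
        if name not in deltas:
            raise MassCalcError(f"unknown PTM {name!r}; known: {sorted(deltas)}")
        if count < 0:
            raise MassCalcError(f"negative PTM count for {name!r}")
        mass += count * deltas[name]
    return mass


def truncation_mass(
    base_mass: float,
    removed_prefix: str,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Mass after removing an N-terminal stretch of residues.

    Only residue masses are subtracted: the terminal water is retained and any
    N-terminal modification is assumed to be conserved on the new terminus
    (the A211-type variant keeps its acetyl group).
    """
    if not removed_prefix:
        raise MassCalcError("removed_prefix must be non-empty")
    _check_sequence(removed_prefix)
    mass = base_mass - _residue_sum(removed_prefix, table, mono=False)
    if mass <= 0:
        raise MassCalcError(
            f"truncation leaves non-positive mass ({mass:.2f} Da)"
        )
    return mass


def ppm_error(observed: float, theoretical: float) -> MassError:
    """Signed parts-per-million difference between two masses."""
    if theoretical <= 0:
        raise MassCalcError("theoretical mass must be positive")
    ppm = (observed - theoretical) / theoretical * 1e6
    return MassError(observed=observed, theoretical=theoretical, ppm=ppm)
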