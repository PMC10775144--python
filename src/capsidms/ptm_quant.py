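"""Peptide-level PTM quantitation from peptide-spectrum record tables.

The tool consumes already-identified peptide records (sequence, span,
modification, site, confidence, MS area, mass error, charge, flags) and
applies the release-testing arithmetic: threshold filtering, site-level
relative abundance with replicate statistics, mobile-proton classification
and sequence coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideRecord",
    "PeptideFilterParams",
    "SiteQuant",
    "filter_peptides",
    "relative_abundance",
    "site_state_table",
    "mobile_protons",
    "sequence_coverage",
    "read_records_csv",
    "write_records_csv",
]

KNOWN_FLAGS = ("adduct", "unknown_modification", "gas_phase_ion", "nonspecific")
BASIC_RESIDUES = frozenset("RKH")

_SITE_RE = re.compile(r"^([A-Z])(\d+)$")


class PtmQuantError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide in mature-VP1 numbering (1-based inclusive)."""

    replicate: str
    sequence: str
    start: int
    end: int
    modification: str | None
    site: str | None
    confidence: float
    ms_area: float
    mass_error_ppm: float
    charge: int
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))
        if self.start > self.end:
            raise PtmQuantError(f"start {self.start} > end {self.end}")
        if self.end - self.start + 1 != len(self.sequence):
            raise PtmQuantError(
                f"span {self.start}-{self.end} does not fit sequence "
                f"length {len(self.sequence)}"
            )
        if not 0 <= self.confidence <= 100:
            raise PtmQuantError("confidence must be within [0, 100]")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class PeptideFilterParams:
    """Inclusion thresholds for coverage and quantitation."""

    min_confidence: float = 95.0
    min_avg_area: float = 1e5
    max_abs_ppm: float = 5.0
    exclude_flags: frozenset[str] = frozenset(KNOWN_FLAGS)

    def __post_init__(self) -> None:
        object.__setattr__(self, "exclude_flags", frozenset(self.exclude_flags))
        if self.min_confidence < 0 or self.min_avg_area <= 0 or self.max_abs_ppm <= 0:
            raise PtmQuantError("filter thresholds must be positive")


@dataclass(frozen=True)
class SiteQuant:
    """Relative abundance of one modification at one site."""

    site: str
    modification: str
    per_replicate: Mapping[str, float]
    mean_pct: float
    sd_pct: float
    supporting: tuple[PeptideRecord, ...] = field(default=(), repr=False)

    @property
    def covered(self) -> bool:
        return bool(self.per_replicate)


def parse_site(site: str) -> tuple[str, int]:
    """Split a residue+position label like ``Q606`` into ``('Q', 606)``."""
    m = _SITE_RE.match(site)
    if not m:
        raise PtmQuantError(f"bad site label {site!r}")
    return m.group(1), int(m.group(2))


def filter_peptides(
    records: Iterable[PeptideRecord],
    params: PeptideFilterParams = PeptideFilterParams(),
) -> list[PeptideRecord]:
    """Keep records meeting every threshold and carrying no excluded flag.

    Idempotent and order-preserving.
    """
    return [
        r
        for r in records
        if r.confidence >= params.min_confidence
        and r.ms_area >= params.min_avg_area
        and abs(r.mass_error_ppm) <= params.max_abs_ppm
        and not (r.flags & params.exclude_flags)
    ]


def _group_by_replicate(
    records: Iterable[PeptideRecord],
) -> dict[str, list[PeptideRecord]]:
    groups: dict[str, list[PeptideRecord]] = {}
    for r in records:
        groups.setdefault(r.replicate, []).append(r)
    return groups


def relative_abundance(
    records: Iterable[PeptideRecord], site: str, modification: str
) -> SiteQuant:
    """Site-level relative abundance of ``modification``, per replicate then
    averaged.

    Per replicate the abundance is ``100 * modified area / total area`` over
    every record whose span contains the site position; records already
    filtered should be passed in.  A site covered by no record at all yields a
    ``SiteQuant`` with no per-replicate entries (``covered`` is False).
    """
    _, position = parse_site(site)
    per_rep: dict[str, float] = {}
    supporting: list[PeptideRecord] = []
    for rep, recs in sorted(_group_by_replicate(records).items()):
        covering = [r for r in recs if r.covers(position)]
        if not covering:
            continue
        total = sum(r.ms_area for r in covering)
        modified = [
            r
            for r in covering
            if r.modification == modification and r.site == site
        ]
        mod_area = sum(r.ms_area for r in modified)
        per_rep[rep] = 100.0 * mod_area / total if total > 0 else 0.0
        supporting.extend(modified)

    if not per_rep:
        return SiteQuant(
            site=site,
            modification=modification,
            per_replicate={},
            mean_pct=float("nan"),
            sd_pct=float("nan"),
        )
    values = np.array(list(per_rep.values()))
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return SiteQuant(
        site=site,
        modification=modification,
        per_replicate=per_rep,
        mean_pct=float(values.mean()),
        sd_pct=sd,
        supporting=tuple(
            sorted(supporting, key=lambda r: -r.ms_area)
        ),
    )


def site_state_table(
    records: Iterable[PeptideRecord], site: str
) -> dict[str, dict[str, float]]:
    """Per-replicate abundance of every modification state at a site
    (``None``/unmodified reported under ``"unmodified"``); states sum to 100%
    within each replicate."""
    _, position = parse_site(site)
    out: dict[str, dict[str, float]] = {}
    for rep, recs in sorted(_group_by_replicate(records).items()):
        covering = [r for r in recs if r.covers(position)]
        total = sum(r.ms_area for r in covering)
        if not covering or total <= 0:
            continue
        states: dict[str, float] = {}
        for r in covering:
            is_site_mod = r.modification and r.site == site
            key = r.modification if is_site_mod else "unmodified"
            states[key] = states.get(key, 0.0) + r.ms_area
        out[rep] = {k: 100.0 * v / total for k, v in states.items()}
    return out


def mobile_protons(sequence: str, charge: int) -> int:
    """Charges in excess of the basic-residue count (Arg/Lys/His), floored at 0."""
    if charge < 1:
        raise PtmQuantError("charge must be >= 1")
    basic = sum(1 for r in sequence if r in BASIC_RESIDUES)
    return max(0, charge - basic)


def sequence_coverage(
    records: Iterable[PeptideRecord], protein_sequence: str
) -> float:
    """Percentage of residues covered by at least one record (set union)."""
    n = len(protein_sequence)
    covered = np.zeros(n, dtype=bool)
    for r in records:
        if r.start < 1 or r.end > n:
            raise PtmQuantError(
                f"record span {r.start}-{r.end} outside sequence of length {n}"
            )
        covered[r.start - 1 : r.end] = True
    return 100.0 * float(covered.sum()) / n


# ---------------------------------------------------------------------------
# CSV I/O

_COLUMNS = [
    "replicate",
    "sequence",
    "start",
    "end",
    "modification",
    "site",
    "confidence",
    "ms_area",
    "mass_error_ppm",
    "charge",
    "flags",
]


def read_records_csv(path) -> list[PeptideRecord]:
    """Read peptide records from CSV (``flags`` is semicolon-separated)."""
    df = pd.read_csv(path, dtype={"replicate": str})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise PtmQuantError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        flags = (
            frozenset(str(row.flags).split(";"))
            if isinstance(row.flags, str) and row.flags
            else frozenset()
        )
        records.append(
            PeptideRecord(
                replicate=str(row.replicate),
                sequence=row.sequence,
                start=int(row.start),
                end=int(row.end),
                modification=(
                    None if pd.isna(row.modification) else str(row.modification)
                ),
                site=None if pd.isna(row.site) else str(row.site),
                confidence=float(row.confidence),
                ms_area=float(row.ms_area),
                mass_error_ppm=float(row.mass_error_ppm),
                charge=int(row.charge),
                flags=flags,
            )
        )
    return records


def write_records_csv(records: Sequence[PeptideRecord], path) -> None:
    rows = [
        {
            "replicate": r.replicate,
            "sequence": r.sequence,
            "start": r.start,
            "end": r.end,
            "modification": r.modification,
            "site": r.site,
            "confidence": r.confidence,
            "ms_area": r.ms_area,
            "mass_error_ppm": r.mass_error_ppm,
            "charge": r.charge,
            "flags": ";".join(sorted(r.flags)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
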