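"""VP stoichiometry: copy numbers per 60-mer capsid and ratios per 12.

Both read-outs share one proportional rule: the total (60 copies or 12 ratio
units) is divided by the summed areas of all quantified species and multiplied
by each species' own area.  The fluorescence method uses integrated FLR peak
areas (including any VP3-prime-like extra peak); the MS method sums the XIC
areas of all proteoforms of each VP first.  Replicate areas are averaged
before the proportional rule is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .spectra import Peak

__all__ = [
    "SpeciesQuant",
    "StoichiometryResult",
    "vp_copies",
    "vp_ratios",
    "stoichiometry_flr",
    "stoichiometry_ms",
]

TOTAL_COPIES = 60.0
TOTAL_RATIO = 12.0


class StoichiometryError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesQuant:
    """Per-species averaged area with replicate scatter and derived numbers."""

    label: str
    average_area: float
    area_cv_pct: float | None
    copies: float
    ratio: float


@dataclass(frozen=True)
class StoichiometryResult:
    method: str  # "FLR" or "MS"
    species: tuple[SpeciesQuant, ...]
    n_replicates: int

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "n_replicates": self.n_replicates,
            "species": [
                {
                    "label": s.label,
                    "average_area": s.average_area,
                    "area_cv_pct": s.area_cv_pct,
                    "copies": s.copies,
                    "ratio": s.ratio,
                }
                for s in self.species
            ],
            "totals": {
                "copies": round(sum(s.copies for s in self.species), 2),
                "ratio": round(sum(s.ratio for s in self.species), 2),
            },
        }


def _check_areas(areas: Mapping[str, float]) -> float:
    if not areas:
        raise StoichiometryError("no areas supplied")
    if any(a < 0 for a in areas.values()):
        raise StoichiometryError("areas must be >= 0")
    total = float(sum(areas.values()))
    if total <= 0:
        raise StoichiometryError("at least one area must be positive")
    return total


def vp_copies(
    areas: Mapping[str, float], total_copies: float = TOTAL_COPIES
) -> dict[str, float]:
    """Copies per capsid for each species, ``total * area_i / sum(areas)``,
    reported to 2 decimals."""
    total = _check_areas(areas)
    return {k: round(total_copies * a / total, 2) for k, a in areas.items()}


def vp_ratios(
    areas: Mapping[str, float], total_ratio: float = TOTAL_RATIO
) -> dict[str, float]:
    """Ratio units (of 12) per species, same proportional rule as copies."""
    total = _check_areas(areas)
    return {k: round(total_ratio * a / total, 2) for k, a in areas.items()}


def _exact_shares(areas: Mapping[str, float], total: float) -> dict[str, float]:
    s = _check_areas(areas)
    return {k: total * a / s for k, a in areas.items()}


def _mean_cv(values: Sequence[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2 or mean == 0:
        return mean, None
    cv = float(arr.std(ddof=1) / mean * 100.0)
    return mean, round(cv, 2)


def _result_from_mean_areas(
    method: str,
    mean_areas: Mapping[str, float],
    cvs: Mapping[str, float | None],
    n_replicates: int,
) -> StoichiometryResult:
    copies = vp_copies(mean_areas)
    ratios = vp_ratios(mean_areas)
    species = tuple(
        SpeciesQuant(
            label=label,
            average_area=mean_areas[label],
            area_cv_pct=cvs.get(label),
            copies=copies[label],
            ratio=ratios[label],
        )
        for label in mean_areas
    )
    return StoichiometryResult(
        method=method, species=species, n_replicates=n_replicates
    )


def stoichiometry_flr(
    replicate_peaks: Sequence[Mapping[str, Peak | float]],
) -> StoichiometryResult:
    """FLR-based stoichiometry from labeled peak areas per replicate.

    Each replicate is a mapping label -> :class:`~capsidms.spectra.Peak` (or a
    bare area).  Labels must agree across replicates.  Areas are averaged
    first; copies/ratios are then computed on the mean areas.
    """
    if not replicate_peaks:
        raise StoichiometryError("need at least one replicate")
    labels = list(replicate_peaks[0])
    for rep in replicate_peaks[1:]:
        if set(rep) != set(labels):
            raise StoichiometryError(
                f"replicate labels differ: {sorted(rep)} vs {sorted(labels)}"
            )

    def area_of(v) -> float:
        return float(v.area) if isinstance(v, Peak) else float(v)

    mean_areas: dict[str, float] = {}
    cvs: dict[str, float | None] = {}
    for label in labels:
        values = [area_of(rep[label]) for rep in replicate_peaks]
        mean_areas[label], cvs[label] = _mean_cv(values)
    return _result_from_mean_areas("FLR", mean_areas, cvs, len(replicate_peaks))


def stoichiometry_ms(
    replicate_proteoforms: Sequence[Sequence[tuple[str, float]]],
) -> StoichiometryResult:
    """MS-based stoichiometry from per-replicate proteoform XIC areas.

    Each replicate is a sequence of ``(base_vp, xic_area)`` pairs, one per
    matched proteoform; all proteoforms of a VP are summed to represent that
    VP before averaging across replicates.  Species absent from a replicate
    contribute zero to that replicate's sum.
    """
    if not replicate_proteoforms:
        raise StoichiometryError("need at least one replicate")
    if all(len(rep) == 0 for rep in replicate_proteoforms):
        raise StoichiometryError("no matched proteoforms")

    vps: list[str] = []
    for rep in replicate_proteoforms:
        for vp, _ in rep:
            if vp not in vps:
                vps.append(vp)

    mean_areas: dict[str, float] = {}
    cvs: dict[str, float | None] = {}
    for vp in vps:
        sums = []
        for rep in replicate_proteoforms:
            sums.append(sum(a for v, a in rep if v == vp))
        mean_areas[vp], cvs[vp] = _mean_cv(sums)
    return _result_from_mean_areas(
        "MS", mean_areas, cvs, len(replicate_proteoforms)
    )


def exact_copy_shares(areas: Mapping[str, float]) -> dict[str, float]:
    """Unrounded copies; the rounded-to-2-decimals view is :func:`vp_copies`."""
    return _exact_shares(areas, TOTAL_COPIES)


def exact_ratio_shares(areas: Mapping[str, float]) -> dict[str, float]:
    """Unrounded ratios per 12."""
    return _exact_shares(areas, TOTAL_RATIO)
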