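"""Seeded synthetic HILIC-FLR-MS runs and peptide tables with known truth.

Every pipeline stage is testable offline: :func:`simulate_run` emits an MS1
spectrum set (Gaussian elution profiles times Gaussian charge envelopes,
clipped to the instrument scan range), the matching fluorescence trace and a
ground-truth manifest; :func:`simulate_peptide_table` emits peptide records
whose site-level modification splits are drawn around configured truths.
All randomness flows from a single seed through ``numpy.random.default_rng``,
so a fixed seed reproduces byte-identical output on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .capsid_model import SerotypeDefinition
from .masscalc import PROTON_MASS
from .ptm_quant import KNOWN_FLAGS, BASIC_RESIDUES, PeptideRecord
from .spectra import Chromatogram, Scan, SpectrumSet

__all__ = [
    "SimulatedSpecies",
    "SimulationConfig",
    "simulate_run",
    "simulate_peptide_table",
    "make_test_serotype",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulatedSpecies:
    """One proteoform in a simulated run."""

    label: str
    base_vp: str
    mass: float
    rt_apex: float
    rt_sigma: float = 0.15
    abundance: float = 1e6
    charge_center: float | None = None  # None -> mass / 1400 (m/z ~ 1400)
    charge_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise SimulationError(f"{self.label}: abundance must be > 0")
        if self.rt_sigma <= 0 or self.mass <= 0:
            raise SimulationError(f"{self.label}: invalid mass or width")


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level simulation settings.

    Defaults mirror the intact identity method: scans across the
    13.00-28.50 min processing window, m/z 867-2400 scan range, charge
    envelopes of a few dozen protons.  Noise terms default to zero so that
    closed-form oracles hold exactly.
    """

    species: tuple[SimulatedSpecies, ...]
    rt_limits: tuple[float, float] = (13.00, 28.50)
    scan_interval: float = 0.05
    mz_range: tuple[float, float] = (867.0, 2400.0)
    flr_scale: float = 1.0
    baseline_level: float = 0.0
    intensity_jitter: float = 0.0
    n_noise_peaks: int = 0
    noise_peak_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise SimulationError("need at least one species")
        lo, hi = self.rt_limits
        for sp in self.species:
            if not lo <= sp.rt_apex <= hi:
                raise SimulationError(
                    f"{sp.label}: rt apex {sp.rt_apex} outside limits {self.rt_limits}"
                )
        if self.scan_interval <= 0:
            raise SimulationError("scan_interval must be > 0")


def _envelope_charges(
    mass: float, mz_range: tuple[float, float]
) -> np.ndarray:
    """Integer charges whose m/z falls inside the scan range."""
    lo, hi = mz_range
    z_min = math.ceil(mass / (hi - PROTON_MASS))
    z_max = math.floor(mass / (lo - PROTON_MASS))
    if z_max < z_min:
        return np.array([], dtype=int)
    return np.arange(max(1, z_min), z_max + 1)


def species_envelope(
    sp: SimulatedSpecies, mz_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """(m/z values, normalized weights) of a species' charge envelope."""
    charges = _envelope_charges(sp.mass, mz_range)
    if charges.size == 0:
        raise SimulationError(
            f"{sp.label}: no charge state of mass {sp.mass:.1f} falls in "
            f"scan range {mz_range}"
        )
    center = sp.charge_center if sp.charge_center is not None else sp.mass / 1400.0
    w = np.exp(-0.5 * ((charges - center) / sp.charge_sigma) ** 2)
    if w.sum() == 0:
        raise SimulationError(f"{sp.label}: charge envelope entirely truncated")
    mz = (sp.mass + charges * PROTON_MASS) / charges
    return mz, w / w.sum()


def simulate_run(
    cfg: SimulationConfig,
) -> tuple[SpectrumSet, Chromatogram, dict]:
    """Generate one synthetic HILIC-FLR-MS run.

    Returns ``(spectra, flr, manifest)``; the manifest records every species'
    true mass, apex, charge support and closed-form FLR/MS areas, plus the
    full configuration snapshot.
    """
    rng = np.random.default_rng(cfg.seed)
    rts = np.arange(cfg.rt_limits[0], cfg.rt_limits[1] + 1e-9, cfg.scan_interval)

    envelopes = [species_envelope(sp, cfg.mz_range) for sp in cfg.species]

    scans: list[Scan] = []
    for rt in rts:
        mz_parts: list[np.ndarray] = []
        in_parts: list[np.ndarray] = []
        for sp, (mz, w) in zip(cfg.species, envelopes):
            g = math.exp(-0.5 * ((rt - sp.rt_apex) / sp.rt_sigma) ** 2)
            inten = sp.abundance * g * w
            if cfg.intensity_jitter > 0:
                inten = inten * (
                    1.0 + cfg.intensity_jitter * rng.standard_normal(inten.size)
                )
                inten = np.clip(inten, 0.0, None)
            keep = inten > sp.abundance * 1e-6
            if keep.any():
                mz_parts.append(mz[keep])
                in_parts.append(inten[keep])
        if cfg.n_noise_peaks:
            noise_mz = rng.uniform(*cfg.mz_range, size=cfg.n_noise_peaks)
            noise_in = rng.exponential(
                cfg.noise_peak_intensity, size=cfg.n_noise_peaks
            )
            mz_parts.append(noise_mz)
            in_parts.append(noise_in)
        if mz_parts:
            mz_all = np.concatenate(mz_parts)
            in_all = np.concatenate(in_parts)
            order = np.argsort(mz_all)
            scans.append(Scan(rt=float(rt), mz=mz_all[order], intensity=in_all[order]))
        else:
            scans.append(Scan(rt=float(rt), mz=np.array([]), intensity=np.array([])))

    spectra = SpectrumSet(
        scans=scans,
        metadata={"simulated": True, "seed": cfg.seed, "mz_range": cfg.mz_range},
    )

    flr_int = np.full(rts.size, cfg.baseline_level, dtype=float)
    for sp in cfg.species:
        flr_int += (
            cfg.flr_scale
            * sp.abundance
            * np.exp(-0.5 * ((rts - sp.rt_apex) / sp.rt_sigma) ** 2)
        )
    if cfg.intensity_jitter > 0:
        flr_int = np.clip(
            flr_int * (1.0 + cfg.intensity_jitter * rng.standard_normal(rts.size)),
            0.0,
            None,
        )
    flr = Chromatogram(label="FLR", time=rts.copy(), intensity=flr_int)

    sqrt2pi = math.sqrt(2.0 * math.pi)
    manifest = {
        "seed": cfg.seed,
        "rt_limits": list(cfg.rt_limits),
        "scan_interval": cfg.scan_interval,
        "mz_range": list(cfg.mz_range),
        "n_scans": int(rts.size),
        "species": [
            {
                "label": sp.label,
                "base_vp": sp.base_vp,
                "mass": sp.mass,
                "rt_apex": sp.rt_apex,
                "rt_sigma": sp.rt_sigma,
                "abundance": sp.abundance,
                "charges": [int(z.min()), int(z.max())],
                "flr_area": cfg.flr_scale * sp.abundance * sp.rt_sigma * sqrt2pi,
                "ms_area": sp.abundance * sp.rt_sigma * sqrt2pi,
            }
            for sp, z in zip(
                cfg.species,
                [_envelope_charges(sp.mass, cfg.mz_range) for sp in cfg.species],
            )
        ],
    }
    return spectra, flr, manifest


def simulate_peptide_table(
    protein_sequence: str,
    site_truths: Mapping[str, tuple[str, float]],
    n_replicates: int = 3,
    seed: int = 0,
    peptide_length: int = 20,
    base_area: float = 1e6,
    abundance_noise_sd: float = 0.0,
    area_jitter: float = 0.0,
    n_flagged: int = 0,
) -> list[PeptideRecord]:
    """Tile ``protein_sequence`` into peptides with known modification splits.

    ``site_truths`` maps a site label (e.g. ``"N56"``) to
    ``(modification name, true percent abundance)``.  Each tile containing a
    site is emitted as a modified record carrying ``truth + noise`` percent of
    the tile's area plus one unmodified record carrying the rest.
    ``n_flagged`` appends that many decoy records carrying exclusion flags.
    """
    from .ptm_quant import parse_site

    rng = np.random.default_rng(seed)
    n = len(protein_sequence)
    sites = {}
    for label, (mod, pct) in site_truths.items():
        residue, pos = parse_site(label)
        if not 1 <= pos <= n:
            raise SimulationError(f"site {label} outside sequence")
        if protein_sequence[pos - 1] != residue:
            raise SimulationError(
                f"site {label}: sequence has {protein_sequence[pos - 1]!r} there"
            )
        if not 0 <= pct <= 100:
            raise SimulationError(f"site {label}: abundance outside [0, 100]")
        sites[label] = (mod, pct, pos)

    windows = [
        (s, min(s + peptide_length - 1, n))
        for s in range(1, n + 1, peptide_length)
    ]

    records: list[PeptideRecord] = []
    for rep in range(1, n_replicates + 1):
        rep_id = str(rep)
        for start, end in windows:
            seq = protein_sequence[start - 1 : end]
            charge = max(
                1, 1 + sum(1 for r in seq if r in BASIC_RESIDUES)
            )
            total = base_area * (
                1.0 + (area_jitter * rng.standard_normal() if area_jitter else 0.0)
            )
            total = max(total, base_area * 0.1)
            covered = {
                label: (mod, pct)
                for label, (mod, pct, pos) in sites.items()
                if start <= pos <= end
            }
            mod_fraction_sum = 0.0
            for label, (mod, pct) in sorted(covered.items()):
                noisy = pct + (
                    abundance_noise_sd * rng.standard_normal()
                    if abundance_noise_sd
                    else 0.0
                )
                frac = min(max(noisy, 0.0), 100.0) / 100.0
                mod_fraction_sum += frac
                if mod_fraction_sum > 1.0:
                    raise SimulationError(
                        f"window {start}-{end}: modified fractions exceed 100%"
                    )
                records.append(
                    PeptideRecord(
                        replicate=rep_id,
                        sequence=seq,
                        start=start,
                        end=end,
                        modification=mod,
                        site=label,
                        confidence=100.0,
                        ms_area=total * frac,
                        mass_error_ppm=float(rng.uniform(-2.0, 2.0)),
                        charge=charge,
                        flags=frozenset(),
                    )
                )
            records.append(
                PeptideRecord(
                    replicate=rep_id,
                    sequence=seq,
                    start=start,
                    end=end,
                    modification=None,
                    site=None,
                    confidence=100.0,
                    ms_area=total * (1.0 - mod_fraction_sum),
                    mass_error_ppm=float(rng.uniform(-2.0, 2.0)),
                    charge=charge,
                    flags=frozenset(),
                )
            )

    for i in range(n_flagged):
        start, end = windows[0]
        records.append(
            PeptideRecord(
                replicate="1",
                sequence=protein_sequence[start - 1 : end],
                start=start,
                end=end,
                modification=None,
                site=None,
                confidence=100.0,
                ms_area=base_area,
                mass_error_ppm=0.0,
                charge=2,
                flags=frozenset({KNOWN_FLAGS[i % len(KNOWN_FLAGS)]}),
            )
        )
    return records


_SEQ_ALPHABET = "ADEFGHIKLNPQRSTVWY"  # no Met so initiator placement is explicit


def make_test_serotype(
    name: str,
    seed: int,
    length: int = 700,
    vp2_start: int = 120,
    vp3_start: int = 180,
    variant_start: int | None = None,
) -> SerotypeDefinition:
    """Deterministic toy serotype with realistic chain sizes.

    The mature sequence is random (seeded), begins with Ala so Met excision
    fires, and carries explicit initiator Met residues immediately before the
    VP3 (and optional variant) starts.  Different seeds give sequences whose
    chain masses differ by far more than any matching tolerance, which is what
    the identity-specificity tests need.
    """
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(_SEQ_ALPHABET), size=length)
    letters[0] = "A"
    if vp3_start >= 2:
        letters[vp3_start - 2] = "M"
        letters[vp3_start - 1] = "A"
    if variant_start is not None:
        letters[variant_start - 2] = "M"
        letters[variant_start - 1] = "A"
    mature = "".join(letters)
    return SerotypeDefinition(
        name=name,
        vp1_sequence="M" + mature,
        vp2_start=vp2_start,
        vp3_start=vp3_start,
        variant_starts=(variant_start,) if variant_start is not None else (),
    )
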