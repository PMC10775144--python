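"""Intact-run MS1 and fluorescence-trace processing.

Covers reading spectrum sets (minimal mzML or a plain-text CSV spectrum-table
dialect), charge-ladder deconvolution of multiply-protonated envelopes to
neutral average masses, extracted-ion chromatograms and chromatographic peak
integration.

The deconvolution is a standard consecutive-charge ladder method: every
observed peak at m/z ``m`` is re-interpreted under each candidate charge ``z``
as a neutral-mass hypothesis ``M = z * (m - proton)``; hypotheses agreeing
within the merge tolerance across several distinct charge states form a
feature.  A greedy pass assigns each observed peak to the most intense
surviving feature first, which suppresses the classic 2x/0.5x harmonic
artifacts.  The 0-100 quality score grows with the number of supporting charge
states and the completeness of the ladder; it is calibrated only so that
well-supported envelopes exceed the conventional >=60 acceptance threshold
while sparse coincidences do not.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .masscalc import PROTON_MASS

__all__ = [
    "Scan",
    "SpectrumSet",
    "Chromatogram",
    "DeconvolvedFeature",
    "Peak",
    "DeconvolutionParams",
    "read_spectra",
    "write_spectra",
    "deconvolve",
    "extract_xic",
    "integrate_peaks",
]


class SpectraError(ValueError):
    pass


@dataclass(frozen=True)
class Scan:
    """One MS1 scan: retention time (min) plus sorted m/z and intensity arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise SpectraError("mz and intensity arrays differ in length")
        if mz.size > 1 and np.any(np.diff(mz) < 0):
            order = np.argsort(mz)
            mz, inten = mz[order], inten[order]
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)


@dataclass
class SpectrumSet:
    """Ordered MS1 scans with acquisition metadata."""

    scans: list[Scan]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise SpectraError("scan retention times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def within(self, rt_limits: tuple[float, float]) -> "SpectrumSet":
        lo, hi = rt_limits
        return SpectrumSet(
            scans=[s for s in self.scans if lo <= s.rt <= hi],
            metadata={**self.metadata, "rt_limits": (lo, hi)},
        )


@dataclass
class Chromatogram:
    """A single detector trace (FLR channel or XIC) on a minute time axis."""

    label: str
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape:
            raise SpectraError("time and intensity arrays differ in length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise SpectraError("chromatogram time axis must be increasing")
        self.time, self.intensity = t, y

    def total_integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.time))

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_min,intensity\n")
            for t, y in zip(self.time, self.intensity):
                fh.write(f"{t:.6f},{y:.6f}\n")

    @classmethod
    def read_csv(cls, path, label: str = "FLR") -> "Chromatogram":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(label=label, time=data[:, 0], intensity=data[:, 1])


@dataclass(frozen=True)
class DeconvolvedFeature:
    """A neutral mass recovered from a charge ladder."""

    neutral_mass: float
    rt_apex: float
    area: float
    score: float
    n_charge_states: int

    def __post_init__(self) -> None:
        if self.area < 0:
            raise SpectraError("feature area must be >= 0")
        if not 0 <= self.score <= 100:
            raise SpectraError("score must lie in [0, 100]")
        if self.n_charge_states < 1:
            raise SpectraError("feature needs at least one charge state")


@dataclass(frozen=True)
class Peak:
    """A chromatographic peak with valley-to-valley bounds."""

    apex_rt: float
    start_rt: float
    end_rt: float
    area: float
    height: float

    def __post_init__(self) -> None:
        if not self.start_rt < self.apex_rt < self.end_rt:
            raise SpectraError("peak bounds must bracket the apex")
        if self.area <= 0:
            raise SpectraError("peak area must be positive")


@dataclass(frozen=True)
class DeconvolutionParams:
    """Tunables for charge-ladder deconvolution.

    Defaults follow the processing settings of the intact identity method:
    13.00-28.50 min time limit, 10 ppm merge tolerance, at least 10 supporting
    measurements per feature, charge search centered on 35.
    """

    charge_range: tuple[int, int] = (20, 50)
    merge_tolerance_ppm: float = 10.0
    rt_limits: tuple[float, float] = (13.00, 28.50)
    min_intervals: int = 10
    min_charge_states: int = 3
    proton_mass: float = PROTON_MASS
    peak_rel_threshold: float = 1e-3
    peak_abs_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.merge_tolerance_ppm <= 0:
            raise SpectraError("merge tolerance must be > 0")
        if self.rt_limits[0] >= self.rt_limits[1]:
            raise SpectraError("rt_limits must be ordered")
        if self.charge_range[0] < 1 or self.charge_range[0] > self.charge_range[1]:
            raise SpectraError("invalid charge range")


# ---------------------------------------------------------------------------
# spectrum I/O


def read_spectra(path, dialect: str = "auto") -> SpectrumSet:
    """Read MS1 scans from ``path``.

    ``dialect`` is ``"mzml"``, ``"csv"`` (spectrum-table rows
    ``rt_min,mz,intensity``) or ``"auto"`` (by file suffix).
    """
    path = str(path)
    if dialect == "auto":
        dialect = "mzml" if path.lower().endswith(".mzml") else "csv"
    if dialect == "csv":
        return _read_csv_spectra(path)
    if dialect == "mzml":
        return _read_mzml(path)
    raise SpectraError(f"unknown spectrum dialect {dialect!r}")


def write_spectra(spectra: SpectrumSet, path, dialect: str = "auto") -> None:
    path = str(path)
    if dialect == "auto":
        dialect = "mzml" if path.lower().endswith(".mzml") else "csv"
    if dialect == "csv":
        _write_csv_spectra(spectra, path)
    elif dialect == "mzml":
        _write_mzml(spectra, path)
    else:
        raise SpectraError(f"unknown spectrum dialect {dialect!r}")


def _read_csv_spectra(path) -> SpectrumSet:
    scans: list[Scan] = []
    cur_rt: float | None = None
    buf_mz: list[float] = []
    buf_in: list[float] = []

    def flush() -> None:
        if cur_rt is not None:
            scans.append(
                Scan(rt=cur_rt, mz=np.array(buf_mz), intensity=np.array(buf_in))
            )
            buf_mz.clear()
            buf_in.clear()

    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:3] != ["rt_min", "mz", "intensity"]:
            raise SpectraError(
                f"{path}: expected header 'rt_min,mz,intensity', got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                rt_s, mz_s, in_s = line.split(",")
                rt, mz, inten = float(rt_s), float(mz_s), float(in_s)
            except ValueError as exc:
                raise SpectraError(f"{path}:{lineno}: malformed row") from exc
            if cur_rt is not None and rt != cur_rt:
                flush()
                cur_rt = rt
            elif cur_rt is None:
                cur_rt = rt
            buf_mz.append(mz)
            buf_in.append(inten)
    flush()
    return SpectrumSet(scans=scans, metadata={"source": str(path), "dialect": "csv"})


def _write_csv_spectra(spectra: SpectrumSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("rt_min,mz,intensity\n")
        for scan in spectra.scans:
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{scan.rt:.6f},{mz:.6f},{inten:.6f}\n")


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64_floats(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{values.size}d", *np.asarray(values, dtype=float))
    ).decode("ascii")


def _floats_b64(text: str, n: int) -> np.ndarray:
    raw = base64.b64decode(text)
    return np.array(struct.unpack(f"<{n}d", raw))


def _write_mzml(spectra: SpectrumSet, path) -> None:
    """Write a minimal uncompressed mzML file (MS1 scans, 64-bit arrays)."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0">',
        '  <run id="run">',
        f'    <spectrumList count="{len(spectra)}">',
    ]
    for i, scan in enumerate(spectra.scans):
        n = scan.mz.size
        lines += [
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">',
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>',
            "        <scanList count=\"1\">",
            "          <scan>",
            '            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt:.6f}" unitName="minute"/>',
            "          </scan>",
            "        </scanList>",
            '        <binaryDataArrayList count="2">',
        ]
        for accession, name, arr in (
            ("MS:1000514", "m/z array", scan.mz),
            ("MS:1000515", "intensity array", scan.intensity),
        ):
            lines += [
                "          <binaryDataArray>",
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>',
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>',
                f'            <cvParam cvRef="MS" accession="{accession}" name="{name}"/>',
                f"            <binary>{_b64_floats(arr)}</binary>",
                "          </binaryDataArray>",
            ]
        lines += ["        </binaryDataArrayList>", "      </spectrum>"]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _read_mzml(path) -> SpectrumSet:
    """Read MS1 scans from an mzML file (uncompressed 64-bit arrays only)."""
    ns = {"mz": _MZML_NS}
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SpectraError(f"{path}: malformed mzML ({exc})") from exc
    scans: list[Scan] = []
    for idx, spec in enumerate(tree.iter(f"{{{_MZML_NS}}}spectrum")):
        level = None
        for cv in spec.findall(".//mz:cvParam", ns):
            if cv.get("accession") == "MS:1000511":
                level = cv.get("value")
        if level not in (None, "1"):
            continue
        rt = None
        for cv in spec.findall(".//mz:scanList//mz:cvParam", ns):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        n = int(spec.get("defaultArrayLength", 0))
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.findall(".//mz:binaryDataArray", ns):
            kind = None
            for cv in bda.findall("mz:cvParam", ns):
                acc = cv.get("accession")
                if acc == "MS:1000514":
                    kind = "mz"
                elif acc == "MS:1000515":
                    kind = "intensity"
                elif acc in ("MS:1000574", "MS:1002312", "MS:1002746"):
                    raise SpectraError(
                        f"{path}: scan {idx}: compressed binary arrays not supported"
                    )
            binary = bda.find("mz:binary", ns)
            if kind and binary is not None and binary.text:
                arrays[kind] = _floats_b64(binary.text.strip(), n)
        if rt is None or "mz" not in arrays or "intensity" not in arrays:
            raise SpectraError(f"{path}: scan {idx}: missing rt or binary arrays")
        scans.append(Scan(rt=rt, mz=arrays["mz"], intensity=arrays["intensity"]))
    return SpectrumSet(scans=scans, metadata={"source": str(path), "dialect": "mzml"})


# ---------------------------------------------------------------------------
# deconvolution


def _pick_peaks(scan: Scan, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Points above ``threshold``.  Scans are treated as centroid data, so
    every above-threshold point is a candidate ion (profile peak-shape fitting
    is out of scope)."""
    keep = scan.intensity > threshold
    return scan.mz[keep], scan.intensity[keep]


def deconvolve(
    spectra: SpectrumSet, params: DeconvolutionParams = DeconvolutionParams()
) -> list[DeconvolvedFeature]:
    """Charge-ladder deconvolution of an MS1 run to neutral-mass features.

    Returns features sorted by descending area.  An empty scan window yields
    an empty list.
    """
    windowed = spectra.within(params.rt_limits)
    if len(windowed) == 0:
        return []

    global_max = max(
        (float(s.intensity.max()) for s in windowed.scans if s.intensity.size),
        default=0.0,
    )
    threshold = max(
        params.peak_abs_threshold, params.peak_rel_threshold * global_max
    )

    z_lo, z_hi = params.charge_range
    charges = np.arange(z_lo, z_hi + 1)

    # picked-peak table
    p_mz, p_int, p_scan = [], [], []
    for si, scan in enumerate(windowed.scans):
        mz, inten = _pick_peaks(scan, threshold)
        p_mz.append(mz)
        p_int.append(inten)
        p_scan.append(np.full(mz.size, si))
    peak_mz = np.concatenate(p_mz) if p_mz else np.array([])
    if peak_mz.size == 0:
        return []
    peak_int = np.concatenate(p_int)
    peak_scan = np.concatenate(p_scan).astype(int)
    n_peaks = peak_mz.size

    # hypothesis table: every peak under every candidate charge, sorted by mass
    hyp_mass = (charges[:, None] * (peak_mz[None, :] - params.proton_mass)).ravel()
    hyp_z = np.repeat(charges, n_peaks)
    hyp_peak = np.tile(np.arange(n_peaks), charges.size)
    order = np.argsort(hyp_mass)
    hyp_mass, hyp_z, hyp_peak = hyp_mass[order], hyp_z[order], hyp_peak[order]
    hyp_int = peak_int[hyp_peak]
    hyp_scan = peak_scan[hyp_peak]

    tol = params.merge_tolerance_ppm * 1e-6
    rts = windowed.rts
    scan_dt = float(np.median(np.diff(rts))) if rts.size > 1 else 1.0

    def window(center: float) -> slice:
        lo = np.searchsorted(hyp_mass, center * (1 - tol), side="left")
        hi = np.searchsorted(hyp_mass, center * (1 + tol), side="right")
        return slice(lo, hi)

    consumed = np.zeros(n_peaks, dtype=bool)
    dead_seed = np.zeros(n_peaks, dtype=bool)
    seed_floor = max(threshold, 0.01 * global_max)
    seed_order = np.argsort(-peak_int)

    features: list[DeconvolvedFeature] = []
    for seed in seed_order:
        if consumed[seed] or dead_seed[seed]:
            continue
        if peak_int[seed] < seed_floor:
            break
        # pick the charge whose neutral-mass hypothesis gathers most support
        best = None
        for z in charges:
            m_hyp = z * (peak_mz[seed] - params.proton_mass)
            sl = window(m_hyp)
            live = ~consumed[hyp_peak[sl]]
            support = float(hyp_int[sl][live].sum())
            if best is None or support > best[0]:
                best = (support, m_hyp, sl)
        _, m_hyp, sl = best
        live = ~consumed[hyp_peak[sl]]
        cm, ci = hyp_mass[sl][live], hyp_int[sl][live]
        if cm.size == 0:
            dead_seed[seed] = True
            continue
        # refine the center once with the intensity-weighted mean
        center = float(np.average(cm, weights=ci))
        sl = window(center)
        live = ~consumed[hyp_peak[sl]]
        cm, ci = hyp_mass[sl][live], hyp_int[sl][live]
        cz, cs = hyp_z[sl][live], hyp_scan[sl][live]
        uz = np.unique(cz)
        if uz.size < params.min_charge_states or cm.size < params.min_intervals:
            dead_seed[seed] = True
            continue
        neutral = float(np.average(cm, weights=ci))

        per_scan = np.zeros(rts.size)
        np.add.at(per_scan, cs, ci)
        apex = float(rts[int(np.argmax(per_scan))])
        area = float(np.trapezoid(per_scan, rts)) if rts.size > 1 else float(
            per_scan.sum() * scan_dt
        )

        completeness = uz.size / (int(uz.max()) - int(uz.min()) + 1)
        score = 100.0 * completeness * (1.0 - np.exp(-(uz.size - 1) / 4.0))
        features.append(
            DeconvolvedFeature(
                neutral_mass=neutral,
                rt_apex=apex,
                area=area,
                score=float(min(100.0, max(0.0, score))),
                n_charge_states=int(uz.size),
            )
        )
        consumed[np.unique(hyp_peak[sl][live])] = True

    features.sort(key=lambda f: -f.area)
    return features


# ---------------------------------------------------------------------------
# XIC + peak integration


def extract_xic(
    spectra: SpectrumSet,
    target_mass: float,
    charges: Iterable[int],
    tol_ppm: float = 10.0,
    proton_mass: float = PROTON_MASS,
    label: str | None = None,
) -> Chromatogram:
    """Per-scan intensity summed within ``tol_ppm`` of each theoretical m/z
    of ``target_mass`` over the given charge states."""
    charges = list(charges)
    if not charges:
        raise SpectraError("charge list must be non-empty")
    targets = np.array([(target_mass + zc * proton_mass) / zc for zc in charges])
    tols = targets * tol_ppm * 1e-6
    out = np.zeros(len(spectra))
    for i, scan in enumerate(spectra.scans):
        lo = np.searchsorted(scan.mz, targets - tols, side="left")
        hi = np.searchsorted(scan.mz, targets + tols, side="right")
        out[i] = sum(
            float(scan.intensity[a:b].sum()) for a, b in zip(lo, hi) if b > a
        )
    return Chromatogram(
        label=label or f"XIC {target_mass:.2f}",
        time=spectra.rts,
        intensity=out,
    )


def integrate_peaks(
    chromatogram: Chromatogram,
    noise_multiplier: float = 5.0,
    min_height: float | None = None,
) -> list[Peak]:
    """Detect local maxima above a robust noise threshold and integrate them.

    The threshold defaults to ``median + noise_multiplier * MAD`` of the trace
    (overridable via ``min_height``).  Peak bounds are valley-to-valley: the
    boundary walks downhill from each apex until the trace turns upward or the
    trace ends; adjacent peaks share the minimum between them.  Areas are
    trapezoidal in counts x minutes.
    """
    t, y = chromatogram.time, chromatogram.intensity
    if t.size < 3:
        return []
    median = float(np.median(y))
    mad = float(np.median(np.abs(y - median)))
    threshold = median + noise_multiplier * mad if min_height is None else min_height
    if mad == 0 and min_height is None and median == float(y.max()):
        return []  # flat trace

    apex_idx = [
        i
        for i in range(1, t.size - 1)
        if y[i] > threshold
        and y[i] >= y[i - 1]
        and y[i] >= y[i + 1]
        and (y[i] > y[i - 1] or y[i] > y[i + 1])  # reject flat runs at both sides
    ]
    # keep the earliest point of any plateau apex
    deduped: list[int] = []
    for i in apex_idx:
        if deduped and y[i] == y[deduped[-1]] and all(
            y[j] == y[i] for j in range(deduped[-1], i)
        ):
            continue
        deduped.append(i)

    peaks: list[Peak] = []
    for k, i in enumerate(deduped):
        left = i
        left_limit = deduped[k - 1] if k > 0 else 0
        while left > left_limit and y[left - 1] <= y[left]:
            left -= 1
        right = i
        right_limit = deduped[k + 1] if k + 1 < len(deduped) else t.size - 1
        while right < right_limit and y[right + 1] <= y[right]:
            right += 1
        if k > 0 and left <= deduped[k - 1]:
            left = int(np.argmin(y[deduped[k - 1] : i])) + deduped[k - 1]
        if k + 1 < len(deduped) and right >= deduped[k + 1]:
            right = int(np.argmin(y[i : deduped[k + 1]])) + i
        if left == i or right == i:
            continue
        area = float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
        if area <= 0:
            continue
        peaks.append(
            Peak(
                apex_rt=float(t[i]),
                start_rt=float(t[left]),
                end_rt=float(t[right]),
                area=area,
                height=float(y[i]),
            )
        )
    return peaks


def label_peaks(
    peaks: Sequence[Peak], expected_rts: dict[str, float], max_offset: float = 1.5
) -> dict[str, Peak]:
    """Assign each expected species the nearest peak apex within ``max_offset``
    minutes; used to name FLR peaks before stoichiometry."""
    out: dict[str, Peak] = {}
    taken: set[int] = set()
    for name, rt in sorted(expected_rts.items(), key=lambda kv: kv[1]):
        best, best_d = None, max_offset
        for idx, p in enumerate(peaks):
            d = abs(p.apex_rt - rt)
            if idx not in taken and d <= best_d:
                best, best_d = idx, d
        if best is not None:
            taken.add(best)
            out[name] = peaks[best]
    return out
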