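"""User-facing workflows: rapid identity testing and serotype PTM monitoring.

Both workflows share one deconvolution pass over the raw runs; only the
component target list differs (identity uses the unmodified VPs of every
serotype in the library, PTM monitoring the modified proteoforms of one
serotype).  A sample processed for identity can therefore be reprocessed for
PTM monitoring from the cached features without touching the raw data again.
Every report embeds the full parameter snapshot and the tool version.
"""

from __future__ import annotations

import csv as _csv
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .capsid_model import ComponentLibrary
from .identity import (
    IdentityParams,
    call_serotype,
    filter_replicates,
    match_components,
)
from .spectra import (
    DeconvolutionParams,
    DeconvolvedFeature,
    SpectrumSet,
    deconvolve,
    extract_xic,
    read_spectra,
)

__all__ = [
    "RunManifest",
    "WorkflowError",
    "deconvolve_runs",
    "run_identity",
    "run_ptm_monitor",
    "generate_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1"

logger = logging.getLogger("capsidms")


class WorkflowError(RuntimeError):
    """A stage failure annotated with the stage name and run id."""

    def __init__(self, stage: str, run_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for run {run_id!r}: {cause}")
        self.stage = stage
        self.run_id = run_id
        self.__cause__ = cause


@dataclass
class RunManifest:
    """Files and parameters of one workflow execution."""

    method: str  # identity | ptm_monitor | stoich
    runs: dict[str, str]  # run id -> file path
    library_path: str | None = None
    serotype: str | None = None
    identity_params: IdentityParams = field(default_factory=IdentityParams)
    decon_params: DeconvolutionParams = field(default_factory=DeconvolutionParams)

    def load_spectra(self) -> dict[str, SpectrumSet]:
        out = {}
        for run_id, path in self.runs.items():
            try:
                out[run_id] = read_spectra(path)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise WorkflowError("read", run_id, exc) from exc
        return out


def _params_snapshot(
    identity_params: IdentityParams, decon_params: DeconvolutionParams
) -> dict:
    return {
        "identity": {
            **dataclasses.asdict(identity_params),
            "rt_window_overrides": dict(identity_params.rt_window_overrides),
        },
        "deconvolution": dataclasses.asdict(decon_params),
    }


def deconvolve_runs(
    spectra_by_run: Mapping[str, SpectrumSet],
    decon_params: DeconvolutionParams = DeconvolutionParams(),
) -> dict[str, list[DeconvolvedFeature]]:
    """One deconvolution pass per run; the result is reusable by both methods."""
    out: dict[str, list[DeconvolvedFeature]] = {}
    for run_id, spectra in spectra_by_run.items():
        t0 = time.perf_counter()
        try:
            out[run_id] = deconvolve(spectra, decon_params)
        except Exception as exc:  # noqa: BLE001
            raise WorkflowError("deconvolve", run_id, exc) from exc
        logger.info(
            "deconvolve run=%s scans=%d features=%d elapsed=%.2fs",
            run_id,
            len(spectra),
            len(out[run_id]),
            time.perf_counter() - t0,
        )
    return out


def _feature_dict(f: DeconvolvedFeature) -> dict:
    return {
        "neutral_mass": round(f.neutral_mass, 4),
        "rt_apex": round(f.rt_apex, 3),
        "area": round(f.area, 3),
        "score": round(f.score, 1),
        "n_charge_states": f.n_charge_states,
    }


def _match_runs(
    features_by_run: Mapping[str, Sequence[DeconvolvedFeature]],
    library: ComponentLibrary,
    params: IdentityParams,
):
    per_run = {}
    for run_id, feats in features_by_run.items():
        try:
            per_run[run_id] = match_components(
                feats, library, params, replicate_id=run_id
            )
        except Exception as exc:  # noqa: BLE001
            raise WorkflowError("match", run_id, exc) from exc
    return per_run


def _runs_section(per_run_matches, features_by_run) -> dict:
    return {
        run_id: {
            "n_features": len(features_by_run[run_id]),
            "matches": [
                {
                    "component": m.component_label,
                    "serotype": m.serotype,
                    "base_vp": m.base_vp,
                    "mass_error_ppm": round(m.mass_error_ppm, 2),
                    "rt_offset_min": round(m.rt_offset, 3),
                    "shared_feature": m.shared_feature,
                    "feature": _feature_dict(m.feature),
                }
                for m in matches
            ],
        }
        for run_id, matches in per_run_matches.items()
    }


def run_identity(
    library: ComponentLibrary,
    spectra_by_run: Mapping[str, SpectrumSet] | None = None,
    features_by_run: Mapping[str, Sequence[DeconvolvedFeature]] | None = None,
    identity_params: IdentityParams = IdentityParams(),
    decon_params: DeconvolutionParams = DeconvolutionParams(),
) -> dict:
    """Rapid identity testing: read -> deconvolve -> match -> consensus -> call.

    Pass ``features_by_run`` to reuse an earlier deconvolution pass.
    Returns the JSON-serializable report.
    """
    if features_by_run is None:
        if spectra_by_run is None:
            raise ValueError("need spectra_by_run or features_by_run")
        features_by_run = deconvolve_runs(spectra_by_run, decon_params)

    per_run = _match_runs(features_by_run, library, identity_params)
    consensus = filter_replicates(list(per_run.values()), identity_params)
    call = call_serotype(consensus, library)
    logger.info(
        "identity call=%s consensus=%d flags=%d",
        call.serotype,
        len(consensus),
        len(call.false_positive_flags),
    )
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": _tool_version(),
        "method": "identity",
        "parameters": _params_snapshot(identity_params, decon_params),
        "runs": _runs_section(per_run, features_by_run),
        "consensus": sorted(consensus),
        "call": {
            "serotype": call.serotype,
            "qualifying": list(call.qualifying),
            "false_positive_flags": list(call.false_positive_flags),
            "evidence": {k: list(v) for k, v in call.evidence.items()},
        },
    }


def run_ptm_monitor(
    library: ComponentLibrary,
    serotype: str,
    spectra_by_run: Mapping[str, SpectrumSet] | None = None,
    features_by_run: Mapping[str, Sequence[DeconvolvedFeature]] | None = None,
    identity_params: IdentityParams = IdentityParams(),
    decon_params: DeconvolutionParams = DeconvolutionParams(),
) -> dict:
    """Serotype-specific PTM monitoring over the same deconvolved features.

    Matches every component of ``serotype`` (modified proteoforms included),
    reports masses, ppm errors and areas, and expresses each proteoform as a
    percentage of the summed area of all matched proteoforms of its VP.  XIC
    areas are used when raw spectra are supplied, otherwise the deconvolved
    feature areas.
    """
    if serotype not in library.entries:
        raise ValueError(f"serotype {serotype!r} not in library")
    sub = ComponentLibrary(
        entries={serotype: list(library.entries[serotype])},
        provenance=dict(library.provenance),
    )
    if features_by_run is None:
        if spectra_by_run is None:
            raise ValueError("need spectra_by_run or features_by_run")
        features_by_run = deconvolve_runs(spectra_by_run, decon_params)

    per_run = _match_runs(features_by_run, sub, identity_params)
    consensus = filter_replicates(list(per_run.values()), identity_params)

    # per-component areas averaged over runs
    areas: dict[str, list[float]] = {}
    observed: dict[str, list[float]] = {}
    for label, matches in consensus.items():
        comp = sub.find(label)
        for m in matches:
            if spectra_by_run is not None:
                zc = range(
                    decon_params.charge_range[0], decon_params.charge_range[1] + 1
                )
                xic = extract_xic(
                    spectra_by_run[m.replicate_id],
                    comp.theoretical_mass,
                    charges=zc,
                    tol_ppm=identity_params.mass_tol_ppm,
                )
                area = float(np.trapezoid(xic.intensity, xic.time))
            else:
                area = m.feature.area
            areas.setdefault(label, []).append(area)
            observed.setdefault(label, []).append(m.feature.neutral_mass)

    vp_totals: dict[str, float] = {}
    mean_area = {label: float(np.mean(v)) for label, v in areas.items()}
    for label, a in mean_area.items():
        vp = sub.find(label).base_vp
        vp_totals[vp] = vp_totals.get(vp, 0.0) + a

    proteoforms = []
    for label in sorted(consensus):
        comp = sub.find(label)
        obs = float(np.mean(observed[label]))
        total = vp_totals[comp.base_vp]
        proteoforms.append(
            {
                "component": label,
                "base_vp": comp.base_vp,
                "ptm_counts": dict(comp.ptm_counts),
                "theoretical_mass": round(comp.theoretical_mass, 2),
                "mean_observed_mass": round(obs, 2),
                "mean_ppm_error": round(
                    abs(obs - comp.theoretical_mass) / comp.theoretical_mass * 1e6, 1
                ),
                "mean_area": mean_area[label],
                "pct_of_vp": (
                    round(100.0 * mean_area[label] / total, 2) if total > 0 else 0.0
                ),
            }
        )

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": _tool_version(),
        "method": "ptm_monitor",
        "serotype": serotype,
        "parameters": _params_snapshot(identity_params, decon_params),
        "runs": _runs_section(per_run, features_by_run),
        "consensus": sorted(consensus),
        "proteoforms": proteoforms,
    }


def _tool_version() -> str:
    from . import __version__

    return __version__


def generate_report(results: Mapping, path, fmt: str = "json") -> None:
    """Serialize a report deterministically (stable key order, fixed layout).

    ``fmt`` is ``json`` or ``csv``; identical inputs produce byte-identical
    files.
    """
    path = str(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        rows = _flatten("", results)
        with open(path, "w", newline="") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["key", "value"])
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _flatten(prefix: str, obj) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    if isinstance(obj, Mapping):
        for key in sorted(obj):
            rows.extend(_flatten(f"{prefix}.{key}" if prefix else str(key), obj[key]))
    elif isinstance(obj, (list, tuple)):
        for i, item in enumerate(obj):
            rows.extend(_flatten(f"{prefix}[{i}]", item))
    else:
        rows.append((prefix, "" if obj is None else str(obj)))
    return rows
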