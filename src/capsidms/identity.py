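"""Component matching, replicate consensus and serotype calling.

Matching follows the quantitative-method contract: for every component in the
target list, the most intense deconvolved feature that lies inside the
component's retention-time window (a closed interval) and within the mass
tolerance is assigned to it.  A serotype is called only when its full
unmodified VP1/VP2/VP3 set survives the replicate consensus; any consensus
matches belonging to other serotypes are surfaced as false-positive flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .capsid_model import ComponentLibrary, ProteoformComponent
from .spectra import DeconvolvedFeature

__all__ = [
    "IdentityParams",
    "ComponentMatch",
    "IdentityCall",
    "match_components",
    "filter_replicates",
    "call_serotype",
]


@dataclass(frozen=True)
class IdentityParams:
    """Matching and consensus thresholds.

    ``mass_tol_ppm`` defaults to the 10 ppm deconvolution merge tolerance (no
    separate match tolerance is prescribed, so it is configurable and echoed
    in reports); RT windows default to the per-component values (+/-1.00 min
    VP3-class, +/-0.60 min VP1/VP2) unless overridden per VP name.
    """

    mass_tol_ppm: float = 10.0
    rt_window_overrides: Mapping[str, float] = field(default_factory=dict)
    min_score: float = 60.0
    require_all_replicates: bool = True

    def __post_init__(self) -> None:
        if self.mass_tol_ppm <= 0:
            raise ValueError("mass_tol_ppm must be > 0")
        if any(w <= 0 for w in self.rt_window_overrides.values()):
            raise ValueError("rt window overrides must be > 0")

    def window_for(self, component: ProteoformComponent) -> float:
        return self.rt_window_overrides.get(component.base_vp, component.rt_window)


@dataclass(frozen=True)
class ComponentMatch:
    """One component assigned to one deconvolved feature in one run."""

    component_label: str
    serotype: str
    base_vp: str
    feature: DeconvolvedFeature
    mass_error_ppm: float
    rt_offset: float
    replicate_id: str = ""
    shared_feature: bool = False


@dataclass(frozen=True)
class IdentityCall:
    """The serotype verdict with its supporting evidence."""

    serotype: str  # called serotype, or "none" / "ambiguous"
    evidence: Mapping[str, tuple[str, ...]]  # serotype -> matched core VP labels
    false_positive_flags: tuple[str, ...]  # consensus labels from other serotypes
    qualifying: tuple[str, ...] = ()  # serotypes whose full core set matched


def match_components(
    features: Sequence[DeconvolvedFeature],
    library: ComponentLibrary,
    params: IdentityParams = IdentityParams(),
    replicate_id: str = "",
) -> list[ComponentMatch]:
    """Assign features of one run to the component target list.

    For each component, candidate features must satisfy
    ``|rt - expected_rt| <= rt_window`` (closed) and
    ``|ppm error| <= mass_tol_ppm``; the highest-area candidate wins, with
    ties broken by smaller |mass error| then earlier RT.  A feature claimed by
    more than one component is flagged on every involved match.
    """
    components = library.all_components()
    if not components:
        raise ValueError("component library is empty")

    matches: list[ComponentMatch] = []
    feature_use: dict[int, list[int]] = {}
    for comp in components:
        window = params.window_for(comp)
        best: tuple[float, float, float, int] | None = None
        for fi, feat in enumerate(features):
            rt_off = feat.rt_apex - comp.expected_rt
            if abs(rt_off) > window:
                continue
            ppm = (
                (feat.neutral_mass - comp.theoretical_mass)
                / comp.theoretical_mass
                * 1e6
            )
            if abs(ppm) > params.mass_tol_ppm:
                continue
            key = (-feat.area, abs(ppm), feat.rt_apex, fi)
            if best is None or key < best:
                best = key
        if best is not None:
            fi = best[3]
            feat = features[fi]
            matches.append(
                ComponentMatch(
                    component_label=comp.label,
                    serotype=comp.serotype,
                    base_vp=comp.base_vp,
                    feature=feat,
                    mass_error_ppm=(
                        (feat.neutral_mass - comp.theoretical_mass)
                        / comp.theoretical_mass
                        * 1e6
                    ),
                    rt_offset=feat.rt_apex - comp.expected_rt,
                    replicate_id=replicate_id,
                )
            )
            feature_use.setdefault(fi, []).append(len(matches) - 1)

    for fi, idxs in feature_use.items():
        if len(idxs) > 1:
            for i in idxs:
                m = matches[i]
                matches[i] = ComponentMatch(
                    component_label=m.component_label,
                    serotype=m.serotype,
                    base_vp=m.base_vp,
                    feature=m.feature,
                    mass_error_ppm=m.mass_error_ppm,
                    rt_offset=m.rt_offset,
                    replicate_id=m.replicate_id,
                    shared_feature=True,
                )
    return matches


def filter_replicates(
    per_run_matches: Sequence[Sequence[ComponentMatch]],
    params: IdentityParams = IdentityParams(),
) -> dict[str, list[ComponentMatch]]:
    """Replicate consensus: keep a component only if it was matched in every
    run (under ``require_all_replicates``) with a feature score at or above
    ``min_score`` in each.  Returns label -> per-run matches."""
    if not per_run_matches:
        raise ValueError("need at least one run")
    by_label: dict[str, list[ComponentMatch]] = {}
    for run in per_run_matches:
        seen: dict[str, ComponentMatch] = {}
        for m in run:
            seen[m.component_label] = m
        for label, m in seen.items():
            by_label.setdefault(label, []).append(m)

    n_runs = len(per_run_matches)
    consensus: dict[str, list[ComponentMatch]] = {}
    for label, ms in by_label.items():
        if params.require_all_replicates and len(ms) < n_runs:
            continue
        if any(m.feature.score < params.min_score for m in ms):
            continue
        consensus[label] = ms
    return consensus


def call_serotype(
    consensus: Mapping[str, Sequence[ComponentMatch]] | Sequence[str],
    library: ComponentLibrary,
) -> IdentityCall:
    """Call the serotype from a consensus component set.

    A serotype qualifies when all of its unmodified VP1/VP2/VP3 components are
    present.  Exactly one qualifying serotype is called; zero yields ``none``
    and more than one yields ``ambiguous``.  Consensus components belonging to
    any other serotype are reported as false-positive flags.
    """
    labels = set(consensus)
    evidence: dict[str, tuple[str, ...]] = {}
    qualifying: list[str] = []
    for serotype in library.serotypes():
        core = library.core_labels(serotype)
        hit = tuple(sorted(core & labels))
        evidence[serotype] = hit
        if core and core <= labels:
            qualifying.append(serotype)

    if len(qualifying) == 1:
        called = qualifying[0]
    elif not qualifying:
        called = "none"
    else:
        called = "ambiguous"

    flags: list[str] = []
    if called not in ("none", "ambiguous"):
        for serotype, comps in library.entries.items():
            if serotype == called:
                continue
            flags.extend(sorted(labels & {c.label for c in comps}))

    return IdentityCall(
        serotype=called,
        evidence=evidence,
        false_positive_flags=tuple(flags),
        qualifying=tuple(qualifying),
    )
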