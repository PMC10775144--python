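"""Shared fixtures: toy serotype panels, libraries and simulated runs."""

from __future__ import annotations

import pytest

from capsidms.capsid_model import build_component_library
from capsidms.synth import (
    SimulatedSpecies,
    SimulationConfig,
    make_test_serotype,
    simulate_run,
)

PANEL_SEEDS = {"AAV2": 2, "AAV5": 5, "AAV8": 8, "AAV9": 9}

# universal RT layout: VP3 elutes first, then VP1, then VP2
PANEL_RTS = {"VP3": 16.0, "VP1": 20.0, "VP2": 22.0}

PANEL_ABUNDANCES = {"VP1": 2.0e5, "VP2": 1.5e5, "VP3": 1.0e6}


@pytest.fixture(scope="session")
def panel_definitions():
    return [
        make_test_serotype(name, seed=seed) for name, seed in PANEL_SEEDS.items()
    ]


@pytest.fixture(scope="session")
def panel_library(panel_definitions):
    specs = [("VP1", {}), ("VP2", {}), ("VP3", {})]
    return build_component_library(
        panel_definitions,
        proteoform_specs=specs,
        rt_calibration=PANEL_RTS,
    )


def simulate_serotype_runs(
    library,
    serotype: str,
    n_replicates: int = 3,
    base_seed: int = 100,
    scan_interval: float = 0.1,
    noise: bool = True,
):
    """Triplicate synthetic runs of one serotype against the panel layout."""
    species = tuple(
        SimulatedSpecies(
            label=c.label,
            base_vp=c.base_vp,
            mass=c.theoretical_mass,
            rt_apex=c.expected_rt,
            abundance=PANEL_ABUNDANCES[c.base_vp],
        )
        for c in library.entries[serotype]
    )
    runs = {}
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            species=species,
            seed=base_seed + rep,
            scan_interval=scan_interval,
            n_noise_peaks=20 if noise else 0,
            noise_peak_intensity=500.0,
            intensity_jitter=0.02 if noise else 0.0,
        )
        runs[f"{serotype}_rep{rep + 1}"] = simulate_run(cfg)
    return runs
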