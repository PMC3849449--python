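"""Shared fixtures: the base-case lobule model and cached scenario runs.

Scenario runs are the expensive part of the suite (each integrates
~1e5 explicit transport steps), so every scenario is computed once per
session and shared between the unit, property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import lobuleflow as lf

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

INJECTED = 1.8e-8  # base-case drug mole fraction in the inflow


@pytest.fixture(scope="session")
def lattice():
    return lf.build_lattice()


@pytest.fixture(scope="session")
def fluid():
    return lf.FluidProperties()


@pytest.fixture(scope="session")
def wells():
    return lf.BoundaryWells()


@pytest.fixture(scope="session")
def flow(lattice, fluid, wells):
    return lf.solve_steady_pressure(lattice, fluid, wells)


def _run(lattice, fluid, wells, flow, *, diffusion, reaction, mult=1.0,
         injected=INJECTED, end_time=1.0):
    scenario = lf.ScenarioConfig(
        diffusion_enabled=diffusion,
        reaction_enabled=reaction,
        rate_multiplier=mult,
        injected_pac=injected,
        end_time=end_time,
        snapshot_times=(),
    )
    return lf.run_scenario(lattice, fluid, wells, scenario=scenario, flow=flow)


@pytest.fixture(scope="session")
def nonreactive(lattice, fluid, wells, flow):
    """Non-reactive tracer, diffusion on (breakthrough base case)."""
    return _run(lattice, fluid, wells, flow, diffusion=True, reaction=False)


@pytest.fixture(scope="session")
def nonreactive_nodiff(lattice, fluid, wells, flow):
    return _run(lattice, fluid, wells, flow, diffusion=False, reaction=False)


@pytest.fixture(scope="session")
def reactive_base(lattice, fluid, wells, flow):
    return _run(lattice, fluid, wells, flow, diffusion=True, reaction=True)


@pytest.fixture(scope="session")
def reactive_base_nodiff(lattice, fluid, wells, flow):
    return _run(lattice, fluid, wells, flow, diffusion=False, reaction=True)


@pytest.fixture(scope="session")
def reactive_100x(lattice, fluid, wells, flow):
    return _run(lattice, fluid, wells, flow, diffusion=True, reaction=True, mult=1e-2)


@pytest.fixture(scope="session")
def reactive_1000x(lattice, fluid, wells, flow):
    return _run(lattice, fluid, wells, flow, diffusion=True, reaction=True, mult=1e-3)


@pytest.fixture(scope="session")
def concentration_sweep(lattice, fluid, wells, flow):
    """Reactive, no diffusion, three injected levels spanning the
    linear → saturated Michaelis–Menten regimes."""
    levels = (1.8e-8, 1.8e-7, 1.8e-6)
    return {
        level: _run(lattice, fluid, wells, flow, diffusion=False, reaction=True,
                    injected=level, end_time=0.6)
        for level in levels
    }


def interp_onto(times, other_times, other_values):
    return np.interp(times, other_times, other_values)
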