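"""Reactive transport: kinetics, stepping invariants, mole accounting."""

import numpy as np
import pytest

import lobuleflow as lf
from lobuleflow.transport import TransportSimulator, _mm_exact_decay

from conftest import INJECTED


class TestMichaelisMentenRate:
    def test_half_saturation(self):
        r = lf.ReactionSpec()
        assert lf.michaelis_menten_rate(r.K_m, r) == pytest.approx(
            r.v_max_effective / 2.0, rel=1e-12
        )

    def test_linear_limit_matches_effective_rate(self):
        r = lf.ReactionSpec()
        x = r.K_m * 1e-4
        k_lin = lf.michaelis_menten_rate(x, r) / x
        k_eff = r.v_max_effective / r.K_m
        assert k_lin == pytest.approx(k_eff, rel=2e-4)

    def test_base_injection_level_scalar_oracle(self):
        r = lf.ReactionSpec()
        x = 1.8e-8
        by_hand = (1.08e-9 / 0.76e-6) * x / (1.8e-7 + x)
        assert lf.michaelis_menten_rate(x, r) == pytest.approx(by_hand, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lf.michaelis_menten_rate(-1e-9, lf.ReactionSpec())

    def test_exact_decay_matches_quadrature(self):
        """Lambert-W closed form vs an independent fine-step RK4 integration."""
        r = lf.ReactionSpec()
        v, km = r.v_max_effective, r.K_m
        for x0 in (1.8e-8, 1.8e-7, 1.8e-6):
            x = x0
            dt_total = 2e-4
            nsub = 4000
            h = dt_total / nsub
            f = lambda y: -v * y / (km + y)
            for _ in range(nsub):
                k1 = f(x); k2 = f(x + h / 2 * k1)
                k3 = f(x + h / 2 * k2); k4 = f(x + h * k3)
                x += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            closed = _mm_exact_decay(np.array([x0]), v, km, dt_total)[0]
            assert closed == pytest.approx(x, rel=1e-8)


@pytest.fixture()
def still_flow(lattice, wells):
    """A quiescent 'flow' (zero fluxes, zero well rates)."""
    n = lattice.n
    return lf.PressureSolution(
        pressure=np.full((n, n), 101.8),
        flux_x=np.zeros((n, n - 1)),
        flux_y=np.zeros((n - 1, n)),
        inlet_rate=0.0, outlet_rate=0.0, wells=wells,
    )


class TestAdvance:
    def test_quiescent_state_unchanged(self, lattice, fluid, wells, still_flow):
        sc = lf.ScenarioConfig(diffusion_enabled=False, reaction_enabled=False,
                               end_time=1.0, snapshot_times=())
        sim = TransportSimulator(lattice, fluid, wells, scenario=sc, flow=still_flow)
        sim.state.mole_fraction["PAC"][:] = 1e-8
        before = sim.state.mole_fraction["PAC"].copy()
        sim.advance(1e-3)
        np.testing.assert_array_equal(sim.state.mole_fraction["PAC"], before)

    def test_uniform_composition_preserved(self, lattice, fluid, flow):
        # injecting at the resident level keeps the field exactly uniform
        x0 = 2.5e-8
        wells_u = lf.BoundaryWells(injector_composition={"PAC": x0})
        sc = lf.ScenarioConfig(diffusion_enabled=True, reaction_enabled=False,
                               injected_pac=x0, end_time=1.0, snapshot_times=())
        sim = TransportSimulator(lattice, fluid, wells_u, scenario=sc, flow=flow)
        sim.state.mole_fraction["PAC"][:] = x0
        sim.advance(100 * sim.dt_max)
        field = sim.state.mole_fraction["PAC"]
        # row sums of the discrete operator vanish only to roundoff, which
        # accumulates linearly over the 100 steps
        assert np.abs(field - x0).max() < 1e-9 * x0

    def test_single_step_mole_accounting(self, lattice, fluid, wells, flow):
        sc = lf.ScenarioConfig(diffusion_enabled=True, reaction_enabled=True,
                               end_time=1.0, snapshot_times=())
        sim = TransportSimulator(lattice, fluid, wells, scenario=sc, flow=flow)
        sim.advance(sim.dt_max)
        sim.advance(5 * sim.dt_max)
        assert sim.mass_balance_error() < 1e-10

    def test_substepping_respects_stability_cap(self, lattice, fluid, wells, flow):
        sc = lf.ScenarioConfig(diffusion_enabled=True, reaction_enabled=False,
                               end_time=1.0, snapshot_times=())
        sim = TransportSimulator(lattice, fluid, wells, scenario=sc, flow=flow)
        sim.advance(0.01)  # ≫ dt_max, must sub-step internally
        x = sim.state.mole_fraction["PAC"]
        assert np.isfinite(x).all()
        assert x.min() >= -1e-20
        assert x.max() <= sc.injected_pac * (1 + 1e-9)

    def test_invalid_dt_rejected(self, lattice, fluid, wells, flow):
        sc = lf.ScenarioConfig(snapshot_times=())
        sim = TransportSimulator(lattice, fluid, wells, scenario=sc, flow=flow)
        with pytest.raises(ValueError):
            sim.advance(0.0)


class TestScenarioRuns:
    def test_effluent_monotone_and_bounded_nonreactive(self, nonreactive):
        eff = nonreactive.effluent
        assert (np.diff(eff.drug) >= -1e-16).all()
        assert eff.drug.max() <= INJECTED * (1 + 1e-9)
        assert (eff.metabolite == 0).all()

    def test_fields_bounded_by_injected_level(self, nonreactive):
        x = nonreactive.simulator.state.mole_fraction["PAC"]
        assert x.min() >= 0.0
        assert x.max() <= INJECTED * (1 + 1e-9)

    def test_mole_conservation_all_scenarios(
        self, nonreactive, nonreactive_nodiff, reactive_base,
        reactive_base_nodiff, reactive_100x, reactive_1000x,
    ):
        for res in (nonreactive, nonreactive_nodiff, reactive_base,
                    reactive_base_nodiff, reactive_100x, reactive_1000x):
            assert res.mass_balance_error < 1e-8

    def test_reaction_confined_to_tissue(self, lattice, fluid, wells, still_flow):
        # quiescent fluid + uniform drug: only hepatocyte cells convert
        sc = lf.ScenarioConfig(diffusion_enabled=False, reaction_enabled=True,
                               end_time=1.0, snapshot_times=())
        sim = TransportSimulator(lattice, fluid, wells, scenario=sc, flow=still_flow)
        x0 = 1.8e-8
        sim.state.mole_fraction["PAC"][:] = x0
        sim.advance(1e-5)
        pac = sim.state.mole_fraction["PAC"]
        pacoh = sim.state.mole_fraction["PAC-OH"]
        tis = lattice.tissue_mask
        assert (pac[tis] < x0).all()
        np.testing.assert_array_equal(pac[~tis], x0)
        np.testing.assert_array_equal(pacoh[~tis], 0.0)
        # stoichiometry 1:1 cell by cell
        np.testing.assert_allclose(pac + pacoh, x0, rtol=1e-12)

    def test_snapshots_recorded_at_requested_times(self, lattice, fluid, wells, flow):
        sc = lf.ScenarioConfig(diffusion_enabled=False, reaction_enabled=False,
                               end_time=2e-3, snapshot_times=(5e-4, 1e-3))
        res = lf.run_scenario(lattice, fluid, wells, scenario=sc, flow=flow)
        assert set(res.snapshots) == {5e-4, 1e-3}
        for fields in res.snapshots.values():
            assert set(fields) == {"PAC", "PAC-OH"}

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            lf.ScenarioConfig(end_time=-1.0).validate()
        with pytest.raises(ValueError):
            lf.ScenarioConfig(end_time=0.1, snapshot_times=(0.5,)).validate()

    def test_half_rise_interpolation(self, nonreactive):
        t_half = nonreactive.effluent.half_rise_time(INJECTED)
        eff = nonreactive.effluent
        k = np.searchsorted(eff.times, t_half)
        assert eff.drug[max(k - 1, 0)] <= INJECTED / 2 <= eff.drug[min(k + 1, len(eff.drug) - 1)]
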