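"""Deterministic ODE limit: right-hand side, integration, steady states."""

import numpy as np
import pytest

from protocrm.core import ChemicalSystem, Ecology, FeedSchedule
from protocrm.deterministic import (ReactorState, crm_rhs, integrate,
                                    steady_state)

from conftest import make_type


def single_nutrient_system(feed=200.0, mu=0.1):
    return ChemicalSystem(np.array([1.0]), FeedSchedule.constant([feed]), mu)


class TestRhs:
    def test_feed_equilibrium_without_protocells(self, chem4, config):
        eco = Ecology(chem4, [], initial_counts=[])
        state = ReactorState(0.0, np.array([200.0, 200, 0, 0]), {}, {})
        d = crm_rhs(state, eco, config)
        np.testing.assert_allclose(d.concentrations, 0.0, atol=1e-12)

    def test_population_growth_sign_follows_net_value(self, chem4, config):
        eco = Ecology(chem4, [make_type()], initial_counts=[100])
        state = ReactorState.initial(eco, populations={0: 2.0})
        d = crm_rhs(state, eco, config)
        # at feed-level concentrations the type is strongly viable
        lam = 60.0 * (200.0 / 201.0) * 0.8 - 10.0 - 6.0
        assert d.populations[0] == pytest.approx(2.0 * (config.g * lam - 0.1),
                                                 rel=1e-9)
        assert d.populations[0] > 0

    def test_cross_feeding_byproduct_flux(self, config):
        """With a producer eating chemical 0 and excreting chemical 2, the
        by-product inflow to c2 is p0 * E00 * c0/(1+c0) * M[0->2]."""
        chem = ChemicalSystem(np.array([1.0, 1.0, 0.5, 0.5]),
                              FeedSchedule.constant([200.0, 200, 0, 0]), 0.1)
        producer = make_type(type_id=0, diet=(0,), byproducts=(2,),
                             weights=[[0.6]], enzymes=(30.0,))
        consumer = make_type(type_id=1, diet=(1, 2), byproducts=(3,),
                             weights=[[0.3], [0.3]], enzymes=(30.0, 30.0))
        eco = Ecology(chem, [producer, consumer], initial_counts=[100, 100])
        c = np.array([200.0, 200.0, 0.0, 0.0])
        state = ReactorState(0.0, c, {0: 2.0, 1: 2.0},
                             {0: producer.enzymes, 1: consumer.enzymes})
        d = crm_rhs(state, eco, config)
        expected_c2 = 2.0 * 30.0 * (200.0 / 201.0) * 0.6  # production only
        assert d.concentrations[2] == pytest.approx(expected_c2, rel=1e-12)

    def test_enzymes_constant_without_regulation(self, chem4, config):
        eco = Ecology(chem4, [make_type()], initial_counts=[100])
        traj = integrate(ReactorState.initial(eco), eco, config, 200.0,
                         dt_out=50.0)
        E = traj.enzymes(0)
        np.testing.assert_allclose(E, np.broadcast_to(E[0], E.shape),
                                   rtol=0, atol=1e-12)


class TestIntegrate:
    def test_washout_when_dilution_exceeds_growth(self, config):
        # mu far above g * lambda_max: population must decay ~exp(-mu t)
        chem = ChemicalSystem(np.array([1.0]), FeedSchedule.constant([200.0]),
                              5.0)
        t = make_type(diet=(0,), byproducts=(), weights=np.zeros((1, 0)),
                      enzymes=(60.0,))
        eco = Ecology(chem, [t], initial_counts=[100])
        tau_end = 10.0  # >> 1/mu
        traj = integrate(ReactorState.initial(eco, populations={0: 1.0}),
                         eco, config, tau_end, dt_out=1.0)
        assert traj.population(0)[-1] < 1e-6

    def test_competitive_exclusion_on_shared_nutrient(self, config):
        """Two non-cross-feeding types on one nutrient: the one with lower
        net growth value at the attractor is excluded."""
        chem = single_nutrient_system()
        strong = make_type(type_id=0, diet=(0,), byproducts=(),
                           weights=np.zeros((1, 0)), enzymes=(40.0,))
        weak = make_type(type_id=1, diet=(0,), byproducts=(),
                         weights=np.zeros((1, 0)), enzymes=(30.0,))
        eco = Ecology(chem, [strong, weak], initial_counts=[100, 100])
        traj = integrate(ReactorState.initial(
            eco, populations={0: 1.0, 1: 1.0}), eco, config, 400.0,
            dt_out=40.0)
        share = traj.population(1) / (traj.population(0) + traj.population(1))
        assert share[-1] < 1e-3
        assert traj.population(0)[-1] > 0.1

    def test_value_conservation_along_trajectory(self, chem4, config):
        """Total growth-value inflow into every metabolism strictly exceeds
        its by-product value outflow whenever it is feeding (delta_v > 0)."""
        eco = Ecology(chem4, [make_type()], initial_counts=[100])
        traj = integrate(ReactorState.initial(eco, populations={0: 2.0}),
                         eco, config, 300.0, dt_out=10.0)
        gv = chem4.growth_values
        t = eco.types[0]
        for k in range(traj.n_samples):
            c = traj.chemicals[k]
            s = c[[0, 1]] / (1.0 + c[[0, 1]])
            uptake = t.enzymes * s
            inflow = float(uptake @ gv[[0, 1]])
            outflow = float((uptake @ t.metabolism.weights) @ gv[[2, 3]])
            if inflow > 0:
                assert inflow > outflow


class TestSteadyState:
    def test_empty_ecology_sits_at_feed(self, chem4, config):
        eco = Ecology(chem4, [], initial_counts=[])
        state, info = steady_state(eco, config)
        np.testing.assert_allclose(state.concentrations, [200.0, 200, 0, 0])

    def test_equilibrium_growth_balances_dilution(self, chem4, config):
        """At a populated equilibrium each surviving type has lambda = mu/g."""
        from protocrm.core import net_growth_value
        eco = Ecology(chem4, [make_type()], initial_counts=[100])
        state, info = steady_state(eco, config)
        assert state is not None, info
        t = eco.types[0].copy()
        t.bind_chemistry(chem4)
        lam = net_growth_value(t, state.concentrations)
        assert lam == pytest.approx(chem4.dilution_rate / config.g, abs=1e-6)
        assert state.populations[0] > 0

    def test_infeasible_dilution_reports_extinction(self, config):
        chem = ChemicalSystem(np.array([1.0]), FeedSchedule.constant([200.0]),
                              5.0)
        t = make_type(diet=(0,), byproducts=(), weights=np.zeros((1, 0)),
                      enzymes=(60.0,))
        eco = Ecology(chem, [t], initial_counts=[100])
        state, info = steady_state(eco, config, pre_tau=20.0)
        assert state is None
        assert "extinct" in info["diagnosis"]


class TestMacArthurOracle:
    def test_matches_reference_crm_two_species_two_resources(self, config):
        """With regulation disabled the model is a classical MacArthur
        consumer-resource system; an independent transcription of those
        equations must reproduce the trajectory."""
        from scipy.integrate import solve_ivp

        chem = ChemicalSystem(np.array([1.0, 1.0]),
                              FeedSchedule.constant([150.0, 90.0]), 0.1)
        tA = make_type(type_id=0, diet=(0, 1), byproducts=(),
                       weights=np.zeros((2, 0)), enzymes=(40.0, 20.0))
        tB = make_type(type_id=1, diet=(0, 1), byproducts=(),
                       weights=np.zeros((2, 0)), enzymes=(15.0, 45.0))
        eco = Ecology(chem, [tA, tB], initial_counts=[100, 100])
        tau_end, dt_out = 150.0, 5.0
        traj = integrate(ReactorState.initial(
            eco, populations={0: 1.0, 1: 0.5}), eco, config, tau_end,
            dt_out=dt_out, rtol=1e-10, atol=1e-12)

        # independent reference: straight transcription of the CRM equations
        mu, g, R, e = 0.1, config.g, 10.0, 0.1
        EA, EB = np.array([40.0, 20.0]), np.array([15.0, 45.0])
        f = np.array([150.0, 90.0])

        def rhs(_, y):
            c, pA, pB = y[:2], y[2], y[3]
            s = c / (1.0 + c)
            lamA = EA @ s - R - e * EA.sum()
            lamB = EB @ s - R - e * EB.sum()
            dc = mu * (f - c) - pA * EA * s - pB * EB * s
            return [*dc, pA * (g * lamA - mu), pB * (g * lamB - mu)]

        sol = solve_ivp(rhs, (0, tau_end), [150.0, 90.0, 1.0, 0.5],
                        t_eval=np.arange(0, tau_end + 1e-9, dt_out),
                        rtol=1e-10, atol=1e-12, method="LSODA")
        ours = np.column_stack([traj.chemicals,
                                traj.population(0), traj.population(1)])
        ref = sol.y.T
        scale = np.maximum(np.abs(ref), 1e-3)
        assert np.max(np.abs(ours - ref) / scale) < 1e-6
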