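"""Integration correctness, observables, and robustness of the simulator."""

import numpy as np
import pytest

from lckphos.params import RateParameterSet
from lckphos.simulate import (
    Condition,
    TrajectorySet,
    fraction_doubly_phosphorylated,
    observables,
    simulate,
    standard_conditions,
)

from conftest import uniform_params


GRID_S = np.array([0, 0.25, 0.5, 1, 2, 5, 10, 15, 30, 45, 60, 90]) * 60.0


class TestSimulate:
    def test_zero_catalysis_gives_zero_phospho(self, active_network):
        p = uniform_params(1.0).replace(
            **{f"k_cat_{i}": 0.0 for i in range(1, 17)}
        ).replace(k_cat_csk_uu=0.0, k_cat_csk_pu=0.0)
        traj = simulate(active_network, p, standard_conditions()["high_lck_csk"],
                        output_times=GRID_S, rtol=1e-8, atol=1e-12)
        obs = observables(traj)
        np.testing.assert_allclose(obs.phospho_y394, 0.0, atol=1e-9)
        np.testing.assert_allclose(obs.phospho_y505, 0.0, atol=1e-9)

    @pytest.mark.parametrize("label", ["high_lck", "low_lck_csk", "validation"])
    def test_conserved_totals_along_trajectory(
        self, label, active_network, validation_network, median_params
    ):
        cond = standard_conditions()[label]
        net = validation_network if cond.dead_lck_density > 0 else active_network
        traj = simulate(net, median_params, cond, output_times=GRID_S)
        assert traj.conserved_residual() < 1e-6

    def test_integration_succeeds_for_all_standard_conditions(
        self, active_network, validation_network, median_params
    ):
        for cond in standard_conditions().values():
            net = validation_network if cond.dead_lck_density > 0 else active_network
            simulate(net, median_params, cond, output_times=GRID_S)

    def test_initial_phospho_y505_pool(self, active_network, median_params):
        cond = Condition(500.0, 0.0, initial_phospho_y505_fraction=0.015,
                         label="contaminated")
        traj = simulate(active_network, median_params, cond, output_times=GRID_S)
        obs = observables(traj)
        assert obs.phospho_y505[0] == pytest.approx(0.015, rel=1e-6)

    def test_tolerance_convergence(self, active_network, median_params):
        """Tightening integrator tolerances 10x barely moves the observables."""
        cond = standard_conditions()["high_lck_csk"]
        o1 = observables(simulate(active_network, median_params, cond,
                                  output_times=GRID_S, rtol=1e-8, atol=1e-12))
        o2 = observables(simulate(active_network, median_params, cond,
                                  output_times=GRID_S, rtol=1e-9, atol=1e-13))
        assert np.max(np.abs(o1.phospho_y394 - o2.phospho_y394)) < 1e-4
        assert np.max(np.abs(o1.phospho_y505 - o2.phospho_y505)) < 1e-4


class TestObservables:
    def _all_pp_trajectory(self, net):
        dens = np.zeros((2, len(net.species)))
        dens[:, net.index["PP"]] = 123.0
        return TrajectorySet(np.array([0.0, 5400.0]), dens,
                             Condition(123.0, 0.0), net)

    def test_fully_phosphorylated_state_normalizes_to_one(self, active_network):
        obs = observables(self._all_pp_trajectory(active_network))
        np.testing.assert_allclose(obs.phospho_y394, 1.0)
        np.testing.assert_allclose(obs.phospho_y505, 1.0)
        assert fraction_doubly_phosphorylated(
            self._all_pp_trajectory(active_network), 5400.0
        ) == pytest.approx(1.0)

    def test_doubly_phosphorylated_fraction_starts_at_zero(
        self, active_network, median_params
    ):
        traj = simulate(active_network, median_params,
                        standard_conditions()["high_lck"], output_times=GRID_S)
        assert fraction_doubly_phosphorylated(traj, 0.0) == 0.0

    def test_species_fractions_partition_total_lck(
        self, active_network, median_params
    ):
        traj = simulate(active_network, median_params,
                        standard_conditions()["high_lck_csk"], output_times=GRID_S)
        obs = observables(traj)
        total = sum(obs.species_fractions[f]["total"] for f in ("UU", "PU", "UP", "PP"))
        np.testing.assert_allclose(total, 1.0, atol=1e-6)
        for form in ("UU", "PU", "UP", "PP"):
            fr = obs.species_fractions[form]
            np.testing.assert_allclose(fr["free"] + fr["bound"], fr["total"],
                                       atol=1e-9)

    def test_site_90min_normalization_anchors_at_one(
        self, active_network, median_params
    ):
        traj = simulate(active_network, median_params,
                        standard_conditions()["high_lck"], output_times=GRID_S)
        obs = observables(traj, normalization="site_90min")
        assert obs.phospho_y394[-1] == pytest.approx(1.0)
        assert obs.phospho_y505[-1] == pytest.approx(1.0)

    def test_zero_normalizer_raises(self, active_network):
        p = uniform_params(1.0).replace(
            **{f"k_cat_{i}": 0.0 for i in range(1, 17)}
        ).replace(k_cat_csk_uu=0.0, k_cat_csk_pu=0.0)
        traj = simulate(active_network, p, standard_conditions()["high_lck"],
                        output_times=GRID_S)
        with pytest.raises(ValueError):
            observables(traj, normalization="site_90min")


class TestQuasiSteadyState:
    def test_reduced_condition_matches_michaelis_menten_velocity(
        self, active_network
    ):
        """With E << S and fast binding equilibration, the initial product
        formation rate approaches k_cat*E*S/(K_M + S)."""
        kon, koff, kcat = 1e-2, 10.0, 0.05
        p = uniform_params(0.0).replace(
            k_on=kon,
            **{f"k_off_{i}": 1e9 for i in range(1, 17)},
            k_off_csk_uu=1e9, k_off_csk_pu=1e9,
        ).replace(k_off_6=koff, k_cat_6=kcat)
        E0, S0 = 2.0, 500.0
        from lckphos.network import build_rhs
        from scipy.integrate import solve_ivp

        rhs = build_rhs(active_network, p)
        y0 = np.zeros(23)
        y0[active_network.index["UU"]] = E0
        y0[active_network.index["UP"]] = S0
        t_eval = np.linspace(0, 10, 21)
        sol = solve_ivp(rhs, (0, 10), y0, t_eval=t_eval, jac=rhs.jac,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        pp = sol.y[active_network.index["PP"]]
        v = (np.interp(6, t_eval, pp) - np.interp(2, t_eval, pp)) / 4.0
        KM = (koff + kcat) / kon
        v_qss = kcat * E0 * S0 / (KM + S0)
        assert v == pytest.approx(v_qss, rel=0.05)


class TestEnsembleEnvelope:
    def test_median_curve_within_perturbed_ensemble_band(
        self, active_network, median_params
    ):
        """The median-parameter curve stays inside the pointwise 50% band of
        an ensemble of log-perturbed rate sets (0.3 dex spread), mirroring
        the robustness of the fitted ensemble.  Tolerance covers band
        collapse where every curve saturates."""
        rng = np.random.default_rng(7)
        times = np.array([0, 0.5, 2, 5, 15, 30, 60, 90]) * 60.0
        cond = standard_conditions()["high_lck"]
        curves394, curves505 = [], []
        for _ in range(20):
            vec = median_params.to_vector() * 10 ** rng.normal(0, 0.3, 38)
            p = RateParameterSet.from_vector(vec)
            o = observables(simulate(active_network, p, cond, output_times=times,
                                     rtol=1e-6, atol=1e-10))
            curves394.append(o.phospho_y394)
            curves505.append(o.phospho_y505)
        om = observables(simulate(active_network, median_params, cond,
                                  output_times=times, rtol=1e-6, atol=1e-10))
        for ensemble, med in (
            (np.array(curves394), om.phospho_y394),
            (np.array(curves505), om.phospho_y505),
        ):
            lo = np.percentile(ensemble, 25, axis=0)
            hi = np.percentile(ensemble, 75, axis=0)
            assert np.all(med >= lo - 0.01)
            assert np.all(med <= hi + 0.01)


class TestConditionValidation:
    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            Condition(-1.0, 0.0)

    def test_dead_condition_requires_dead_network(
        self, active_network, median_params
    ):
        with pytest.raises(ValueError):
            simulate(active_network, median_params,
                     standard_conditions()["validation"], output_times=GRID_S)
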