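"""Calibration machinery: AIC model selection, RMSE, the penalized cost,
parameter recovery, topology discrimination and coupling estimation."""

import math

import numpy as np
import pytest

import phenoswitch as ps
from phenoswitch.calibration import PSM1DCostFunction
from phenoswitch.params import CouplingParams, ProliferationParams, Topology
from dataclasses import replace


# ---------------------------------------------------------------------------
# AIC and RMSE


def test_aic_values_and_nesting_penalty():
    assert ps.aic(10.0, 2, 10) == pytest.approx(4.0)       # ln(1) = 0
    assert ps.aic(5.0, 3, 20) - ps.aic(5.0, 2, 20) == pytest.approx(2.0)
    with pytest.warns(RuntimeWarning):
        assert ps.aic(0.0, 2, 10) == -math.inf
    with pytest.raises(ValueError):
        ps.aic(1.0, 2, 0)


def test_rmse_values():
    assert ps.rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert ps.rmse([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)
    assert ps.rmse([10, 20, 30], [12, 18, 33]) \
        == pytest.approx(math.sqrt(17 / 3), abs=1e-3)      # ~2.380
    with pytest.raises(ValueError):
        ps.rmse([1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# proliferation-law fitting and model selection


def test_noiseless_hill_self_consistency():
    pr = ProliferationParams(beta=0.035, n=2.5)
    ctrl = ps.generate_control_growth([2.0, 10.0], pr,
                                      np.arange(0.0, 169.0, 24.0),
                                      ps.NoiseModel(sigma=0.0), seed=0,
                                      replicates=1)
    fit = ps.fit_proliferation(ctrl, candidates=["hill"])
    rec = fit.best("per_seeding")
    assert rec.RSS < 1e-6
    theta = fit.thetas[("hill", "per_seeding")][2.0]
    assert theta[0] == pytest.approx(0.035, rel=0.01)
    assert theta[1] == pytest.approx(2.5, rel=0.01)


def test_logistic_data_selects_logistic_by_mean_aic():
    pr = ProliferationParams(model_id="logistic", beta=0.04)
    ctrl = ps.generate_control_growth([1.0, 5.0, 10.0, 20.0], pr,
                                      np.arange(0.0, 169.0, 24.0),
                                      ps.NoiseModel(sigma=0.5), seed=2,
                                      replicates=3)
    fit = ps.fit_proliferation(ctrl)
    assert fit.best("shared").model_id == "logistic"


def test_exponential_logistic_near_identifiable_at_low_density():
    """Far below carrying capacity the two laws fit equally well."""
    pr = ProliferationParams(model_id="exponential", beta=0.02)
    ctrl = ps.generate_control_growth([0.5, 1.0], pr,
                                      np.arange(0.0, 73.0, 24.0),
                                      ps.NoiseModel(sigma=0.2), seed=4,
                                      replicates=3)
    fit = ps.fit_proliferation(ctrl, candidates=["exponential", "logistic"])
    aics = {r.model_id: r.mean_AIC for r in fit.records
            if r.regime == "shared"}
    assert abs(aics["exponential"] - aics["logistic"]) < 2.0


def test_per_seeding_regime_never_fits_worse():
    pr = ProliferationParams(beta=0.04, n=2.0)
    ctrl = ps.generate_control_growth([1.0, 10.0, 20.0], pr,
                                      np.arange(0.0, 169.0, 24.0),
                                      ps.NoiseModel(sigma=1.0), seed=6,
                                      replicates=2)
    fit = ps.fit_proliferation(ctrl)
    for model_id in ("hill", "logistic"):
        recs = {r.regime: r for r in fit.records if r.model_id == model_id}
        assert recs["per_seeding"].RSS <= recs["shared"].RSS + 1e-9


# ---------------------------------------------------------------------------
# penalized cost


@pytest.fixture(scope="module")
def cost_A(noiseless_data_A, params_A):
    return PSM1DCostFunction(noiseless_data_A, params_A.topology,
                             params_A.prolif, params_A.drug)


def test_cost_vanishes_at_generating_parameters(cost_A, truth_theta_A):
    theta = np.array([truth_theta_A[n] for n in cost_A.names])
    assert cost_A(theta) < 1e-8


def test_bound_penalty_is_exterior(cost_A, truth_theta_A):
    theta = np.array([truth_theta_A[n] for n in cost_A.names])
    at_edge = theta.copy()
    at_edge[0] = cost_A.lower[0]                  # on the bound: no penalty
    assert cost_A._penalty(at_edge) == 0.0
    outside = theta.copy()
    outside[0] = cost_A.lower[0] - 0.01
    assert cost_A._penalty(outside) > 0.0


def test_doubling_weights_doubles_data_term(noiseless_data_A, params_A,
                                            truth_theta_A):
    c1 = PSM1DCostFunction(noiseless_data_A, params_A.topology,
                           params_A.prolif, params_A.drug)
    c2 = PSM1DCostFunction(noiseless_data_A, params_A.topology,
                           params_A.prolif, params_A.drug,
                           weights={r: 2.0 for r in noiseless_data_A.regimens()})
    theta = np.array([truth_theta_A[n] * 1.3 for n in c1.names])
    assert c2(theta) == pytest.approx(2.0 * c1(theta), rel=1e-9)


def test_cost_invariant_to_row_order(noiseless_data_A, params_A,
                                     truth_theta_A):
    shuffled = ps.ObservationSet(
        noiseless_data_A.data.sample(frac=1.0, random_state=1)
        .reset_index(drop=True),
        noiseless_data_A.provenance)
    c1 = PSM1DCostFunction(noiseless_data_A, params_A.topology,
                           params_A.prolif, params_A.drug)
    c2 = PSM1DCostFunction(shuffled, params_A.topology, params_A.prolif,
                           params_A.drug)
    theta = np.array([truth_theta_A[n] * 0.7 for n in c1.names])
    assert c1(theta) == pytest.approx(c2(theta), rel=1e-12)


# ---------------------------------------------------------------------------
# calibration


def test_noiseless_recovery_full_topology(noiseless_data_A, params_A,
                                          truth_theta_A):
    res = ps.calibrate_psm1d(noiseless_data_A, params_A.topology,
                             params_A.prolif, params_A.drug,
                             n_starts=2, seed=1)
    for name, fitted in res.theta.items():
        assert fitted == pytest.approx(truth_theta_A[name], rel=0.05), name
    assert res.cost < 1e-8
    assert max(res.rmse_per_regimen.values()) < 1e-4
    lo = np.array([res.bounds[n][0] for n in res.theta])
    hi = np.array([res.bounds[n][1] for n in res.theta])
    vals = np.array(list(res.theta.values()))
    assert np.all(vals >= lo) and np.all(vals <= hi)


def test_calibration_reproducible_given_seed(noiseless_data_A, params_A):
    kw = dict(n_starts=2, seed=9)
    r1 = ps.calibrate_psm1d(noiseless_data_A, params_A.topology,
                            params_A.prolif, params_A.drug, **kw)
    r2 = ps.calibrate_psm1d(noiseless_data_A, params_A.topology,
                            params_A.prolif, params_A.drug, **kw)
    assert r1.theta == r2.theta and r1.cost == r2.cost


def test_null_topology_fits_drug_modulated_data_worse(noiseless_data_A,
                                                      params_A):
    gen = ps.calibrate_psm1d(noiseless_data_A, params_A.topology,
                             params_A.prolif, params_A.drug,
                             n_starts=2, seed=3)
    null = ps.calibrate_psm1d(noiseless_data_A, Topology.from_index(1),
                              params_A.prolif, params_A.drug,
                              n_starts=2, seed=3)
    assert null.mean_rmse > gen.mean_rmse + 0.1


def test_noisy_recovery_of_rate_ratio(params_A):
    data = ps.generate_regimen_data(params_A, noise=ps.NoiseModel(sigma=1.0),
                                    seed=17, replicates=3)
    res = ps.calibrate_psm1d(data, params_A.topology, params_A.prolif,
                             params_A.drug, n_starts=3, seed=5)
    ratio = res.theta["alpha_ST0"] / res.theta["alpha_TS0"]
    assert ratio == pytest.approx(0.01 / 0.04, rel=0.2)


# ---------------------------------------------------------------------------
# topology grid


@pytest.fixture(scope="module")
def grid_A(noiseless_data_A, params_A):
    return ps.topology_grid(noiseless_data_A, params_A.prolif, params_A.drug,
                            n_starts=2, seed=7)


def test_grid_shape_and_annotations(grid_A):
    assert grid_A.grid.shape == (8, 3)
    assert set(grid_A.grid.columns) == {"Repeated", "Resting", "Sustained"}
    assert grid_A.labels[3] == "(+,-,-)" and grid_A.labels[1] == "(=,=,=)"
    assert set(grid_A.annotated()["topology"]) == set(grid_A.labels.values())


def test_generating_topology_attains_column_minimum(grid_A):
    assert all(best == 3 for best in grid_A.best_per_regimen.values())


def test_grid_scaling_unit_interval(grid_A):
    scaled = grid_A.scaled().to_numpy()
    assert np.nanmin(scaled) == 0.0 and np.nanmax(scaled) == 1.0


# ---------------------------------------------------------------------------
# coupling estimation


def test_coupling_recovery_noiseless(params_2d):
    data = ps.generate_psm2d_data(params_2d, noise=ps.NoiseModel(sigma=0.0),
                                  seed=9, replicates=1)
    sched = ps.alternated(20.0, 10.0, n_inputs=4, horizon=96.0)
    res = ps.calibrate_coupling(data, params_2d, sched, n_starts=3, seed=2)
    assert res.theta["mu_TSN"] == pytest.approx(2.5, rel=0.1)
    assert res.theta["lambda_TSN"] == pytest.approx(0.5, rel=0.1)


def test_null_coupling_recovered_as_null(params_2d):
    uncoupled = replace(params_2d, coupling=CouplingParams(mu_TSN=1e-9,
                                                           lambda_TSN=0.5))
    data = ps.generate_psm2d_data(uncoupled, noise=ps.NoiseModel(sigma=0.0),
                                  seed=11, replicates=1)
    sched = ps.alternated(20.0, 10.0, n_inputs=4, horizon=96.0)
    res = ps.calibrate_coupling(data, params_2d, sched, n_starts=3, seed=4)
    # effective activation (1 + M) stays within a percent of unity
    assert res.theta["mu_TSN"] / res.theta["lambda_TSN"] < 0.02


def test_coupling_fit_beats_uncoupled_model(params_2d):
    data = ps.generate_psm2d_data(params_2d, noise=ps.NoiseModel(sigma=0.0),
                                  seed=13, replicates=1)
    sched = ps.alternated(20.0, 10.0, n_inputs=4, horizon=96.0)
    res = ps.calibrate_coupling(data, params_2d, sched, n_starts=3, seed=6)
    from phenoswitch.calibration import _N_on_grid_2d
    t_obs = np.arange(0.0, 96.1, 24.0)
    obs = data.mean_curve("Alternated").loc[t_obs].to_numpy()
    un = _N_on_grid_2d(params_2d, CouplingParams(mu_TSN=1e-9, lambda_TSN=0.5),
                       sched, t_obs, 10.0, 0.1)
    assert res.rmse_per_regimen["Alternated"] < ps.rmse(un, obs)
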