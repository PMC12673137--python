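"""Coupled two-drug model: conservation, reduction to the one-drug
model, coupling behaviour, threshold crossings and regimen comparison."""

import numpy as np
import pytest
from dataclasses import replace

import phenoswitch as ps
from phenoswitch.params import (CouplingParams, DrugParams, MemoryBank,
                                MemoryParams, ProliferationParams,
                                PSM1DParams, PSM2DParams, SwitchRates,
                                Topology)


def test_frozen_state():
    frozen1d = PSM1DParams(prolif=ProliferationParams(beta=0.0),
                           switch=SwitchRates(0.0, 0.0))
    p2 = PSM2DParams(drug_A=frozen1d,
                     drug_N=replace(frozen1d, drug=DrugParams(drug_id="N")),
                     coupling=CouplingParams(mu_TSN=0.0))
    dx = ps.psm2d_rhs([3, 4, 5, 0, 0] + [0.0] * 7, 0.0, p2)
    assert np.allclose(dx[:3], 0.0)


def test_switching_conserves_total_density(params_2d):
    x = np.array([10.0, 8.0, 6.0, 5.0, 3.0, 0.4, 0.2, 0.1, 0.3, 0.2, 0.1, 0.5])
    dx = ps.psm2d_rhs(x, 0.0, params_2d)
    N = x[:3].sum()
    # shared per-capita proliferation with both beta inhibitions active
    beta = params_2d.drug_A.prolif.beta / (1 + x[7]) / (1 + x[10])
    P = beta * (1 - (N / 100.0) ** params_2d.drug_A.prolif.n)
    assert dx[:3].sum() == pytest.approx(P * N, rel=1e-12)


def test_reduction_to_psm1d(params_N):
    """With the coupling off and the drug-A channel silenced, (S_N, T)
    reproduce a standalone one-drug simulation of drug N."""
    silent_A = PSM1DParams(
        prolif=params_N.prolif,
        drug=DrugParams(drug_id="A"),
        switch=SwitchRates(0.0, 0.0),
        memory=MemoryBank(*(MemoryParams(0.0, 1.0),) * 3),
        topology=Topology())
    p2 = PSM2DParams(drug_A=silent_A, drug_N=params_N,
                     coupling=CouplingParams(mu_TSN=0.0))
    sched = ps.repeated(ps.DrugId.N, 10.0, n_inputs=3, horizon=96.0)
    y0_1d = ps.initial_state_psm1d(params_N, N0=10.0)
    traj1 = ps.simulate_psm1d(params_N, sched, y0=y0_1d)
    y0_2d = np.zeros(12)
    y0_2d[1], y0_2d[2] = y0_1d[0], y0_1d[1]
    traj2 = ps.simulate_psm2d(p2, sched, y0=y0_2d)
    t = sched.observation_times()
    s1 = traj1.sample(t, side="left")
    s2 = traj2.sample(t, side="left")
    assert np.abs(s2[:, 1] - s1[:, 0]).max() < 1e-6       # S_N vs S
    assert np.abs(s2[:, 2] - s1[:, 1]).max() < 1e-6       # T
    assert np.allclose(s2[:, 0], 0.0)                     # S_A stays empty


def test_drug_N_impulse_extinguishes_sensitive_pool(params_2d):
    """With no tolerant cells, a necroptotic input kills the whole dish."""
    sched = ps.RegimenSchedule(
        events=(ps.DoseEvent(ps.DrugId.N, 0.0, 10.0),), horizon=24.0)
    y0 = np.zeros(12)
    y0[0], y0[1] = 6.0, 4.0       # T(0) = 0
    traj = ps.simulate_psm2d(params_2d, sched, y0=y0)
    assert traj.impulse_right[0, :3].sum() == 0.0
    assert np.allclose(traj.N[-1], 0.0)                   # N = 0 is absorbing


def test_coupling_speeds_resensitization(params_2d):
    """A stronger TRAIL->necroptosis coupling replenishes S_N faster
    after a drug-A input."""
    sched = ps.alternated(20.0, 10.0, n_inputs=2, horizon=48.0)
    t = np.arange(2.0, 23.0, 2.0)        # between the A input and the N kill
    weak = replace(params_2d, coupling=CouplingParams(mu_TSN=1e-9,
                                                      lambda_TSN=0.5))
    strong = replace(params_2d, coupling=CouplingParams(mu_TSN=5.0,
                                                        lambda_TSN=0.5))
    sw = ps.simulate_psm2d(weak, sched, t_eval=t).sample(t)[:, 1]
    ss = ps.simulate_psm2d(strong, sched, t_eval=t).sample(t)[:, 1]
    assert np.all(ss >= sw)
    assert ss[-1] > sw[-1] * 1.05        # clearly faster within day 1


def test_coupling_memory_tracks_drug_when_reset_is_fast(params_2d):
    """With a fast reset the activated T->S_N rate replicates the drug-A
    concentration profile (high when drug present, gone soon after)."""
    fast = replace(params_2d, coupling=CouplingParams(mu_TSN=2.5,
                                                      lambda_TSN=0.5))
    sched = ps.repeated(ps.DrugId.A, 20.0, n_inputs=1, horizon=96.0)
    traj = ps.simulate_psm2d(fast, sched)
    t = np.array([12.0, 90.0])
    m = traj.sample(t)[:, traj.columns.index("M_TSN")]
    d = traj.sample(t)[:, traj.columns.index("D_A")]
    assert d[0] > 0 and m[0] > 0.5       # charged while drug present
    assert d[1] == 0 and m[1] < 1e-4     # forgotten shortly after clearance


# ---------------------------------------------------------------------------
# threshold crossings


def test_no_crossing_for_constant_density():
    traj = ps.Trajectory(times=np.arange(5.0), columns=("S", "T"),
                         states=np.tile([30.0, 20.0], (5, 1)))
    rep = ps.detect_threshold_crossing(traj, 0.1, 99.5)
    assert rep.extinction_time is None and rep.occupation_time is None


def test_extinction_at_impulse(params_2d):
    sched = ps.RegimenSchedule(
        events=(ps.DoseEvent(ps.DrugId.N, 0.0, 10.0),), horizon=24.0)
    y0 = np.zeros(12)
    y0[0], y0[1] = 6.0, 4.0
    traj = ps.simulate_psm2d(params_2d, sched, y0=y0)
    rep = ps.detect_threshold_crossing(traj, 0.1, 99.5)
    assert rep.extinction_time == 0.0


def test_occupation_time_matches_logistic_closed_form():
    params = PSM1DParams(prolif=ProliferationParams(model_id="logistic",
                                                    beta=0.05),
                         switch=SwitchRates(0.0, 0.0))
    traj = ps.simulate_psm1d(params, ps.no_drug(250.0), y0=(1.0, 0.0),
                             dense_interval=0.1)
    thr = 99.5
    t_pred = np.log((thr / (100 - thr)) * (100 - 1) / 1) / 0.05
    rep = ps.detect_threshold_crossing(traj, 0.1, thr)
    assert rep.occupation_time == pytest.approx(t_pred, rel=0.01)


def test_threshold_domain_errors():
    traj = ps.Trajectory(times=np.arange(3.0), columns=("S", "T"),
                         states=np.tile([30.0, 20.0], (3, 1)))
    with pytest.raises(ValueError):
        ps.detect_threshold_crossing(traj, -1.0, 99.5)
    with pytest.raises(ValueError):
        ps.detect_threshold_crossing(traj, 0.1, 100.0)


# ---------------------------------------------------------------------------
# regimen comparison


def test_compare_regimens_deterministic_and_directional(params_2d):
    regimens = {
        "Repeated": ps.repeated(ps.DrugId.A, 20.0, n_inputs=4, horizon=96.0),
        "Repeated-bis": ps.repeated(ps.DrugId.A, 20.0, n_inputs=4,
                                    horizon=96.0),
        "Alternated": ps.alternated(20.0, 10.0, n_inputs=4, horizon=96.0),
    }
    table, crossings = ps.compare_regimens(params_2d, regimens)
    a = table[table.regimen == "Repeated"].drop(columns="regimen")
    b = table[table.regimen == "Repeated-bis"].drop(columns="regimen")
    assert np.allclose(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
    # alternating the cell death modality outperforms repeating drug A
    n96 = table.set_index(["regimen", "time_h"])["N"]
    assert n96["Alternated", 96.0] < n96["Repeated", 96.0]
    assert set(crossings) == set(regimens)


def test_null_drug_regimen_matches_no_drug_growth(params_A):
    inert = replace(params_A, drug=replace(params_A.drug, kappa=1.0))
    sched = ps.RegimenSchedule(
        events=tuple(ps.DoseEvent(ps.DrugId.A, t, 0.0) for t in (0., 24., 48.)),
        horizon=96.0)
    table, _ = ps.compare_regimens(inert, {"null": sched})
    ref = ps.simulate_psm1d(params_A, ps.no_drug(96.0))
    obs = sched.observation_times()
    assert np.allclose(table["N"].to_numpy(),
                       ref.sample_N(obs), atol=1e-6)


def test_compare_regimens_rejects_empty(params_2d):
    with pytest.raises(ValueError):
        ps.compare_regimens(params_2d, {})


def test_no_bistability_proportions_converge(params_2d):
    """From widely spread initial proportions, drug-free proportion
    dynamics settle on one attracting equilibrium (no hysteresis)."""
    rng = np.random.default_rng(11)
    sched = ps.no_drug(1500.0)
    finals = []
    for _ in range(10):
        w = rng.dirichlet([1.0, 1.0, 1.0])
        traj = ps.simulate_psm2d(params_2d, sched, y0=10.0 * w,
                                 t_eval=[0.0, 1500.0], dense_interval=1500.0)
        end = traj.states[-1, :3]
        finals.append(end / end.sum())
    finals = np.array(finals)
    assert np.max(finals.max(0) - finals.min(0)) < 1e-4
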