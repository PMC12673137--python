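"""One-drug model: elementary operations, dynamics and the simulation
engine, checked against closed forms and a brute-force integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phenoswitch as ps
from phenoswitch.params import (DrugParams, MemoryBank, MemoryParams,
                                ProliferationParams, PSM1DParams, SwitchRates,
                                Topology)


# ---------------------------------------------------------------------------
# proliferation laws


@pytest.mark.parametrize("N,expected", [
    (100.0, 0.0),        # rate vanishes at carrying capacity
    (0.0, 0.04),         # low-density rate is beta
    (50.0, 0.03),        # 0.04 * (1 - 0.25)
])
def test_hill_proliferation_closed_form(N, expected):
    p = ProliferationParams(beta=0.04, n=2.0)
    assert ps.proliferation_rate(p, N) == pytest.approx(expected, abs=1e-12)


def test_other_proliferation_laws():
    assert ps.proliferation_rate(
        ProliferationParams(model_id="exponential", beta=0.04), 70.0) == 0.04
    assert ps.proliferation_rate(
        ProliferationParams(model_id="logistic", beta=0.04), 50.0) \
        == pytest.approx(0.02)
    g = ProliferationParams(model_id="gompertz", beta=0.04)
    assert ps.proliferation_rate(g, 50.0) == pytest.approx(0.04 * np.log(2.0))
    # the N -> 0 singularity is capped, not divergent
    assert ps.proliferation_rate(g, 0.0) == pytest.approx(
        0.04 * np.log(100.0 / 1e-3))
    r = ProliferationParams(beta=0.04, n=2.0, hill_rational=True)
    assert ps.proliferation_rate(r, 100.0) == pytest.approx(0.02)


def test_proliferation_domain_errors():
    p = ProliferationParams()
    with pytest.raises(ValueError):
        ps.proliferation_rate(p, -1.0)
    with pytest.raises(ValueError):
        ps.proliferation_rate(p, 101.0)


# ---------------------------------------------------------------------------
# drug concentration


def test_drug_concentration_impulse_and_decay():
    d = DrugParams(D_input=20.0, k_d=0.8)
    sched = ps.repeated(ps.DrugId.A, 20.0, n_inputs=2, interval=24.0,
                        horizon=72.0)
    assert ps.drug_concentration(sched, d, 0.0) == 20.0         # just after
    assert ps.drug_concentration(sched, d, 10.0) == pytest.approx(12.0)
    # linear decay hits the floor after D_input / k_d
    fast = DrugParams(D_input=20.0, k_d=1.0)
    assert ps.drug_concentration(sched, fast, 21.0) == 0.0
    # wash + treat resets (does not add), regardless of residual drug
    slow = DrugParams(D_input=20.0, k_d=0.1)
    assert ps.drug_concentration(sched, slow, 24.0) == 20.0
    assert ps.drug_concentration(sched, slow, 24.0, side="left") \
        == pytest.approx(20.0 - 0.1 * 24.0)
    with pytest.raises(ValueError):
        ps.drug_concentration(sched, d, 100.0)


def test_sustained_single_input_no_reset():
    d = DrugParams(D_input=20.0, k_d=0.2)
    sched = ps.sustained(ps.DrugId.A, 20.0, horizon=168.0)
    assert ps.drug_concentration(sched, d, 48.0) == pytest.approx(20 - 0.2 * 48)
    assert ps.drug_concentration(sched, d, 150.0) == 0.0


# ---------------------------------------------------------------------------
# memory variables


def test_memory_derivative_cases():
    d = DrugParams(D_50=20.0)
    assert ps.memory_derivative(0.0, 5.0, MemoryParams(mu=0.0, lambda_=0.1),
                                d) == 0.0
    assert ps.memory_derivative(0.5, 0.0, MemoryParams(mu=0.3, lambda_=0.1),
                                d) == pytest.approx(-0.05)
    with pytest.raises(ValueError):
        ps.memory_derivative(-0.1, 0.0, MemoryParams(), d)


def test_memory_fixed_point_by_fine_step_integration():
    """At constant D = D_50 the memory converges to (mu/lambda)/2."""
    mp = MemoryParams(mu=0.2, lambda_=0.1)
    d = DrugParams(D_50=20.0)
    M, dt = 0.0, 1e-3
    for _ in range(int(200.0 / dt)):       # 200 h >> 1/lambda
        M += dt * ps.memory_derivative(M, 20.0, mp, d)
    assert M == pytest.approx(1.0, abs=1e-4)


# ---------------------------------------------------------------------------
# effective rates and right-hand side


def test_effective_rates_identities_and_closed_form():
    sr = SwitchRates(0.1, 0.2)
    pr = ProliferationParams(beta=0.04)
    null = Topology()
    assert ps.effective_rates(null, sr, pr, 5.0, 7.0, 9.0) == (0.1, 0.2, 0.04)
    full = Topology(True, True, True)
    assert ps.effective_rates(full, sr, pr, 0.0, 0.0, 0.0) == (0.1, 0.2, 0.04)
    a_st, a_ts, beta = ps.effective_rates(full, sr, pr, 1.0, 1.0, 1.0)
    assert (a_st, a_ts, beta) == pytest.approx((0.2, 0.1, 0.02))
    with pytest.raises(ValueError):
        ps.effective_rates(full, sr, pr, -1.0, 0.0, 0.0)


def test_rhs_frozen_and_absorbing(params_A):
    frozen = PSM1DParams(prolif=ProliferationParams(beta=0.0),
                         switch=SwitchRates(0.0, 0.0))
    assert np.allclose(ps.psm1d_rhs([10, 5, 0, 0, 0, 0], 0.0, frozen)[:2], 0.0)
    # empty dish is absorbing
    dx = ps.psm1d_rhs([0, 0, 10, 0, 0, 0], 0.0, params_A)
    assert dx[0] == dx[1] == 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(S=st.floats(0.01, 60.0), T=st.floats(0.01, 39.0),
       a_st=st.floats(0.0, 0.5), a_ts=st.floats(0.0, 0.5),
       m=st.floats(0.0, 3.0))
def test_switching_conserves_total_density(S, T, a_st, a_ts, m):
    """dS/dt + dT/dt equals P(N) * N exactly for any switching rates."""
    params = PSM1DParams(switch=SwitchRates(a_st, a_ts),
                         topology=Topology(True, True, True))
    dx = ps.psm1d_rhs([S, T, 10.0, m, m, m], 0.0, params)
    _, _, beta = ps.effective_rates(params.topology, params.switch,
                                    params.prolif, m, m, m)
    N = S + T
    P = beta * (1 - (N / 100.0) ** 2)
    assert dx[0] + dx[1] == pytest.approx(P * N, rel=1e-12, abs=1e-12)


def test_symmetric_exchange_cancels():
    params = PSM1DParams(switch=SwitchRates(0.1, 0.1))
    S = T = 7.0
    dx = ps.psm1d_rhs([S, T, 0, 0, 0, 0], 0.0, params)
    P = ps.proliferation_rate(params.prolif, S + T)
    assert dx[0] == pytest.approx(P * S)


# ---------------------------------------------------------------------------
# impulses


def test_apply_impulse():
    d = DrugParams(D_input=20.0, kappa=0.0)
    out = ps.apply_impulse([10.0, 5.0, 3.0, 0.1, 0.2, 0.3], d)
    assert out[0] == 0.0 and out[1] == 5.0 and out[2] == 20.0
    assert np.allclose(out[3:], [0.1, 0.2, 0.3])
    # kappa = 1: no kill, only the drug reset
    d1 = DrugParams(D_input=20.0, kappa=1.0)
    out1 = ps.apply_impulse([10.0, 5.0, 3.0, 0, 0, 0], d1)
    assert out1[0] == 10.0 and out1[2] == 20.0
    # idempotent on S at kappa = 0
    assert ps.apply_impulse(out, d)[0] == 0.0


# ---------------------------------------------------------------------------
# simulation engine


def test_constant_trajectory_without_dynamics():
    params = PSM1DParams(prolif=ProliferationParams(beta=0.0),
                         switch=SwitchRates(0.0, 0.0))
    traj = ps.simulate_psm1d(params, ps.no_drug(72.0), y0=(10.0, 5.0))
    assert np.allclose(traj.column("S"), 10.0)
    assert np.allclose(traj.column("T"), 5.0)


def test_impulse_at_zero_and_continuity(params_A, repeated_72h):
    traj = ps.simulate_psm1d(params_A, repeated_72h)
    assert traj.impulse_times.tolist() == [0.0, 24.0, 48.0]
    i_s = traj.columns.index("S")
    i_t = traj.columns.index("T")
    # S jumps to 0, T and memories are continuous at every impulse
    assert np.allclose(traj.impulse_right[:, i_s], 0.0)
    for i_cont in [i_t] + [traj.columns.index(c)
                           for c in ("M_ST", "M_TS", "M_beta")]:
        assert np.allclose(traj.impulse_left[:, i_cont],
                           traj.impulse_right[:, i_cont], atol=1e-12)
    i_d = traj.columns.index("D")
    assert np.allclose(traj.impulse_right[:, i_d], 20.0)


def test_nonnegativity_and_boundedness_random_draws():
    rng = np.random.default_rng(42)
    sched = ps.repeated(ps.DrugId.A, 20.0, horizon=168.0)
    for _ in range(8):
        params = ps.random_psm1d_params(rng)
        traj = ps.simulate_psm1d(params, sched)
        assert traj.states.min() >= -1e-9
        assert traj.N.max() <= 100.0 + 1e-6


def test_proportion_autonomy():
    """The sensitive fraction s(t) is independent of the growth law."""
    sched = ps.no_drug(120.0)
    fracs = []
    for beta, n in [(0.01, 1.5), (0.06, 3.0)]:
        params = PSM1DParams(prolif=ProliferationParams(beta=beta, n=n),
                             switch=SwitchRates(0.03, 0.07))
        traj = ps.simulate_psm1d(params, sched, y0=(9.0, 1.0))
        fracs.append(traj.column("S") / traj.N)
    assert np.max(np.abs(fracs[0] - fracs[1])) < 1e-6


def test_closed_form_relaxation_half_life():
    """s(t) - s_eq decays at rate alpha_ST + alpha_TS (half-life ln2/rate)."""
    a_st, a_ts = 0.02, 0.06
    params = PSM1DParams(switch=SwitchRates(a_st, a_ts))
    traj = ps.simulate_psm1d(params, ps.no_drug(100.0), y0=(10.0, 0.0),
                             t_eval=np.arange(0, 100.0001, 0.05))
    s = traj.column("S") / traj.N
    s_eq = a_ts / (a_st + a_ts)
    dev = s - s_eq
    half = np.interp(abs(dev[0]) / 2, np.abs(dev[::-1]), traj.times[::-1])
    assert half == pytest.approx(np.log(2) / (a_st + a_ts), rel=0.01)


def test_adaptive_matches_fine_fixed_step_oracle():
    """Adaptive solver vs an independent dt=1e-3 RK4 replay, 3 seeded draws."""
    rng = np.random.default_rng(7)
    sched = ps.repeated(ps.DrugId.A, 20.0, n_inputs=3, horizon=72.0)
    obs = np.arange(0.0, 72.1, 6.0)
    for _ in range(3):
        params = ps.random_psm1d_params(rng)
        traj = ps.simulate_psm1d(params, sched, t_eval=obs)
        ref = ps.reference_states_psm1d(params, sched, obs, dt=1e-3)
        assert np.abs(traj.sample(obs, side="left") - ref).max() < 1e-3


def test_trajectory_frame_and_sampling(params_A, repeated_72h):
    traj = ps.simulate_psm1d(params_A, repeated_72h)
    df = traj.frame()
    assert {"time_h", "S", "T", "N", "D"} <= set(df.columns)
    assert np.allclose(df["N"], df["S"] + df["T"])
    left = traj.sample([24.0], side="left")[0]
    right = traj.sample([24.0], side="right")[0]
    assert left[0] > 0 and right[0] == 0.0          # S killed at the input
    assert left[1] == pytest.approx(right[1])       # T continuous
    with pytest.raises(ValueError):
        traj.sample([500.0])


def test_simulation_rejects_bad_inputs(params_A, repeated_72h):
    with pytest.raises(ValueError):
        ps.simulate_psm1d(params_A, repeated_72h, y0=(-1.0, 5.0))
    with pytest.raises(ValueError):
        ps.simulate_psm1d(params_A, repeated_72h, y0=(1.0, 2.0, 3.0))


def test_schedule_validation():
    with pytest.raises(ValueError):
        ps.RegimenSchedule(events=(ps.DoseEvent("A", 0.0, 20.0),
                                   ps.DoseEvent("A", 0.0, 20.0)), horizon=72)
    with pytest.raises(ValueError):
        ps.RegimenSchedule(events=(ps.DoseEvent("A", 100.0, 20.0),),
                           horizon=72)
    sched = ps.repeated(ps.DrugId.A, 20.0, horizon=72.0)
    assert sched.observation_times().tolist() == [0.0, 24.0, 48.0, 72.0]
    assert sched.last_input_time() == 48.0
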