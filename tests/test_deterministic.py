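"""Deterministic engine: integration, adaptation, fixed points, metrics."""

import numpy as np
import pytest

import biopid as bp


def rho_to_k(rho, k1=1.0, theta=1.0, g1=1.0, g2=1.0):
    return rho * g1 * g2 * (g1 + g2) / (k1 * theta)


def test_ai_tracks_setpoint(gene_plant):
    spec = bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=1e4, k=rho_to_k(0.5))
    cl = bp.compose_closed_loop(gene_plant, spec)
    traj = bp.simulate_ode(cl, np.zeros(4), 250.0)
    assert traj.output(cl)[-1] == pytest.approx(5.0, abs=1e-6)


def test_ai_unstable_oscillates(gene_plant):
    spec = bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=1e4, k=rho_to_k(1.5))
    cl = bp.compose_closed_loop(gene_plant, spec)
    traj = bp.simulate_ode(cl, np.zeros(4), 200.0)
    y = traj.output(cl)
    late = y[traj.t > 150.0]
    assert late.max() - late.min() > 1.0  # sustained oscillation, no settling


def test_plant_alone_stays_at_zero(gene_plant):
    traj = bp.simulate_ode(gene_plant, [0.0, 0.0], 10.0)
    assert np.all(traj.x == 0.0)


def test_fixed_points(gene_plant):
    spec = bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=1e3, k=0.5)
    cl = bp.compose_closed_loop(gene_plant, spec)
    fp = bp.find_fixed_point(cl)
    assert fp[1] == pytest.approx(5.0, abs=1e-8)
    assert fp[0] == pytest.approx(5.0, abs=1e-8)  # gamma2*r/k1
    # output component solves g(mu, x) = theta*x to high accuracy
    assert abs(spec.mu - spec.theta * fp[1]) < 1e-10 * spec.mu

    o2 = bp.ControllerSpec("APID_ORDER2", mechanism="DEGRADATION", mu=6.0,
                           theta=3.0, beta=1.0, eta=1e3, k=0.5, delta=0.5)
    fp2 = bp.find_fixed_point(bp.compose_closed_loop(gene_plant, o2))
    assert fp2[1] == pytest.approx(3.0, abs=1e-8)

    c3 = bp.ControllerSpec("API_CLASS3", mechanism="MULTIPLICATIVE", mu=2.0,
                           theta=1.0, kappa=1.0, n=1, eta=1e3, k=0.3)
    fp3 = bp.find_fixed_point(bp.compose_closed_loop(gene_plant, c3))
    assert fp3[1] == pytest.approx(1.0, abs=1e-8)


def test_find_fixed_point_divergent_raises(gene_plant):
    # additive inhibition beyond alpha_TH: z2 diverges, no nonnegative
    # fixed point exists
    ath = bp.alpha_threshold(1.0, 1.0, 1.0, 5.0, 2.0, 1)
    spec = bp.ControllerSpec("API_CLASS1", mechanism="ADDITIVE", mu=5.0,
                             theta=1.0, eta=100.0, k=0.5, alpha=2.0 * ath,
                             kappa=2.0, n=1)
    cl = bp.compose_closed_loop(gene_plant, spec)
    with pytest.raises(bp.FixedPointError):
        bp.find_fixed_point(cl)


def test_transient_metrics_closed_forms():
    t = np.linspace(0.0, 30.0, 30001)
    r = 2.0
    y = r * (1.0 - np.exp(-t))
    traj = bp.Trajectory(t, y[:, None], ("y",))
    m = bp.transient_metrics(traj, r)
    assert m.overshoot_pct == 0.0
    assert m.rise_time == pytest.approx(np.log(9.0), abs=1e-3)
    assert m.settling_time == pytest.approx(-np.log(0.02), abs=1e-2)

    const = bp.Trajectory(t, np.full_like(t, r)[:, None], ("y",))
    m0 = bp.transient_metrics(const, r)
    assert (m0.settling_time, m0.overshoot_pct, m0.rise_time,
            m0.steady_state_error) == (0.0, 0.0, 0.0, 0.0)

    # decaying oscillation: settling time agrees with a direct scan oracle
    y2 = r * (1.0 + 0.5 * np.exp(-0.3 * t) * np.cos(2.0 * t))
    traj2 = bp.Trajectory(t, y2[:, None], ("y",))
    m2 = bp.transient_metrics(traj2, r)
    inside = np.abs(y2 - r) <= 0.02 * r
    oracle = t[np.where(~inside)[0][-1] + 1]
    assert m2.settling_time == pytest.approx(oracle, abs=1e-6)
    with pytest.raises(ValueError):
        bp.transient_metrics(traj2, -1.0)


def test_performance_index_properties():
    perfect = bp.TransientMetrics(0.0, 0.0, 0.0, 0.0, True)
    assert bp.performance_index(perfect) == 0.0
    m1 = bp.TransientMetrics(4.0, 10.0, 1.0, 0.0, True)
    m2 = bp.TransientMetrics(4.0, 20.0, 1.0, 0.0, True)
    J1 = bp.performance_index(m1, t_ref=10.0)
    J2 = bp.performance_index(m2, t_ref=10.0)
    assert J2 - J1 == pytest.approx(0.1)  # w_o * delta_overshoot / 100
    unsettled = bp.TransientMetrics(4.0, 10.0, 1.0, 0.5, False)
    assert bp.performance_index(unsettled, t_ref=10.0) > J1 + 9.0


def test_integral_action_identity(gene_plant):
    """d(z1 - z2)/dt equals g(mu, x_L) - theta*x_L along the trajectory and
    vanishes at steady state (the integral-action argument)."""
    spec = bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=50.0, k=0.4)
    cl = bp.compose_closed_loop(gene_plant, spec)
    traj = bp.simulate_ode(cl, np.zeros(4), 120.0, n_eval=12000)
    w = traj.x[:, 2] - traj.x[:, 3]
    dw = np.gradient(w, traj.t)
    rhs = spec.mu - spec.theta * traj.output(cl)
    mid = slice(100, -100)
    assert np.allclose(dw[mid], rhs[mid], atol=2e-2)
    assert abs(rhs[-1]) < 1e-6


def test_disturbance_rejection(gene_plant):
    spec = bp.ControllerSpec("API_CLASS1", mechanism="DEGRADATION", mu=5.0,
                             theta=1.0, eta=1e3, k=0.5, delta=1.0, kappa1=1.0)
    cl = bp.compose_closed_loop(gene_plant, spec)
    dist = [bp.DisturbanceEvent(60.0, "X2_deg", 2.0)]
    traj = bp.simulate_ode(cl, np.zeros(4), 180.0, disturbances=dist)
    y = traj.output(cl)
    assert y[np.searchsorted(traj.t, 59.9)] == pytest.approx(5.0, abs=1e-5)
    assert y[-1] == pytest.approx(5.0, abs=1e-6)  # back to the same setpoint


def test_rpa_over_random_stable_loops():
    """Robust perfect adaptation: the steady output is mu/theta regardless of
    plant rates and initial conditions, for 20 random stable closed loops."""
    rng = np.random.default_rng(2024)
    count = 0
    worst = 0.0
    while count < 20:
        L = int(rng.integers(2, 4))
        plant = bp.random_plant(int(rng.integers(0, 2 ** 31)), L=L)
        topo = ["AI", "API_CLASS1", "API_CLASS2"][count % 3]
        mech = ["MULTIPLICATIVE", "DEGRADATION"][count % 2]
        spec = bp.ControllerSpec(topo, mechanism=mech, mu=5.0, theta=1.0,
                                 eta=200.0, k=0.1, delta=0.5, kappa=2.0,
                                 kappa1=1.0)
        try:
            rep = bp.closed_loop_stability(spec, plant)
        except bp.FixedPointError:
            continue
        if not rep.stable:
            continue
        decay = abs(rep.dominant.real)
        if decay < 5e-3:  # nearly marginal: convergence too slow to observe
            continue
        cl = bp.compose_closed_loop(plant, spec)
        x0 = rng.uniform(0.0, 3.0, cl.n_species)
        traj = bp.simulate_ode(cl, x0, min(3000.0, 100.0 + 35.0 / decay))
        worst = max(worst, abs(traj.output(cl)[-1] - 5.0))
        count += 1
    assert worst < 1e-6


def test_trajectory_frame_and_signals(gene_plant):
    spec = bp.ControllerSpec("API_CLASS1", mechanism="DEGRADATION", mu=5.0,
                             theta=1.0, eta=100.0, k=0.5, delta=1.0)
    cl = bp.compose_closed_loop(gene_plant, spec)
    traj = bp.simulate_ode(cl, np.zeros(4), 20.0, n_eval=200)
    df = traj.to_frame()
    assert list(df.columns)[:5] == ["time", "X1", "X2", "Z1", "Z2"]
    assert "u" in df.columns and "u_I" in df.columns
    # u = u_I + u_P; the integral channel is the z1-driven part
    assert np.all(df["u_I"] >= -1e-12)
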