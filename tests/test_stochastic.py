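"""Stochastic engine: exact SSA, stationary moments, closure, PSD."""

import numpy as np
import pytest

import biopid as bp
from biopid.network import Reaction, mass_action


@pytest.fixture(scope="module")
def birth_death():
    return bp.build_reaction_network(
        ["X"], [Reaction("b", {"X": +1}, mass_action(20.0)),
                Reaction("d", {"X": -1}, mass_action(1.0, "X"))])


def test_birth_death_poisson(birth_death):
    """Stationary law of the linear birth-death chain is Poisson(20):
    mean and variance agree within 3 batch-means standard errors."""
    tr = bp.ssa_simulate(birth_death, [0], 3000.0, seed=42)
    assert tr.n_events > 1e5
    m = bp.stationary_moments([tr], burn_in=30.0)
    assert abs(m.mean[0] - 20.0) < 3 * m.se_mean[0]
    assert abs(m.variance[0] - 20.0) < 3 * m.se_variance[0]


def test_seed_determinism(birth_death):
    a = bp.ssa_simulate(birth_death, [0], 50.0, seed=7)
    b = bp.ssa_simulate(birth_death, [0], 50.0, seed=7)
    assert np.array_equal(a.t, b.t) and np.array_equal(a.x, b.x)
    c = bp.ssa_simulate(birth_death, [0], 50.0, seed=8)
    assert not np.array_equal(a.t, c.t)


def test_frozen_trajectory_without_sources():
    net = bp.build_reaction_network(
        ["A", "B"], [Reaction("r", {"A": -1, "B": +1}, mass_action(1.0, "A"))])
    tr = bp.ssa_simulate(net, [0, 0], 10.0, seed=1)
    assert tr.n_events == 0


def test_moment_input_validation(birth_death):
    tr = bp.ssa_simulate(birth_death, [0], 10.0, seed=1)
    with pytest.raises(ValueError, match="burn-in"):
        bp.stationary_moments([tr], burn_in=10.0)
    with pytest.raises(ValueError):
        bp.ssa_simulate(birth_death, [-1], 10.0, seed=1)


def test_stochastic_rpa_class1_class2(gene_plant):
    """Affine reference propensity -> stationary mean of the output equals
    mu/theta in the stochastic setting, across random parameter sets."""
    rng = np.random.default_rng(17)
    for i in range(6):
        topo = "API_CLASS1" if i % 2 == 0 else "API_CLASS2"
        mech = ("DEGRADATION", "MULTIPLICATIVE", "ADDITIVE")[i % 3]
        kw = {}
        if mech == "DEGRADATION":
            kw = dict(delta=float(rng.uniform(0.5, 3.0)), kappa1=1.0)
        elif mech == "MULTIPLICATIVE":
            kw = dict(kappa=float(rng.uniform(2.0, 8.0)), n=1)
        else:
            kw = dict(alpha=float(rng.uniform(0.5, 4.0)), kappa=5.0, n=1)
        spec = bp.ControllerSpec(topo, mechanism=mech, mu=5.0, theta=1.0,
                                 eta=10.0, k=float(rng.uniform(0.3, 1.2)), **kw)
        cl = bp.compose_closed_loop(gene_plant, spec)
        m = bp.ensemble_moments(cl, np.zeros(4, int), 400.0, 50.0,
                                n_traj=16, seed=100 + i)
        i_out = cl.output_index
        assert abs(m.mean[i_out] - 5.0) < 3 * m.se_mean[i_out], (topo, mech)


def test_class3_breaks_stochastic_rpa(gene_plant):
    """Non-affine reference (Class 3): the stationary mean deviates from
    mu/theta (it tracks the deterministic root of a different equation)."""
    spec = bp.ControllerSpec("API_CLASS3", mechanism="MULTIPLICATIVE", mu=5.0,
                             theta=1.0, eta=10.0, k=0.5, kappa=2.0, n=2)
    cl = bp.compose_closed_loop(gene_plant, spec)
    m = bp.ensemble_moments(cl, np.zeros(4, int), 400.0, 50.0, n_traj=16, seed=3)
    i_out = cl.output_index
    assert abs(m.mean[i_out] - 5.0) > 3 * m.se_mean[i_out]


def test_closure_reduces_to_ai_without_p(gene_plant):
    ai = bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=10.0, k=1.0)
    off = bp.ControllerSpec("API_CLASS1", mechanism="DEGRADATION", mu=5.0,
                            theta=1.0, eta=10.0, k=1.0, delta=0.0)
    va = bp.analytic_variance_class1(ai, gene_plant)["variance"]
    vo = bp.analytic_variance_class1(off, gene_plant)["variance"]
    assert va == pytest.approx(vo, rel=1e-12)


def test_closure_variance_monotone_in_delta(gene_plant):
    vs = []
    for d in (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0):
        spec = bp.ControllerSpec("API_CLASS1", mechanism="DEGRADATION", mu=5.0,
                                 theta=1.0, eta=10.0, k=1.0, delta=d, kappa1=1.0)
        vs.append(bp.analytic_variance_class1(spec, gene_plant)["variance"])
    assert all(a >= b for a, b in zip(vs, vs[1:]))


def test_closure_flags_ergodicity_loss(gene_plant):
    ath = bp.alpha_threshold(1, 1, 1, 5.0, 5.0, 1)
    spec = bp.ControllerSpec("API_CLASS1", mechanism="ADDITIVE", mu=5.0,
                             theta=1.0, eta=10.0, k=1.0, alpha=1.2 * ath,
                             kappa=5.0, n=1)
    with pytest.warns(UserWarning, match="ergodicity"):
        res = bp.analytic_variance_class1(spec, gene_plant)
    assert res["flags"]["ergodicity_lost"]


@pytest.mark.parametrize("mech,kw", [
    ("DEGRADATION", dict(delta=2.0, kappa1=1.0)),
    ("DEGRADATION", dict(delta=10.0, kappa1=1.0)),
    ("MULTIPLICATIVE", dict(kappa=2.0, n=1)),
    ("MULTIPLICATIVE", dict(kappa=0.5, n=1)),
])
def test_closure_agrees_with_ssa(gene_plant, mech, kw):
    """Moment-closure variance within 15% of the SSA estimate for the
    degradation and multiplicative mechanisms away from the boundary."""
    spec = bp.ControllerSpec("API_CLASS1", mechanism=mech, mu=5.0, theta=1.0,
                             eta=10.0, k=1.0, **kw)
    cl = bp.compose_closed_loop(gene_plant, spec)
    m = bp.ensemble_moments(cl, np.zeros(4, int), 600.0, 60.0, n_traj=32, seed=5)
    v_closure = bp.analytic_variance_class1(spec, gene_plant)["variance"]
    i_out = cl.output_index
    assert v_closure == pytest.approx(m.variance[i_out], rel=0.15)


def test_variance_ordering_degradation_multiplicative_additive(gene_plant):
    """At matched setpoint (5) with each mechanism at a strong proportional
    setting (additive at 80% of its ergodicity threshold, the others at
    comparable inhibition levels), the stationary output variance orders
    degradation < multiplicative < additive."""
    specs = [
        bp.ControllerSpec("API_CLASS1", mechanism="DEGRADATION", mu=5.0,
                          theta=1.0, eta=10.0, k=1.0, delta=10.0, kappa1=1.0),
        bp.ControllerSpec("API_CLASS1", mechanism="MULTIPLICATIVE", mu=5.0,
                          theta=1.0, eta=10.0, k=1.0, kappa=0.5, n=1),
        bp.ControllerSpec("API_CLASS1", mechanism="ADDITIVE", mu=5.0,
                          theta=1.0, eta=10.0, k=1.0, alpha=8.0, kappa=5.0, n=1),
    ]
    out = []
    for i, spec in enumerate(specs):
        cl = bp.compose_closed_loop(gene_plant, spec)
        m = bp.ensemble_moments(cl, np.zeros(4, int), 600.0, 60.0,
                                n_traj=32, seed=11)
        j = cl.output_index
        out.append((m.variance[j], m.se_variance[j]))
    (vd, sd), (vm, sm), (va, sa) = out
    assert vd + 2 * (sd + sm) < vm
    assert vm + 2 * (sm + sa) < va
    # degradation reaches sub-Poisson levels (below the mean 5)
    assert vd < 5.0


def test_psd_detects_sine_peak():
    rng = np.random.default_rng(0)
    t = np.arange(0.0, 400.0, 1.0)
    sig = np.sin(2 * np.pi * 0.1 * t) + 0.1 * rng.normal(size=(8, t.size))
    rep = bp.power_spectral_density(sig, 1.0)
    assert rep["peak"]["freq"] == pytest.approx(0.1, abs=0.005)
    assert rep["peak"]["significant"]


def test_psd_white_noise_has_no_peak():
    rng = np.random.default_rng(1)
    rep = bp.power_spectral_density(rng.normal(size=(16, 512)), 1.0,
                                    prominence_rel=10.0)
    assert not rep["peak"]["significant"]
    with pytest.raises(ValueError):
        bp.power_spectral_density(np.ones((2, 1)), 1.0)


def test_underdamped_loop_has_sharper_psd_peak(gene_plant):
    """Single-cell stochastic oscillations: an underdamped aI loop shows a
    more prominent PSD peak than the same loop damped by a proportional
    degradation component."""
    plant = bp.gene_expression_plant(1.0, 0.5, 0.5)
    k = 1.2 * 0.5 * 0.5 * 1.0 / 1.0  # rho = 1.2: lightly unstable aI
    ai = bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=20.0, k=k)
    pid = bp.ControllerSpec("API_CLASS1", mechanism="DEGRADATION", mu=5.0,
                            theta=1.0, eta=20.0, k=k, delta=4.0, kappa1=1.0)
    grid = np.arange(100.0, 1500.0, 1.0)
    proms = []
    for spec in (ai, pid):
        cl = bp.compose_closed_loop(plant, spec)
        sigs = np.stack([bp.ssa_resample(cl, np.zeros(4, int), grid, seed=s)
                         [:, cl.output_index] for s in range(40, 52)])
        proms.append(bp.power_spectral_density(sigs, 1.0)["peak"]["prominence"])
    assert proms[0] > proms[1]
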