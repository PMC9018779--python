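"""Linear analysis: Routh-Hurwitz, thresholds, gains, pole placement."""

import numpy as np
import pytest

import biopid as bp
from biopid.controllers import ControllerSpecError
from biopid.linear import routh_hurwitz_stable


# --------------------------------------------------------------------------
# linearize / Routh-Hurwitz
# --------------------------------------------------------------------------

def test_linearize_gene_expression(gene_plant):
    lin = bp.linearize(gene_plant, [0.0, 0.0])
    assert sorted(lin.eigenvalues.real) == pytest.approx([-1.0, -1.0])
    # char poly of diag(-gamma1, -gamma2): s^2 + 2s + 1
    assert lin.char_poly == pytest.approx([1.0, 2.0, 1.0])
    with pytest.raises(bp.FixedPointError):
        bp.linearize(gene_plant, [1.0, 0.0])  # not a fixed point


@pytest.mark.parametrize("coeffs,stable", [
    ([1, 3, 3, 1], True),         # (s+1)^3
    ([1, 1, 1, 2], False),        # a2*a1 < a0
    ([1, 2], True),
    ([1, -1], False),
])
def test_routh_examples(coeffs, stable):
    assert routh_hurwitz_stable(coeffs).stable is stable


def test_routh_marginal_and_errors():
    v = routh_hurwitz_stable([1, 0, 1])   # purely imaginary pair
    assert not v.stable and v.marginal
    with pytest.raises(ValueError):
        routh_hurwitz_stable([0, 1, 1])


def test_routh_agrees_with_eigenvalue_oracle():
    """1000 random polynomials of degree <= 6, log-uniform coefficients,
    against the companion-matrix root oracle."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        deg = int(rng.integers(1, 7))
        c = np.exp(rng.uniform(np.log(1e-2), np.log(1e2), deg + 1))
        c *= rng.choice([1.0, -1.0], deg + 1)
        c[0] = abs(c[0])
        oracle = bool(np.all(np.roots(c).real < 0))
        assert routh_hurwitz_stable(c).stable is oracle


# --------------------------------------------------------------------------
# lumped groups
# --------------------------------------------------------------------------

def test_rho_group_values():
    assert bp.rho_group(2, 3, 1, 1, 2) == pytest.approx(1.0)
    assert bp.rho_group(1, 1, 1, 1, 1) == pytest.approx(0.5)
    assert bp.rho_group(3 * 2, 3, 1, 1, 2) == pytest.approx(3.0)  # linear in k
    with pytest.raises(ZeroDivisionError):
        bp.rho_group(1, 1, 1, 0, 1)


def test_alpha_threshold_values():
    assert bp.alpha_threshold(1, 1, 1, 2, 2, 2) == pytest.approx(4.0)
    assert bp.alpha_threshold(1, 1, 1, 2, 1e12, 2) == pytest.approx(2.0, rel=1e-6)
    rs = [bp.alpha_threshold(1, 1, 1, r, 2, 2) for r in (1, 2, 4, 8)]
    assert all(a < b for a, b in zip(rs, rs[1:]))


# --------------------------------------------------------------------------
# large-eta closed forms vs the eigenvalue verdict
# --------------------------------------------------------------------------

def _mk(topology, mechanism, rho, **kw):
    k = rho * 2.0  # gamma1=gamma2=k1=theta=1
    return bp.ControllerSpec(topology, mechanism=mechanism, mu=5.0, theta=1.0,
                             eta=1e6, k=k, **kw)


def test_large_eta_examples(gene_plant):
    assert bp.stability_large_eta(_mk("AI", "ADDITIVE", 0.5), gene_plant).stable
    assert not bp.stability_large_eta(_mk("AI", "ADDITIVE", 1.5), gene_plant).stable
    # degradation inhibition stabilizes a loop the standalone aI cannot
    deg = _mk("API_CLASS1", "DEGRADATION", 1.5, delta=2.0, kappa1=0.5)
    assert bp.stability_large_eta(deg, gene_plant).stable
    assert bp.closed_loop_stability(deg, gene_plant).stable


def test_large_eta_agrees_with_eigenvalues(gene_plant):
    """Closed-form fast-sequestration verdicts match the full closed-loop
    eigenvalue verdict at eta = 1e6 across a parameter grid for every
    supported topology (points within 3% of the predicted stability
    boundary are excluded as genuinely eta-sensitive)."""
    rng = np.random.default_rng(11)
    cases = []
    for rho in (0.3, 0.8, 1.3, 2.5, 4.0):
        cases.append(_mk("AI", "ADDITIVE", rho))
        cases.append(_mk("API_CLASS1", "ADDITIVE", rho,
                         alpha=float(rng.uniform(0.5, 8.0)), kappa=2.0, n=1))
        cases.append(_mk("API_CLASS1", "MULTIPLICATIVE", rho,
                         kappa=float(rng.uniform(1.0, 10.0)), n=2))
        cases.append(_mk("API_CLASS1", "DEGRADATION", rho,
                         delta=float(rng.uniform(0.2, 5.0)), kappa1=1.0))
        cases.append(_mk("API_CLASS2", "MULTIPLICATIVE", rho, kappa=3.0))
        cases.append(_mk("API_CLASS2", "DEGRADATION", rho, delta=1.0))
        cases.append(_mk("API_CLASS3", "MULTIPLICATIVE", rho, kappa=5.0, n=1))
        cases.append(_mk("API_CLASS3", "ADDITIVE", rho, alpha=3.0, kappa=5.0, n=2))
    checked = 0
    for spec in cases:
        rep = bp.stability_large_eta(spec, gene_plant)
        if abs(rep.rho - rep.detail["rho_bound"]) < 0.03 * rep.detail["rho_bound"]:
            continue
        if rep.alpha_th is not None and abs(spec.alpha - rep.alpha_th) \
                < 0.03 * rep.alpha_th:
            continue
        try:
            full = bp.closed_loop_stability(spec, gene_plant)
            verdict = full.stable
        except bp.FixedPointError:
            verdict = False
        assert rep.stable == verdict, f"{spec.topology}/{spec.mechanism} rho={rep.rho}"
        checked += 1
    assert checked >= 30


def test_large_eta_rejects_other_plants():
    chain = bp.chain_feedback_plant(3, [1, 1], [1, 1, 1])
    with pytest.raises(ValueError, match="gene-expression"):
        bp.stability_large_eta(bp.ControllerSpec("AI"), chain)


def test_additive_threshold_flip_matches_closed_form(gene_plant):
    """The stability verdict of the additive Class-1 loop flips exactly at
    alpha_TH: bisection of the eigenvalue verdict vs the closed form."""
    rng = np.random.default_rng(99)
    for _ in range(10):
        kappa = float(rng.uniform(0.5, 10.0))
        n = int(rng.integers(1, 4))
        k = float(rng.uniform(0.2, 1.6))  # rho < 1 regime
        ath = bp.alpha_threshold(1, 1, 1, 5.0, kappa, n)

        def stable(alpha):
            spec = bp.ControllerSpec("API_CLASS1", mechanism="ADDITIVE", mu=5.0,
                                     theta=1.0, eta=1e6, k=k, alpha=alpha,
                                     kappa=kappa, n=n)
            try:
                return bp.closed_loop_stability(spec, gene_plant).stable
            except bp.FixedPointError:
                return False

        lo, hi = 0.5 * ath, 1.5 * ath
        assert stable(lo) and not stable(hi)
        while (hi - lo) / ath > 1e-8:
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if stable(mid) else (lo, mid)
        assert 0.5 * (lo + hi) == pytest.approx(ath, rel=1e-6)


# --------------------------------------------------------------------------
# root locus
# --------------------------------------------------------------------------

def test_root_locus_degradation_asymptote():
    out = bp.degradation_asymptote()
    assert out["divisor"] == pytest.approx(2.0, rel=0.01)


def test_root_locus_integral_pole_to_origin(gene_plant):
    spec = bp.ControllerSpec("API_CLASS1", mechanism="DEGRADATION", mu=5.0,
                             theta=1.0, eta=1e5, k=0.5, kappa1=1e-3)
    vals, loci = bp.root_locus(spec, gene_plant, "delta",
                               np.logspace(0, 5, 11))
    assert len(vals) == 11
    # one real eigenvalue approaches the origin from the left
    slow = [eigs[np.argmin(np.abs(eigs))] for eigs in loci]
    assert abs(slow[-1]) < abs(slow[0])
    assert -1e-2 < slow[-1].real < 0


def test_root_locus_constant_when_param_inert(gene_plant):
    spec = bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=1e4, k=0.5)
    vals, loci = bp.root_locus(spec, gene_plant, "alpha", [0.0, 1.0, 2.0])
    # alpha does not enter the aI network at all
    assert np.allclose(loci[0], loci[1]) and np.allclose(loci[0], loci[2])


# --------------------------------------------------------------------------
# PID gains: extraction and inversion
# --------------------------------------------------------------------------

def test_extract_ai_gains(gene_plant):
    g = bp.extract_pid_gains(
        bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=1e6, k=0.5), gene_plant)
    assert g.K_I == pytest.approx(0.5, rel=1e-4)   # K_I ~ k (theta = 1)
    assert abs(g.K_P) < 1e-5 and abs(g.K_D) < 1e-10
    assert g.K_I > 0


def test_extract_order2_kp_is_delta(gene_plant):
    spec = bp.ControllerSpec("APID_ORDER2", mechanism="DEGRADATION", mu=5.0,
                             theta=1.0, eta=1e5, k=0.5, delta=3.0, beta=0.3,
                             kappa1=1e-4)
    g = bp.extract_pid_gains(spec, gene_plant)
    assert g.K_P == pytest.approx(3.0, rel=1e-3)


def test_order3_constraint_on_random_grid(gene_plant):
    """Every valid order-3 spec yields K_P <= K_D*omega."""
    rng = np.random.default_rng(21)
    checked = 0
    while checked < 25:
        alpha0 = float(rng.uniform(0.2, 3.0))
        gamma0 = float(rng.uniform(0.5, 4.0))
        delta0 = float(rng.uniform(0.05, 1.0))
        delta = float(rng.uniform(0.0, 2.0 * delta0 * alpha0 / gamma0))
        try:
            spec = bp.ControllerSpec("APID_ORDER3", mechanism="DEGRADATION",
                                     mu=5.0, theta=1.0, eta=1e5,
                                     k=float(rng.uniform(0.1, 1.0)),
                                     delta=delta, alpha0=alpha0, gamma0=gamma0,
                                     delta0=delta0, kappa1=1e-3)
            g = bp.extract_pid_gains(spec, gene_plant)
        except (ControllerSpecError, bp.FixedPointError):
            continue
        assert g.K_P <= g.K_D * g.omega + 1e-9
        assert g.K_I > 0
        checked += 1


@pytest.mark.parametrize("topology,gains", [
    ("APID_ORDER4_DEG", bp.PIDGains(1.5, 0.4, 0.3, 4.0)),
    ("APID_ORDER4_DEG", bp.PIDGains(0.5, 0.8, 0.05, 10.0)),
    ("APID_ORDER3", bp.PIDGains(0.2, 0.4, 0.3, 4.0)),
    ("APID_ORDER3", bp.PIDGains(-0.5, 0.3, 0.2, 3.0)),  # negative K_P
])
def test_pid_inversion_round_trip(gene_plant, topology, gains):
    spec = bp.biomolecular_from_pid(topology, gains, gene_plant)
    g = bp.extract_pid_gains(spec, gene_plant)
    for a, b in [(g.K_P, gains.K_P), (g.K_I, gains.K_I), (g.K_D, gains.K_D),
                 (g.omega, gains.omega)]:
        assert a == pytest.approx(b, rel=1e-6, abs=1e-9)


def test_order3_infeasible_gains(gene_plant):
    with pytest.raises(ControllerSpecError, match="K_D"):
        bp.biomolecular_from_pid("APID_ORDER3", bp.PIDGains(2.0, 0.4, 0.3, 4.0),
                                 gene_plant)


# --------------------------------------------------------------------------
# pole placement
# --------------------------------------------------------------------------

def test_pole_placement_order2(gene_plant):
    res = bp.pole_placement(gene_plant, "APID_ORDER2", 1.5)
    assert res["max_rel_error"] < 0.05
    with pytest.raises(bp.PolePlacementInfeasible) as exc:
        bp.pole_placement(gene_plant, "APID_ORDER2", 4.0)
    assert exc.value.bound == pytest.approx((2 + np.sqrt(2)), rel=1e-12)


def test_pole_placement_boundary_matches_bound(gene_plant):
    lo, hi = 1.5, 4.0
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        try:
            bp.pole_placement(gene_plant, "APID_ORDER2", mid, verify=False)
            lo = mid
        except bp.PolePlacementInfeasible:
            hi = mid
    assert 0.5 * (lo + hi) == pytest.approx(bp.order2_pole_bound(1, 1), rel=0.01)


@pytest.mark.parametrize("topology", ["APID_ORDER3", "APID_ORDER4_DEG"])
def test_higher_order_placement_unbounded(gene_plant, topology):
    """Third- and fourth-order designs reach poles far beyond the order-2
    bound (here 10x gamma1+gamma2)."""
    a = 10.0 * 2.0
    res = bp.pole_placement(gene_plant, topology, a)
    dom = res["dominant_poles"]
    assert np.all(dom.real < -0.6 * a)  # deep in the left-half plane
    assert res["max_rel_error"] < 0.4   # quadruple roots split ~eps^(1/4)


def test_headline_rho_thresholds():
    # criterion-style: critical rho of the standalone aI is 1
    assert bp.critical_rho_ai(1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0, abs=1e-3)
    assert bp.critical_rho_ai(0.5, 2.0, 1.5, 1.0) == pytest.approx(1.0, abs=1e-3)
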