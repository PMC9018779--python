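"""Linear analysis: stability, thresholds, PID gains, pole placement.

Everything here operates on exact analytic linearizations of the reaction
networks (the propensity vocabulary carries exact derivatives); finite
differences never enter.  The large-sequestration (eta -> infinity) stability
conditions for the gene-expression plant are encoded in closed form and
cross-validated against the eigenvalue verdict of the full closed loop in the
test suite.

Conventions: the compensator transfer function is identified as

    C(s) = K_P + K_I / s + K_D s / (1 + s/omega)

acting on the tracking error e = r - y, from the exact partial-fraction
expansion of the linearized controller subsystem (integrator residue -> K_I,
slowest nonzero pole -> omega and K_D, remaining terms -> K_P).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .controllers import ControllerSpec, ControllerSpecError, warn_class2_additive_regime
from .deterministic import FixedPointError, find_fixed_point
from .network import ClosedLoopNetwork, ReactionNetwork, compose_closed_loop
from .plants import gene_expression_plant

__all__ = [
    "PIDGains",
    "StabilityReport",
    "Linearization",
    "RouthVerdict",
    "linearize",
    "routh_hurwitz_stable",
    "rho_group",
    "alpha_threshold",
    "stability_large_eta",
    "root_locus",
    "extract_pid_gains",
    "biomolecular_from_pid",
    "pole_placement",
    "PolePlacementInfeasible",
    "analytic_fixed_point",
    "closed_loop_stability",
    "critical_rho_ai",
    "additive_rho_supremum",
    "degradation_asymptote",
    "order2_pole_bound",
]


# --------------------------------------------------------------------------
# basic types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PIDGains:
    """Effective PID gains and low-pass cutoff of a linearized controller."""

    K_P: float
    K_I: float
    K_D: float
    omega: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("low-pass cutoff omega must be positive")


@dataclass(frozen=True)
class StabilityReport:
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    verdict: str                      # "stable" | "marginal" | "unstable"
    dominant: complex
    rho: float | None = None
    alpha_th: float | None = None
    detail: dict = field(default_factory=dict)

    @property
    def stable(self) -> bool:
        return self.verdict == "stable"


@dataclass(frozen=True)
class Linearization:
    point: np.ndarray
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    char_poly: np.ndarray             # coefficients, highest power first


@dataclass(frozen=True)
class RouthVerdict:
    stable: bool
    marginal: bool = False


class PolePlacementInfeasible(RuntimeError):
    def __init__(self, msg: str, bound: float | None = None):
        super().__init__(msg)
        self.bound = bound


_EIG_TOL = 1e-9


def _verdict_from_eigs(eigs: np.ndarray, tol: float = _EIG_TOL) -> str:
    i = int(np.argmax(eigs.real))
    m = float(eigs.real[i])
    scale = max(1.0, float(abs(eigs[i])))
    if m < -tol * scale:
        return "stable"
    if m > tol * scale:
        return "unstable"
    return "marginal"


# --------------------------------------------------------------------------
# linearize
# --------------------------------------------------------------------------

def linearize(network: ReactionNetwork, point) -> Linearization:
    """Exact Jacobian, eigenvalues and characteristic polynomial at a fixed
    point (residual checked against the propensity scale)."""
    point = np.asarray(point, dtype=float)
    res = np.linalg.norm(network.rhs(point), ord=np.inf)
    scale = max(1.0, float(np.max(np.abs(network.propensities(point)))))
    if res > 1e-8 * scale:
        raise FixedPointError(f"point is not a fixed point (residual {res:.2e})")
    J = network.jacobian(point)
    eigs = np.linalg.eigvals(J)
    poly = np.real(np.poly(J))
    return Linearization(point, J, eigs, poly)


# --------------------------------------------------------------------------
# Routh-Hurwitz
# --------------------------------------------------------------------------

def routh_hurwitz_stable(coeffs) -> RouthVerdict:
    """Hurwitz test on a real polynomial (highest power first) via the Routh
    array with the standard epsilon-perturbation for zero pivots.  Marginal
    cases (imaginary-axis roots) are reported unstable with a flag."""
    a = np.asarray(coeffs, dtype=float)
    if a.size == 0 or a[0] == 0.0:
        raise ValueError("leading coefficient must be nonzero")
    if a[0] < 0:
        a = -a
    n = a.size - 1
    if n == 0:
        return RouthVerdict(True)
    scale = float(np.max(np.abs(a)))
    eps = 1e-12 * scale
    width = n // 2 + 1
    rows = np.zeros((n + 1, width + 1))
    rows[0, : (n // 2) + 1] = a[0::2]
    rows[1, : ((n + 1) // 2)] = a[1::2]
    marginal = False
    for i in range(2, n + 1):
        upper, lower = rows[i - 2], rows[i - 1]
        if np.all(np.abs(lower) <= eps):
            # all-zero row: even auxiliary polynomial -> symmetric roots
            marginal = True
            order = n - (i - 2)
            aux = upper[: order // 2 + 1]
            powers = np.arange(order, -1, -2, dtype=float)
            lower = rows[i - 1] = np.zeros_like(upper)
            lower[: len(aux)] = aux * powers[: len(aux)]
        pivot = lower[0]
        if abs(pivot) <= eps:
            marginal = True
            pivot = eps
        for j in range(width):
            rows[i, j] = (pivot * upper[j + 1] - upper[0] * lower[j + 1]) / pivot
    first = np.array([rows[0, 0], rows[1, 0]] + [rows[i, 0] for i in range(2, n + 1)])
    first = np.where(np.abs(first) <= eps, eps, first)
    sign_changes = int(np.sum(np.sign(first[:-1]) != np.sign(first[1:])))
    if marginal:
        return RouthVerdict(False, marginal=True)
    return RouthVerdict(sign_changes == 0)


# --------------------------------------------------------------------------
# lumped parameter groups
# --------------------------------------------------------------------------

def rho_group(k: float, k1: float, theta: float, gamma1: float, gamma2: float) -> float:
    """rho = k*k1*theta / (gamma1*gamma2*(gamma1+gamma2)), the group that
    governs stability of the aI-controlled gene expression loop."""
    denom = gamma1 * gamma2 * (gamma1 + gamma2)
    if denom == 0:
        raise ZeroDivisionError("rho is undefined for zero degradation rates")
    return k * k1 * theta / denom


def alpha_threshold(gamma1: float, gamma2: float, k1: float, r: float,
                    kappa: float, n: float) -> float:
    """Additive-inhibition strength above which the Class-1 additive loop
    loses its nonnegative fixed point (and, stochastically, ergodicity)."""
    return gamma1 * gamma2 / k1 * r * (1.0 + (r / kappa) ** n)


# --------------------------------------------------------------------------
# analytic fixed points for chain plants
# --------------------------------------------------------------------------

def _plant_chain_rates(plant: ReactionNetwork):
    """(k_i, gamma_i, gamma_F, kappa_F) recovered from a chain plant."""
    L = plant.n_species
    k = [plant.rate_of(f"X{i}_to_X{i + 1}") for i in range(1, L)]
    gamma = [plant.rate_of(f"X{i}_deg") for i in range(1, L + 1)]
    gF, kF = 0.0, None
    for r in plant.reactions:
        if r.label == "fb_deg":
            gF = r.propensity.rate
            for f in r.propensity.factors:
                if f.kind == "michaelis":
                    kF = f.kappa
    return k, gamma, gF, kF


def analytic_fixed_point(spec: ControllerSpec, plant: ReactionNetwork) -> np.ndarray:
    """Closed-loop fixed point for a chain plant, exploiting the setpoint
    identity g(mu, r) = theta*r: the plant profile follows from the output
    backwards, the controller species from the input balance."""
    k, gamma, gF, kF = _plant_chain_rates(plant)
    L = plant.n_species
    r = spec.setpoint()
    x = np.zeros(L)
    x[L - 1] = r
    for i in range(L - 1, 1, -1):
        x[i - 1] = gamma[i] * x[i] / k[i - 1]
    # X1 balance includes the feedback degradation of X2 by the output
    fb = 0.0
    if gF > 0 and L >= 3:
        fb = gF * r * x[1] if kF is None else gF * r * x[1] / (x[1] + kF)
    x[0] = (gamma[1] * x[1] + fb) / k[0]
    x1 = x[0]

    cl = compose_closed_loop(plant, spec)
    zs = cl.controller_species
    state = {s: v for s, v in zip(plant.species, x)}

    # differentiator species at stationarity
    extra: dict[str, float] = {}
    sat1 = x1 / (x1 + spec.kappa1) if x1 + spec.kappa1 > 0 else 0.0
    if spec.topology == "APID_ORDER3":
        extra["Z3"] = spec.alpha0 * r / spec.gamma0
    elif spec.topology == "APID_ORDER4_DEG":
        denom = spec.k0 * r * sat1
        if denom <= 0:
            raise FixedPointError("order-4 differentiator needs k0*r > 0")
        extra["Z3"] = spec.mu0 / denom
        extra["Z4"] = spec.mu0 / (spec.eta0 * extra["Z3"]) if spec.mu0 > 0 else 0.0
    elif spec.topology == "APID_ORDER4_PROD":
        extra["Z3"] = spec.mu0 * (1.0 + r / spec.kappa0) / spec.k0 if spec.k0 > 0 else 0.0
        extra["Z4"] = (spec.mu0 / (spec.eta0 * extra["Z3"])
                       if spec.mu0 > 0 and extra["Z3"] > 0 else 0.0)
    elif spec.topology == "DIFF_OUTFLOW":
        if spec.k0 * r <= spec.mu0:
            raise FixedPointError("outflow differentiator needs k0*r > mu0")
        extra["Z3"] = spec.mu0 * spec.kappa0 / (spec.k0 * r - spec.mu0)
    elif spec.topology == "DIFF_INFLOW":
        def f(z3):
            return (spec.k0 * r / (1.0 + z3 / spec.kappa_d)
                    - spec.mu0 * z3 / (z3 + spec.kappa0))
        if f(1e-12) <= 0:
            extra["Z3"] = 0.0
        else:
            hi = 1.0
            while f(hi) > 0 and hi < 1e12:
                hi *= 10.0
            extra["Z3"] = brentq(f, 1e-12, hi, xtol=1e-14)
    elif spec.topology == "DIFF_AUTOCATALYTIC":
        z3 = spec.mu0 / (spec.k0 * r) - spec.kappa0 if spec.k0 * r > 0 else 0.0
        if z3 <= 0:
            raise FixedPointError(
                "autocatalytic differentiator has no positive fixed point "
                "(needs mu0 > k0*r*kappa0)")
        extra["Z3"] = z3
    state.update(extra)

    # controller balance on the input species: u(z1) = gamma1 * x1bar
    theta_r = spec.theta * r
    vec = np.array([state.get(s, 0.0) for s in cl.species])
    iz1 = cl.species_index("Z1")
    iz2 = cl.species_index("Z2")

    def input_balance(z1):
        v = vec.copy()
        v[iz1] = z1
        v[iz2] = theta_r / (spec.eta * z1)
        u, _, _ = cl.actuation_value(v)
        return u - gamma[0] * x1

    lo, hi = 1e-12, 1.0
    if input_balance(lo) > 0:
        raise FixedPointError(
            "no nonnegative fixed point: actuation exceeds the input balance even "
            "as z1 -> 0 (e.g. additive inhibition beyond alpha_TH)")
    while input_balance(hi) < 0 and hi < 1e14:
        hi *= 10.0
    if input_balance(hi) < 0:
        raise FixedPointError("input balance has no root; actuation cannot reach it")
    z1 = brentq(input_balance, lo, hi, xtol=1e-300, rtol=1e-15)
    state["Z1"] = z1
    state["Z2"] = theta_r / (spec.eta * z1)

    return np.array([state[s] for s in cl.species])


# --------------------------------------------------------------------------
# eigenvalue verdict of the full closed loop
# --------------------------------------------------------------------------

def closed_loop_stability(spec: ControllerSpec, plant: ReactionNetwork,
                          point=None) -> StabilityReport:
    cl = compose_closed_loop(plant, spec)
    if point is None:
        try:
            point = analytic_fixed_point(spec, plant)
        except KeyError:
            # not a chain plant: fall back to the generic damped root search
            point = find_fixed_point(cl)
    J = cl.jacobian(point)
    eigs = np.linalg.eigvals(J)
    verdict = _verdict_from_eigs(eigs)
    rho = None
    alpha_th = None
    if plant.n_species == 2:
        k, gamma, _, _ = _plant_chain_rates(plant)
        rho = rho_group(spec.k, k[0], spec.theta, gamma[0], gamma[1])
        if spec.mechanism == "ADDITIVE" and spec.alpha > 0:
            alpha_th = alpha_threshold(gamma[0], gamma[1], k[0], spec.setpoint(),
                                       spec.kappa, spec.n)
    dom = eigs[np.argmax(eigs.real)]
    return StabilityReport(J, eigs, verdict, dom, rho, alpha_th,
                           detail={"point": np.asarray(point)})


# --------------------------------------------------------------------------
# closed-form large-eta verdicts (gene-expression plant)
# --------------------------------------------------------------------------

def stability_large_eta(spec: ControllerSpec, plant: ReactionNetwork) -> StabilityReport:
    """Closed-form stability verdict in the fast-sequestration limit for the
    two-species gene-expression plant.

    The reduced (eta -> infinity) loop is third order with characteristic
    polynomial s^3 + (a+g2)s^2 + (a*g2 + b*k1)s + theta*k1*h_z1, where
    a = g1 - dh/dx1, b = -dh/dx_L and h_z1 = dh/dz1 at the fixed point; the
    Hurwitz condition reduces to the rho-inequalities tabulated per topology.
    """
    if plant.n_species != 2:
        raise ValueError(
            "closed-form large-eta conditions cover the gene-expression plant only; "
            "use closed_loop_stability (eigenvalue analysis) for other plants")
    k1 = plant.rate_of("X1_to_X2")
    g1 = plant.rate_of("X1_deg")
    g2 = plant.rate_of("X2_deg")
    r = spec.setpoint()
    rho = rho_group(spec.k, k1, spec.theta, g1, g2)
    x1 = g2 * r / k1
    detail: dict = {"rho": rho}
    alpha_th = None

    topo, mech = spec.topology, spec.mechanism
    if topo == "AI" or (topo in ("API_CLASS1", "API_CLASS2")
                        and mech == "ADDITIVE" and spec.alpha == 0.0):
        bound = 1.0
        stable = rho < bound
    elif topo == "API_CLASS1":
        q = (r / spec.kappa) ** spec.n
        if mech == "ADDITIVE":
            warnings_on = False
            alpha_th = alpha_threshold(g1, g2, k1, r, spec.kappa, spec.n)
            b = spec.alpha * spec.n * q / (r * (1.0 + q) ** 2)
            bound = 1.0 + k1 * b / (g1 * g2)
            stable = (spec.alpha < alpha_th) and (rho < bound)
            detail["fixed_point_exists"] = spec.alpha < alpha_th
        elif mech == "MULTIPLICATIVE":
            bound = (1.0 + q) * (1.0 + spec.n * q / (1.0 + q))
            stable = rho < bound
        else:  # DEGRADATION
            a = g1 + spec.delta * r * spec.kappa1 / (x1 + spec.kappa1) ** 2
            b = spec.delta * x1 / (x1 + spec.kappa1)
            bound = (a + g2) * (a * g2 + b * k1) / (g1 * g2 * (g1 + g2))
            stable = rho < bound
    elif topo == "API_CLASS2":
        warn_class2_additive_regime(spec, g1, g2, k1)
        bound = 1.0
        stable = rho < bound
        if mech == "ADDITIVE" and spec.alpha >= g1 * g2 * r / k1:
            detail["regime"] = "Z2-integral (not analyzed)"
            stable = False
    elif topo == "API_CLASS3":
        q = (r / spec.kappa) ** spec.n
        strength = spec.mu if mech == "MULTIPLICATIVE" else spec.alpha
        g_slope = strength * spec.n * q / (r * (1.0 + q) ** 2)
        bound = spec.theta / (spec.theta + g_slope)
        stable = rho < bound
    else:
        raise ValueError(
            f"no closed-form large-eta condition for topology {topo}; use "
            "closed_loop_stability")

    detail["rho_bound"] = bound
    verdict = "stable" if stable else "unstable"
    J = np.zeros((0, 0))
    return StabilityReport(J, np.zeros(0, dtype=complex), verdict,
                           dominant=0j, rho=rho, alpha_th=alpha_th, detail=detail)


# --------------------------------------------------------------------------
# root locus
# --------------------------------------------------------------------------

def root_locus(spec: ControllerSpec, plant: ReactionNetwork, param: str, values):
    """Eigenvalue loci of the closed loop as one controller parameter sweeps.

    Returns (values_done, loci) where loci[i] is the eigenvalue set at
    values_done[i], ordered for continuity by nearest-neighbour matching
    between consecutive grid points.  Truncates (with a warning) if the fixed
    point is lost along the sweep.
    """
    from dataclasses import replace
    from scipy.optimize import linear_sum_assignment

    done, loci = [], []
    prev = None
    for v in values:
        s = replace(spec, **{param: v})
        try:
            rep = closed_loop_stability(s, plant)
        except (FixedPointError, ControllerSpecError) as e:
            warnings.warn(f"root locus truncated at {param}={v:g}: {e}", stacklevel=2)
            break
        eigs = rep.eigenvalues
        if prev is not None:
            cost = np.abs(prev[:, None] - eigs[None, :])
            _, cols = linear_sum_assignment(cost)
            eigs = eigs[cols]
        done.append(v)
        loci.append(eigs)
        prev = eigs
    return np.asarray(done), np.asarray(loci)


# --------------------------------------------------------------------------
# PID gain extraction
# --------------------------------------------------------------------------

def extract_pid_gains(spec: ControllerSpec, plant: ReactionNetwork,
                      point=None) -> PIDGains:
    """Identify C(s) = K_P + K_I/s + K_D s/(1+s/omega) from the exact
    linearization of the controller subsystem about the closed-loop fixed
    point (output perturbation -> actuation, plant input held at its
    stationary value)."""
    cl = compose_closed_loop(plant, spec)
    if point is None:
        point = analytic_fixed_point(spec, plant)
    point = np.asarray(point, dtype=float)
    nz = len(cl.controller_species)
    np_plant = cl.n_plant
    zi = list(range(np_plant, np_plant + nz))
    J = cl.jacobian(point)
    A = J[np.ix_(zi, zi)]
    B = J[zi, cl.output_index]

    # gradient of u = sum(sign * lambda_act) wrt (z, x_L)
    m = {s: float(v) for s, v in zip(cl.species, point)}
    Crow = np.zeros(nz)
    D = 0.0
    for rxn in cl.controller_reactions:
        role = cl.controller_meta["roles"].get(rxn.label)
        if role not in ("act_I", "act_P", "act_D"):
            continue
        sign = 1.0 if rxn.stoich.get(cl.input_species, 0) > 0 else -1.0
        grad = rxn.propensity.gradient(m)
        for s, g in grad.items():
            if s in cl.controller_species:
                Crow[cl.species_index(s) - np_plant] += sign * g
            elif s == cl.output_species:
                D += sign * g

    lam, V = np.linalg.eig(A)
    W = np.linalg.inv(V)
    residues = (Crow @ V) * (W @ B)          # residues of T(s) at each pole
    izero = int(np.argmin(np.abs(lam)))
    others = [i for i in range(nz) if i != izero]
    # the antithetic integrator contributes a structurally exact origin pole;
    # compare it against the slowest remaining (filter) pole
    scale = max(1.0, min(abs(lam[i]) for i in others)) if others else 1.0
    if abs(lam[izero]) > 1e-6 * scale:
        raise ValueError("controller linearization has no pole at the origin; "
                         "no integral action to extract")
    if any(abs(lam[i]) < 1e-8 for i in others):
        raise ValueError("two controller poles at the origin; extraction undefined")
    if any(lam[i].real > 0 for i in others):
        raise ValueError("unstable filter pole in the controller subsystem")

    K_I = float(np.real(-residues[izero]))
    # slowest nonzero pole defines the low-pass filter
    islow = min(others, key=lambda i: abs(lam[i]))
    omega = float(abs(lam[islow]))
    K_D = float(np.real(residues[islow] / lam[islow] ** 2))
    K_P = float(np.real(-D + sum(residues[i] / lam[i] for i in others)))
    if np.iscomplex(lam[islow]) and abs(lam[islow].imag) > 1e-9 * omega:
        warnings.warn("slowest controller pole is complex; K_D/omega identify its "
                      "magnitude only approximately", stacklevel=2)
    if K_I <= 0:
        raise ValueError(f"extracted K_I = {K_I:.3e} is not positive; the antithetic "
                         "integrator should always yield K_I > 0")
    return PIDGains(K_P, K_I, K_D, omega,
                    meta={"poles": lam, "residues": residues, "direct": -D,
                          "point": point})


# --------------------------------------------------------------------------
# differentiator open-loop frequency response
# --------------------------------------------------------------------------

def differentiator_frequency_response(spec: ControllerSpec, freq: float,
                                      x_bar: float = 5.0, x1_bar: float = 100.0,
                                      eps_rel: float = 0.02) -> dict:
    """Open-loop harness for the derivative channel: impose
    x_L(t) = x_bar + eps*sin(2*pi*freq*t), integrate the differentiator
    species, and compare the steady oscillatory amplitude of u_D with the
    ideal filtered derivative K_D * s/(1+s/omega) at that frequency.

    K_D and omega come from the exact linearization of the differentiator
    subsystem at x_L = x_bar (slowest pole -> omega, its residue -> K_D).
    Returns measured/predicted gains and their ratio.
    """
    from scipy.integrate import solve_ivp

    frag = spec.compile(plant_input="X1", plant_output="XL")
    dspecies = [s for s in frag.species if s in ("Z3", "Z4")]
    if not dspecies:
        raise ValueError(f"topology {spec.topology} has no differentiator species")
    drxns = [r for r in frag.reactions
             if frag.roles.get(r.label) == "diff" and any(s in r.stoich for s in dspecies)]
    act = [r for r in frag.reactions if frag.roles.get(r.label) == "act_D"]
    if not act:
        raise ValueError("no derivative actuation channel")

    eps = eps_rel * x_bar

    def env(t):
        return x_bar + eps * math.sin(2.0 * math.pi * freq * t)

    def state_map(z, xl):
        m = {"X1": x1_bar, "XL": xl}
        m.update({s: float(v) for s, v in zip(dspecies, z)})
        return m

    def u_d(z, xl):
        m = state_map(z, xl)
        tot = 0.0
        for r in act:
            sign = 1.0 if r.stoich.get("X1", 0) > 0 else -1.0
            tot += sign * r.propensity.value(m)
        return tot

    def rhs(t, z):
        m = state_map(z, env(t))
        dz = np.zeros(len(dspecies))
        for r in drxns:
            v = r.propensity.value(m)
            for i, s in enumerate(dspecies):
                dz[i] += r.stoich.get(s, 0) * v
        return dz

    # stationary differentiator state at the carrier level x_bar
    z0 = np.full(len(dspecies), 1.0)
    if spec.topology == "DIFF_AUTOCATALYTIC":
        z0[0] = spec.z3_init
    eqs = solve_ivp(lambda t, z: _frozen_rhs(drxns, dspecies, z, x_bar, x1_bar),
                    (0, 2000.0 / max(freq, 1e-3)), z0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    zbar = np.maximum(eqs.y[:, -1], 0.0)

    # exact linearization of the subsystem at (zbar, x_bar)
    m0 = state_map(zbar, x_bar)
    nd = len(dspecies)
    A = np.zeros((nd, nd))
    B = np.zeros(nd)
    for r in drxns:
        grad = r.propensity.gradient(m0)
        for i, s in enumerate(dspecies):
            c = r.stoich.get(s, 0)
            if c == 0:
                continue
            for s2, g in grad.items():
                if s2 in dspecies:
                    A[i, dspecies.index(s2)] += c * g
                elif s2 == "XL":
                    B[i] += c * g
    Crow = np.zeros(nd)
    D = 0.0
    for r in act:
        sign = 1.0 if r.stoich.get("X1", 0) > 0 else -1.0
        grad = r.propensity.gradient(m0)
        for s2, g in grad.items():
            if s2 in dspecies:
                Crow[dspecies.index(s2)] += sign * g
            elif s2 == "XL":
                D += sign * g
    lam, V = np.linalg.eig(A)
    W = np.linalg.inv(V)
    residues = (Crow @ V) * (W @ B)
    islow = int(np.argmin(np.abs(lam)))
    omega = float(abs(lam[islow]))
    K_D = float(np.real(residues[islow] / lam[islow] ** 2))

    # time-domain measurement: transient decays like exp(-omega*t)
    t_end = 10.0 / omega + 6.0 / freq
    sol = solve_ivp(rhs, (0.0, t_end), zbar, method="LSODA", rtol=1e-10,
                    atol=1e-12, dense_output=True)
    tt = np.linspace(t_end - 4.0 / freq, t_end, 800)
    uu = np.array([u_d(sol.sol(t), env(t)) for t in tt])
    X = np.column_stack([np.sin(2 * np.pi * freq * tt), np.cos(2 * np.pi * freq * tt),
                         np.ones_like(tt)])
    coef, *_ = np.linalg.lstsq(X, uu, rcond=None)
    measured = math.hypot(coef[0], coef[1]) / eps
    s = 2j * math.pi * freq
    predicted = abs(K_D * s / (1.0 + s / omega))
    return {"measured_gain": measured, "predicted_gain": float(predicted),
            "ratio": measured / predicted, "K_D": K_D, "omega": omega,
            "zbar": zbar}


def _frozen_rhs(drxns, dspecies, z, xl, x1):
    m = {"X1": x1, "XL": xl}
    m.update({s: float(v) for s, v in zip(dspecies, z)})
    dz = np.zeros(len(dspecies))
    for r in drxns:
        v = r.propensity.value(m)
        for i, s in enumerate(dspecies):
            dz[i] += r.stoich.get(s, 0) * v
    return dz


# --------------------------------------------------------------------------
# inverse mapping: biomolecular parameters from PID gains
# --------------------------------------------------------------------------

def biomolecular_from_pid(topology: str, gains: PIDGains, plant: ReactionNetwork,
                          setpoint_value: float = 5.0, theta: float = 1.0,
                          eta: float = 1e5, eta0: float = 1e5,
                          tol: float = 1e-6) -> ControllerSpec:
    """Biomolecular rates realizing requested (K_P, K_I, K_D, omega).

    Feasibility by topology: the fourth-order design covers any positive
    quadruple; the third-order is restricted to K_P <= K_D*omega (and
    K_P >= -K_D*omega so the direct arm stays nonnegative); AI covers
    (0, K_I, 0, -) only.  Analytic seeds are refined by damped least squares
    until re-extraction reproduces the request to ``tol`` relative.
    """
    k1 = plant.rate_of("X1_to_X2")
    g2 = plant.rate_of("X2_deg")
    r = setpoint_value
    mu = theta * r
    x1 = g2 * r / k1
    kappa1 = 1e-4 * x1

    if gains.K_I <= 0:
        raise ValueError("K_I must be positive for an antithetic design")

    if topology == "AI":
        if abs(gains.K_P) > tol or abs(gains.K_D) > tol:
            raise ControllerSpecError("AI topology realizes K_P = K_D = 0 only")
        return ControllerSpec("AI", mu=mu, theta=theta, eta=eta, k=gains.K_I / theta)

    if topology == "APID_ORDER3":
        if gains.K_D <= 0:
            raise ControllerSpecError("order-3 design needs K_D > 0")
        if gains.K_P > gains.K_D * gains.omega + 1e-12:
            raise ControllerSpecError(
                f"infeasible for order-3: K_P = {gains.K_P:g} exceeds K_D*omega = "
                f"{gains.K_D * gains.omega:g}; the achievable set satisfies "
                "K_P <= K_D*omega")
        if gains.K_P < -gains.K_D * gains.omega - 1e-12:
            raise ControllerSpecError(
                "infeasible for order-3: K_P < -K_D*omega would need a negative "
                "direct inhibition strength")
        gamma0 = gains.omega
        alpha0 = gamma0
        delta0 = gains.K_D * gamma0
        delta_eff = gains.K_P + gains.K_D * gains.omega
        names = ["k", "delta", "delta0"]
        seed = [gains.K_I / theta, max(delta_eff, 1e-12), delta0]
        fixed = dict(topology="APID_ORDER3", mechanism="DEGRADATION", mu=mu,
                     theta=theta, eta=eta, alpha0=alpha0, gamma0=gamma0,
                     kappa1=kappa1)
    elif topology in ("APID_ORDER4_DEG", "APID_ORDER4_PROD"):
        if gains.K_D <= 0 or gains.K_P < 0:
            raise ControllerSpecError(
                "order-4 inversion implemented for positive (K_P, K_I, K_D, omega)")
        k0 = gains.omega / r
        mu0 = gains.K_D * gains.omega * r
        names = ["k", "delta", "mu0", "k0"]
        seed = [gains.K_I / theta, max(gains.K_P, 1e-12), mu0, k0]
        fixed = dict(topology="APID_ORDER4_DEG", mechanism="DEGRADATION", mu=mu,
                     theta=theta, eta=eta, eta0=eta0, kappa1=kappa1)
    else:
        raise ControllerSpecError(
            f"inverse mapping not implemented for topology {topology!r}")

    target = np.array([gains.K_P, gains.K_I, gains.K_D, gains.omega])
    norm = np.maximum(np.abs(target), 1e-9)

    def make(params):
        kw = dict(fixed)
        kw.update({n: float(max(v, 0.0)) for n, v in zip(names, params)})
        return ControllerSpec(**kw)

    def resid(params):
        try:
            g = extract_pid_gains(make(params), plant)
        except (ValueError, FixedPointError, ControllerSpecError):
            return np.full(4, 1e3)
        return (np.array([g.K_P, g.K_I, g.K_D, g.omega]) - target) / norm

    best = None
    for scale_try in (1.0, 0.5, 2.0):
        sol = least_squares(resid, np.asarray(seed) * scale_try, xtol=1e-14,
                            ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if np.max(np.abs(sol.fun)) < tol:
            break
    if best is None or np.max(np.abs(best.fun)) > tol:
        raise ControllerSpecError(
            f"could not realize the requested gains with {topology} "
            f"(residual {np.max(np.abs(best.fun)):.2e}); they may be infeasible")
    return make(best.x)


# --------------------------------------------------------------------------
# pole placement (gene-expression plant, quadruple pole at -a)
# --------------------------------------------------------------------------

def order2_pole_bound(gamma1: float, gamma2: float) -> float:
    """Deepest quadruple pole the order-2 design can realize."""
    return (2.0 + math.sqrt(2.0)) * (gamma1 + gamma2) / 2.0


def _order2_match(a, g1, g2, k1, r):
    G = g1 + g2
    P = 4.0 * a - G
    if P <= 0:
        raise PolePlacementInfeasible(f"a = {a:g} too small: 4a <= gamma1+gamma2")
    dk1 = 6.0 * a * a - g1 * g2 - G * P
    Bc = 20.0 * a ** 3 - 22.0 * a * a * G + 8.0 * a * G * G - G ** 3
    if dk1 < 0 or Bc < 0:
        raise PolePlacementInfeasible(
            f"a = {a:g}: coefficient matching needs a negative rate (delta*k1 = "
            f"{dk1:g}, beta*k*k1 = {Bc:g})")
    C = (g1 * g2 + dk1) * r / k1          # = z1bar * k
    # (P - t r / C)(t k1 - Bc) = a^4, quadratic in t = theta*k
    A2 = -r * k1 / C
    A1 = P * k1 + Bc * r / C
    A0 = -P * Bc - a ** 4
    disc = A1 * A1 - 4.0 * A2 * A0
    if disc < 0:
        raise PolePlacementInfeasible(
            f"a = {a:g} beyond the order-2 reach (no real theta*k solves the "
            f"matching equations); bound = {order2_pole_bound(g1, g2):g}",
            bound=order2_pole_bound(g1, g2))
    roots = sorted(((-A1 + s * math.sqrt(disc)) / (2.0 * A2) for s in (+1.0, -1.0)))
    t = None
    for cand in roots:
        if cand > Bc / k1 and (P - cand * r / C) > 0:
            t = cand
            break
    if t is None:
        raise PolePlacementInfeasible(
            f"a = {a:g} beyond the order-2 reach (matching roots violate "
            f"positivity); bound = {order2_pole_bound(g1, g2):g}",
            bound=order2_pole_bound(g1, g2))
    q_ = a ** 4 / (t * k1 - Bc)
    return dict(P=P, delta=dk1 / k1, Bc=Bc, t=t, q_=q_, C=C)


def pole_placement(plant: ReactionNetwork, topology: str, a: float,
                   setpoint_value: float = 5.0, verify: bool = True) -> dict:
    """Place the four dominant closed-loop poles at s = -a on the
    gene-expression plant; returns the biomolecular parameters (as a
    ControllerSpec) plus the verified dominant poles.

    Raises PolePlacementInfeasible with the structural bound when the order-2
    design cannot reach the requested a.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    k1 = plant.rate_of("X1_to_X2")
    g1 = plant.rate_of("X1_deg")
    g2 = plant.rate_of("X2_deg")
    G = g1 + g2
    r = setpoint_value
    x1 = g2 * r / k1
    kappa1 = 1e-6 * x1

    if topology == "APID_ORDER2":
        m = _order2_match(a, g1, g2, k1, r)
        k = m["t"]                         # split theta*k as theta=1
        theta = 1.0
        beta = m["Bc"] / (k * k1)
        delta = m["delta"]
        mu = (theta - beta) * r
        z1 = m["C"] / k
        eta = m["q_"] / z1
        spec = ControllerSpec("APID_ORDER2", mechanism="DEGRADATION", mu=mu,
                              theta=theta, eta=eta, k=k, delta=delta, beta=beta,
                              kappa1=kappa1)
    elif topology == "APID_ORDER3":
        gamma0 = 4.0 * a - G
        if gamma0 <= 0:
            raise PolePlacementInfeasible(f"a = {a:g} too small: 4a <= gamma1+gamma2")
        dk1 = 6.0 * a * a - g1 * g2 - G * gamma0
        ktheta = a ** 4 / (k1 * gamma0)
        d0a0k1 = gamma0 * (g1 * g2 + dk1) + a ** 4 / gamma0 - 4.0 * a ** 3
        if dk1 < 0 or d0a0k1 < 0:
            raise PolePlacementInfeasible(
                f"a = {a:g}: order-3 matching needs a negative rate")
        alpha0 = gamma0
        spec = ControllerSpec("APID_ORDER3", mechanism="DEGRADATION", mu=r,
                              theta=1.0, eta=1e6, k=ktheta, delta=dk1 / k1,
                              alpha0=alpha0, gamma0=gamma0,
                              delta0=d0a0k1 / (alpha0 * k1), kappa1=kappa1)
    elif topology in ("APID_ORDER4_DEG", "APID_ORDER4_PROD"):
        d = 4.0 * a - G
        if d <= 0:
            raise PolePlacementInfeasible(f"a = {a:g} too small: 4a <= gamma1+gamma2")
        bk1 = 6.0 * a * a - g1 * g2 - G * d
        ck1 = g1 * g2 + bk1 + (a ** 4 / d - 4.0 * a ** 3) / d
        if bk1 < 0 or ck1 < 0 or bk1 < ck1:
            raise PolePlacementInfeasible(
                f"a = {a:g}: order-4 matching needs a negative rate "
                f"(b*k1 = {bk1:g}, c*k1 = {ck1:g})")
        k0 = d / r
        mu0 = ck1 * r / k1
        delta = (bk1 - ck1) / k1
        spec = ControllerSpec("APID_ORDER4_DEG", mechanism="DEGRADATION", mu=r,
                              theta=1.0, eta=1e6, eta0=1e6, k=a ** 4 / (k1 * d),
                              delta=delta, mu0=mu0, k0=k0, kappa1=kappa1)
    else:
        raise ValueError(f"pole placement not implemented for topology {topology!r}")

    out = {"spec": spec, "a": a}
    if verify:
        rep = closed_loop_stability(spec, plant)
        eigs = np.sort_complex(rep.eigenvalues)
        dom = sorted(eigs, key=lambda z: -z.real)[:4]
        out["dominant_poles"] = np.array(dom)
        out["max_rel_error"] = float(max(abs(z - (-a)) / a for z in dom))
    return out


# --------------------------------------------------------------------------
# headline quantities (bisections against the eigenvalue verdict)
# --------------------------------------------------------------------------

def _ai_like_verdict(rho, g1, g2, k1, theta, mu, eta, make_spec) -> bool:
    k = rho * g1 * g2 * (g1 + g2) / (k1 * theta)
    spec = make_spec(k)
    plant = gene_expression_plant(k1, g1, g2)
    try:
        rep = closed_loop_stability(spec, plant)
    except FixedPointError:
        return False
    return rep.stable


def critical_rho_ai(gamma1: float = 1.0, gamma2: float = 1.0, k1: float = 1.0,
                    theta: float = 1.0, mu: float = 5.0, eta: float = 1e6,
                    tol: float = 1e-4) -> float:
    """Critical rho at which the standalone aI loop loses stability, by
    bisection of the Jacobian eigenvalue verdict over the integral gain k."""
    def make(k):
        return ControllerSpec("AI", mu=mu, theta=theta, eta=eta, k=k)

    lo, hi = 0.25, 4.0
    assert _ai_like_verdict(lo, gamma1, gamma2, k1, theta, mu, eta, make)
    assert not _ai_like_verdict(hi, gamma1, gamma2, k1, theta, mu, eta, make)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _ai_like_verdict(mid, gamma1, gamma2, k1, theta, mu, eta, make):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def additive_rho_supremum(gamma1: float = 1.0, gamma2: float = 1.0, k1: float = 1.0,
                          theta: float = 1.0, mu: float = 5.0, eta: float = 1e6,
                          n: int = 1, n_kappa: int = 13, tol: float = 5e-3) -> float:
    """Largest rho for which some (alpha, kappa) of the Class-1 additive aPI
    stabilizes the gene-expression loop in the fast-sequestration limit
    (eigenvalue verdict; alpha searched up to the ergodicity threshold
    alpha_TH, kappa over six decades).

    The limit eta -> infinity is realized per operating point: eta is raised
    (beyond the ``eta`` floor) until the sequestration regime z2bar << z1bar
    holds, because at any fixed finite eta an alpha close enough to alpha_TH
    drives z1bar -> 0, leaves that regime, and stabilizes arbitrarily large
    rho -- an effect the asymptotic statement deliberately excludes.
    """
    r = mu / theta
    kappas = np.logspace(math.log10(r) - 4.0, math.log10(r) + 2.0, n_kappa)
    fracs = (0.25, 0.5, 0.75, 0.9, 0.97, 0.995, 0.999)
    plant = gene_expression_plant(k1, gamma1, gamma2)
    x1 = gamma2 * r / k1

    def stabilizable(rho: float) -> bool:
        k = rho * gamma1 * gamma2 * (gamma1 + gamma2) / (k1 * theta)
        for kap in kappas:
            ath = alpha_threshold(gamma1, gamma2, k1, r, kap, n)
            for f in fracs:
                z1 = (1.0 - f) * gamma1 * x1 / k
                eta_pt = min(max(eta, 1e4 * theta * r / z1 ** 2), 1e14)
                spec = ControllerSpec("API_CLASS1", mechanism="ADDITIVE", mu=mu,
                                      theta=theta, eta=eta_pt, k=k, alpha=f * ath,
                                      kappa=kap, n=n)
                try:
                    if closed_loop_stability(spec, plant).stable:
                        return True
                except FixedPointError:
                    continue
        return False

    lo, hi = 1.0, 2.0 + float(n)
    assert stabilizable(lo)
    while stabilizable(hi):
        hi *= 1.5
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stabilizable(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def degradation_asymptote(gamma1: float = 1.0, gamma2: float = 1.0,
                          k1: float = 0.003, theta: float = 1.0, mu: float = 5.0,
                          k: float = 0.5, eta: float = 1e6, kappa1: float = 1e-3,
                          delta_max: float = 1e6) -> dict:
    """Limiting real part of the complex eigenvalue pair of the Class-1
    degradation loop as delta grows (root-locus asymptote).

    Returns the limit sigma and the divisor d = -(gamma1+gamma2)/sigma
    (the asymptote claim is d = 2).  The plant is operated with x1bar >>
    kappa1 so the input degradation is saturated throughout the sweep.
    """
    plant = gene_expression_plant(k1, gamma1, gamma2)
    deltas = np.logspace(0, math.log10(delta_max), 13)
    sigma = None
    for d in deltas:
        spec = ControllerSpec("API_CLASS1", mechanism="DEGRADATION", mu=mu,
                              theta=theta, eta=eta, k=k, delta=d, kappa1=kappa1)
        rep = closed_loop_stability(spec, plant)
        cplx = rep.eigenvalues[np.abs(rep.eigenvalues.imag) > 1e-9]
        if cplx.size:
            sigma = float(np.max(cplx.real))
    if sigma is None:
        raise RuntimeError("no complex pair found along the delta sweep")
    return {"sigma": sigma, "divisor": -(gamma1 + gamma2) / sigma}
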