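"""Controller library: antithetic I, PI and PID topologies as reaction fragments.

All controllers share the antithetic integral motif: Z_1 is produced at a
reference rate g(mu, x_L), Z_2 is produced by the sensed output at rate
theta*x_L, and the pair annihilates at rate eta*z_1*z_2, so z_1 - z_2
integrates g(mu, x_L) - theta*x_L.  The proportional (P) action is appended
through one of three inhibition mechanisms (additive, multiplicative,
degradation) in one of three classes (inhibition of the input by the output,
by Z_2, or of Z_1's production by the output).  Derivative (D) action is
realized either by incoherent feedforward (orders 2 and 3), by a second
antithetic motif acting as a differentiator (order 4), or by zero-order /
autocatalytic integrators placed in feedback with themselves (the alternative
differentiators).

Every compiled fragment exposes its exact propensity formulas via
``ControllerFragment.describe`` so the realized kinetics can be audited.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from scipy.optimize import brentq

from .network import (
    Factor,
    NetworkValidationError,
    Propensity,
    Reaction,
    custom_composite,
    hill_activation,
    hill_repression,
    mass_action,
    saturating_degradation,
)

__all__ = [
    "TOPOLOGIES",
    "MECHANISMS",
    "ControllerSpec",
    "ControllerFragment",
    "ControllerSpecError",
    "compile_controller",
    "control_action",
    "setpoint",
]

TOPOLOGIES = (
    "AI",
    "API_CLASS1",
    "API_CLASS2",
    "API_CLASS3",
    "APID_ORDER2",
    "APID_ORDER3",
    "APID_ORDER4_PROD",
    "APID_ORDER4_DEG",
    "DIFF_INFLOW",
    "DIFF_OUTFLOW",
    "DIFF_AUTOCATALYTIC",
)

MECHANISMS = ("ADDITIVE", "MULTIPLICATIVE", "DEGRADATION")

#: topologies whose actuation includes a Class-1-style P component
_P_BEARING = {
    "API_CLASS1", "API_CLASS2", "API_CLASS3", "APID_ORDER2", "APID_ORDER3",
    "APID_ORDER4_PROD", "APID_ORDER4_DEG", "DIFF_INFLOW", "DIFF_OUTFLOW",
    "DIFF_AUTOCATALYTIC",
}

# topologies with a separable derivative channel (the order-2 design embeds
# its D action inseparably in the Z1 channel, so it reports no u_D)
_D_BEARING = {
    "APID_ORDER3", "APID_ORDER4_PROD", "APID_ORDER4_DEG",
    "DIFF_INFLOW", "DIFF_OUTFLOW", "DIFF_AUTOCATALYTIC",
}


class ControllerSpecError(ValueError):
    """Controller specification violates a structural constraint."""


@dataclass(frozen=True)
class ControllerFragment:
    """Species + reactions a controller contributes to the closed loop."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    roles: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def describe(self) -> str:
        lines = []
        for r in self.reactions:
            terms = [f"{r.propensity.rate:g}"]
            for f in r.propensity.factors:
                x = f.species
                if f.kind == "linear":
                    terms.append(x if f.power == 1 else f"{x}^{f.power}")
                elif f.kind == "hill_rep":
                    terms.append(f"1/(1+({x}/{f.kappa:g})^{f.n:g})")
                elif f.kind == "hill_act":
                    terms.append(f"({x}/{f.kappa:g})^{f.n:g}/(1+({x}/{f.kappa:g})^{f.n:g})")
                else:
                    terms.append(f"{x}/({x}+{f.kappa:g})")
            stoich = " ".join(f"{c:+d}{s}" for s, c in r.stoich.items())
            lines.append(f"{r.label:18s} [{self.roles.get(r.label, '-'):6s}] "
                         f"{stoich:24s} rate = {' * '.join(terms)}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ControllerSpec:
    """Topology + inhibition mechanism + per-component feedback type + rates.

    Rates are per-hour in arbitrary concentration units (the paper's gene
    expression examples run on an hour time base); the default reference
    mu/theta = 5 matches the setpoint used throughout the stochastic studies.
    """

    topology: str = "AI"
    mechanism: str = "DEGRADATION"
    # feedback type per component: "N" (negative) or "P" (positive feedback)
    i_sign: str = "N"
    p_sign: str = "N"
    d_sign: str = "N"
    # antithetic integral motif
    mu: float = 5.0          # reference production of Z1
    theta: float = 1.0       # output sensing gain
    eta: float = 1000.0      # sequestration rate
    k: float = 0.1           # integral actuation gain
    # proportional component
    alpha: float = 0.0       # additive repression strength
    kappa: float = 1.0       # repression coefficient
    n: int = 1               # Hill coefficient
    delta: float = 0.0       # degradation-inhibition strength
    kappa1: float = 0.01     # Michaelis constant of input degradation
    # derivative components
    beta: float = 0.0        # order-2: catalytic Z1 production by the output
    alpha0: float = 0.0      # order-3: Z3 production by the output
    gamma0: float = 1.0      # order-3: Z3 decay
    delta0: float = 0.0      # order-3: Z3 actuation strength
    mu0: float = 0.0         # order-4 / alt diff: constitutive rate
    eta0: float = 1000.0     # order-4: differentiator sequestration
    k0: float = 0.0          # order-4 / alt diff: feedback gain g
    kappa0: float = 0.1      # order-4 PROD repression / alt diff Michaelis constant
    kappa_d: float = 1.0     # inflow differentiator Z3-repression coefficient
    z3_init: float = 1.0     # autocatalytic differentiator initial value
    kappa_act: float = 0.0   # optional saturation of the k*z1 actuation (0 = linear)

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ControllerSpecError(f"unknown topology {self.topology!r}")
        if self.mechanism not in MECHANISMS:
            raise ControllerSpecError(f"unknown mechanism {self.mechanism!r}")
        for sgn in (self.i_sign, self.p_sign, self.d_sign):
            if sgn not in ("N", "P"):
                raise ControllerSpecError(f"feedback sign must be 'N' or 'P', got {sgn!r}")
        for name in ("mu", "theta", "eta", "k", "alpha", "kappa", "delta", "kappa1",
                     "beta", "alpha0", "gamma0", "delta0", "mu0", "eta0", "k0",
                     "kappa0", "kappa_d", "z3_init", "kappa_act"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ControllerSpecError(f"rate parameter {name} must be nonnegative, got {v}")
        if int(self.n) != self.n or self.n < 1:
            raise ControllerSpecError(f"Hill coefficient n must be an integer >= 1, got {self.n}")
        if self.topology == "APID_ORDER2" and not self.beta < self.theta:
            raise ControllerSpecError(
                f"order-2 aPID requires beta < theta (got beta={self.beta}, theta={self.theta}); "
                "the setpoint mu/(theta-beta) would not exist")
        if self.topology == "API_CLASS3" and self.mechanism == "DEGRADATION":
            raise ControllerSpecError(
                "Class 3 with degradation inhibition destroys robust perfect adaptation "
                "and is not a supported controller")
        if self.topology == "APID_ORDER3" and self.delta > 0:
            if self.delta * self.gamma0 > 2.0 * self.delta0 * self.alpha0:
                raise ControllerSpecError(
                    "order-3 aPID outside the PD regime: requires "
                    "delta*gamma0 <= 2*delta0*alpha0 so that K_P <= K_D*omega")
        if self.topology == "DIFF_AUTOCATALYTIC" and not self.z3_init > 0:
            raise ControllerSpecError(
                "the autocatalytic differentiator needs z3_init > 0: z3 = 0 is an "
                "invariant (absorbing) state of the self-producing species")

    # ------------------------------------------------------------------
    @property
    def n_controller_species(self) -> int:
        return {"AI": 2, "API_CLASS1": 2, "API_CLASS2": 2, "API_CLASS3": 2,
                "APID_ORDER2": 2, "APID_ORDER3": 3,
                "APID_ORDER4_PROD": 4, "APID_ORDER4_DEG": 4,
                "DIFF_INFLOW": 3, "DIFF_OUTFLOW": 3, "DIFF_AUTOCATALYTIC": 3,
                }[self.topology]

    # ------------------------------------------------------------------
    def _act_integral(self, x_in: str, x_out: str, reactions, roles) -> None:
        """The z1-driven actuation h+ (or h- for P-type), with the mechanism's
        multiplicative inhibition folded in where the class dictates."""
        factors = [Factor("Z1")]
        if self.kappa_act > 0:  # optional saturation of the linear term
            factors = [Factor("Z1", "hill_act", kappa=self.kappa_act, n=1)]
        if self.topology in _P_BEARING and self.mechanism == "MULTIPLICATIVE" \
                and self.topology != "API_CLASS3":
            inhib = "Z2" if self.topology == "API_CLASS2" else x_out
            factors.append(Factor(inhib, "hill_rep", kappa=self.kappa, n=self.n))
        if self.i_sign == "N":
            reactions.append(Reaction("act_I", {x_in: +1},
                                      custom_composite(self.k, factors)))
        else:
            factors.append(Factor(x_in, "michaelis", kappa=self.kappa1))
            reactions.append(Reaction("act_I", {x_in: -1},
                                      custom_composite(self.k, factors)))
        roles["act_I"] = "act_I"

    def compile(self, plant_input: str = "X1", plant_output: str = "X2") -> ControllerFragment:
        """Compile the spec to a reaction fragment over Z_1..Z_M."""
        x_in, x_out = plant_input, plant_output
        M = self.n_controller_species
        z = tuple(f"Z{i + 1}" for i in range(M))
        reactions: list[Reaction] = []
        roles: dict[str, str] = {}
        initial: dict[str, float] = {}

        # --- reference production g(mu, x_L) -> Z1 -------------------------
        if self.topology == "API_CLASS3":
            if self.mechanism == "MULTIPLICATIVE":
                reactions.append(Reaction("ref", {"Z1": +1},
                                          hill_repression(self.mu, x_out, self.kappa, self.n)))
            else:  # additive: constitutive mu plus repressed alpha-term
                reactions.append(Reaction("ref", {"Z1": +1}, mass_action(self.mu)))
                reactions.append(Reaction("ref_P", {"Z1": +1},
                                          hill_repression(self.alpha, x_out, self.kappa, self.n)))
                roles["ref_P"] = "ref"
        else:
            reactions.append(Reaction("ref", {"Z1": +1}, mass_action(self.mu)))
        roles["ref"] = "ref"

        # --- sensing and sequestration -------------------------------------
        reactions.append(Reaction("sense", {"Z2": +1}, mass_action(self.theta, x_out)))
        roles["sense"] = "sense"
        reactions.append(Reaction("seq", {"Z1": -1, "Z2": -1},
                                  mass_action(self.eta, "Z1", "Z2")))
        roles["seq"] = "seq"

        # --- integral (+ multiplicative-P) actuation ------------------------
        self._act_integral(x_in, x_out, reactions, roles)

        # --- additive / degradation P component ----------------------------
        if self.topology in _P_BEARING and self.topology != "API_CLASS3":
            inhib = "Z2" if self.topology == "API_CLASS2" else x_out
            if self.mechanism == "ADDITIVE" and self.alpha > 0:
                if self.p_sign == "N":
                    reactions.append(Reaction("act_P", {x_in: +1},
                                              hill_repression(self.alpha, inhib, self.kappa, self.n)))
                else:
                    reactions.append(Reaction("act_P", {x_in: +1},
                                              hill_activation(self.alpha, inhib, self.kappa, self.n)))
                roles["act_P"] = "act_P"
            elif self.mechanism == "DEGRADATION" and self.delta > 0:
                if self.p_sign == "N":
                    reactions.append(Reaction("act_P", {x_in: -1},
                                              saturating_degradation(self.delta, x_in, self.kappa1,
                                                                     modifiers=[inhib])))
                else:
                    reactions.append(Reaction("act_P", {x_in: +1},
                                              mass_action(self.delta, inhib)))
                roles["act_P"] = "act_P"

        # --- derivative components -----------------------------------------
        if self.topology == "APID_ORDER2":
            reactions.append(Reaction("d_feed", {"Z1": +1}, mass_action(self.beta, x_out)))
            roles["d_feed"] = "diff"
        elif self.topology == "APID_ORDER3":
            reactions.append(Reaction("d_prod", {"Z3": +1}, mass_action(self.alpha0, x_out)))
            reactions.append(Reaction("d_decay", {"Z3": -1}, mass_action(self.gamma0, "Z3")))
            roles["d_prod"] = roles["d_decay"] = "diff"
            if self.d_sign == "N":  # delayed positive arm of the IFFL
                reactions.append(Reaction("act_D", {x_in: +1}, mass_action(self.delta0, "Z3")))
            else:
                reactions.append(Reaction("act_D", {x_in: -1},
                                          saturating_degradation(self.delta0, x_in, self.kappa1,
                                                                 modifiers=["Z3"])))
            roles["act_D"] = "act_D"
        elif self.topology in ("APID_ORDER4_PROD", "APID_ORDER4_DEG"):
            reactions.append(Reaction("d_ref", {"Z3": +1}, mass_action(self.mu0)))
            reactions.append(Reaction("d_seq", {"Z3": -1, "Z4": -1},
                                      mass_action(self.eta0, "Z3", "Z4")))
            roles["d_ref"] = roles["d_seq"] = "diff"
            if self.topology == "APID_ORDER4_PROD":
                # mutual production of Z4 and X1; g increasing in z3, decreasing in x_L
                g = custom_composite(self.k0, [Factor("Z3"),
                                               Factor(x_out, "hill_rep", kappa=self.kappa0, n=1)])
                stoich = {"Z4": +1, x_in: +1 if self.d_sign == "N" else -1}
                if stoich[x_in] < 0:
                    g = custom_composite(self.k0, g.factors +
                                         (Factor(x_in, "michaelis", kappa=self.kappa1),))
                reactions.append(Reaction("act_D", stoich, g))
            else:
                # produce Z4 while degrading X1; g increasing in z3 and x_L
                fac = (Factor("Z3"), Factor(x_out))
                if self.d_sign == "N":
                    g = custom_composite(self.k0, fac + (Factor(x_in, "michaelis",
                                                                kappa=self.kappa1),))
                    reactions.append(Reaction("act_D", {"Z4": +1, x_in: -1}, g))
                else:
                    g = custom_composite(self.k0, fac)
                    reactions.append(Reaction("act_D", {"Z4": +1, x_in: +1}, g))
            roles["act_D"] = "act_D"
        elif self.topology in ("DIFF_INFLOW", "DIFF_OUTFLOW", "DIFF_AUTOCATALYTIC"):
            if self.topology == "DIFF_OUTFLOW":
                # constant inflow; u_D = g(z3, x_L) drains Z3 (zero-order in z3)
                reactions.append(Reaction("d_in", {"Z3": +1}, mass_action(self.mu0)))
                g = custom_composite(self.k0, (Factor(x_out),
                                               Factor("Z3", "michaelis", kappa=self.kappa0)))
                reactions.append(Reaction("d_out", {"Z3": -1}, g))
            elif self.topology == "DIFF_INFLOW":
                # u_D = g(z3, x_L) produces Z3; zero-order degradation drains it
                g = custom_composite(self.k0, (Factor(x_out),
                                               Factor("Z3", "hill_rep", kappa=self.kappa_d, n=1)))
                reactions.append(Reaction("d_in", {"Z3": +1}, g))
                reactions.append(Reaction("d_out", {"Z3": -1},
                                          saturating_degradation(self.mu0, "Z3", self.kappa0)))
            else:  # DIFF_AUTOCATALYTIC: Z3 produces itself; g(0, x_L) = 0
                reactions.append(Reaction("d_in", {"Z3": +1},
                                          saturating_degradation(self.mu0, "Z3", self.kappa0)))
                g = mass_action(self.k0, "Z3", x_out)
                reactions.append(Reaction("d_out", {"Z3": -1}, g))
                initial["Z3"] = self.z3_init
            roles["d_in"] = roles["d_out"] = "diff"
            act = custom_composite(self.k0, g.factors + (Factor(x_in, "michaelis",
                                                                kappa=self.kappa1),))
            if self.d_sign == "N":
                reactions.append(Reaction("act_D", {x_in: -1}, act))
            else:
                reactions.append(Reaction("act_D", {x_in: +1}, g))
            roles["act_D"] = "act_D"

        return ControllerFragment(z, tuple(reactions), roles, initial)

    # ------------------------------------------------------------------
    def control_action(self, state: Mapping[str, float],
                       plant_input: str = "X1", plant_output: str = "X2"):
        """(u, u_I, u_D) at a state given as a species->value mapping.

        u = h+ - h- is the net rate the controller applies to the plant
        input; u_D is reported only for derivative-bearing topologies.
        """
        frag = self.compile(plant_input, plant_output)
        u = ui = 0.0
        ud = 0.0 if self.topology in _D_BEARING else None
        for r in frag.reactions:
            role = frag.roles.get(r.label)
            if role not in ("act_I", "act_P", "act_D"):
                continue
            sign = 1.0 if r.stoich.get(plant_input, 0) > 0 else -1.0
            v = r.propensity.value(state)
            u += sign * v
            if role == "act_I":
                ui += sign * v
            if role == "act_D":
                ud += sign * v  # type: ignore[operator]
        return u, ui, ud

    # ------------------------------------------------------------------
    def setpoint(self) -> float:
        """The output steady state solving g(mu, x) = theta*x.

        mu/theta for the affine-reference controllers, mu/(theta - beta) for
        the order-2 aPID, and the positive root of a degree-(n+1) polynomial
        for Class 3 (unique because g is decreasing in x_L).
        """
        if self.theta <= 0:
            raise ControllerSpecError("setpoint requires theta > 0")
        if self.topology == "APID_ORDER2":
            return self.mu / (self.theta - self.beta)
        if self.topology == "API_CLASS3":
            if self.mechanism == "MULTIPLICATIVE":
                def f(x):
                    return self.mu / (1.0 + (x / self.kappa) ** self.n) - self.theta * x
            else:
                def f(x):
                    return (self.mu + self.alpha / (1.0 + (x / self.kappa) ** self.n)
                            - self.theta * x)
            hi = (self.mu + self.alpha) / self.theta + 1.0
            return float(brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14))
        return self.mu / self.theta


def compile_controller(spec: ControllerSpec, plant_input: str = "X1",
                       plant_output: str = "X2") -> ControllerFragment:
    return spec.compile(plant_input, plant_output)


def control_action(spec: ControllerSpec, state: Mapping[str, float],
                   plant_input: str = "X1", plant_output: str = "X2"):
    return spec.control_action(state, plant_input, plant_output)


def setpoint(spec: ControllerSpec) -> float:
    return spec.setpoint()


def warn_class2_additive_regime(spec: ControllerSpec, gamma1: float, gamma2: float,
                                k1: float) -> bool:
    """Warn when a Class-2 additive controller enters the regime where Z2
    takes over the integral action (alpha > gamma1*gamma2*r/k1); the analysis
    of that regime is out of scope."""
    if spec.topology == "API_CLASS2" and spec.mechanism == "ADDITIVE":
        r = spec.setpoint()
        if spec.alpha > gamma1 * gamma2 * r / k1:
            warnings.warn(
                "Class-2 additive aPI with alpha > gamma1*gamma2*r/k1: Z2 becomes "
                "responsible for the integral action; this regime is not analyzed",
                stacklevel=2)
            return True
    return False
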