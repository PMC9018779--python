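"""Reaction-network data model for biomolecular feedback control.

A biochemical reaction network (BCRN) is the triplet (species, stoichiometry,
propensities): ``L`` species, ``K`` reactions with integer stoichiometry
vectors (the columns of ``S``) and nonnegative propensity functions.  The same
object serves two interpretations: concentrations with deterministic
mass-action/Hill kinetics, and copy numbers driving a continuous-time Markov
chain.  All reactions in this package are at most bimolecular between distinct
species, so the two interpretations share the same propensity formulas.

Propensities come from a closed vocabulary of named forms (mass action,
Hill activation/repression, Michaelis–Menten saturating degradation) plus a
``custom_composite`` product of elementary factors, so that networks are fully
serializable to JSON and have exact analytic derivatives (no finite
differences anywhere in the linear analysis).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Factor",
    "Propensity",
    "Reaction",
    "ReactionNetwork",
    "ClosedLoopNetwork",
    "NetworkValidationError",
    "CompositionError",
    "mass_action",
    "hill_activation",
    "hill_repression",
    "saturating_degradation",
    "custom_composite",
    "build_reaction_network",
    "compose_closed_loop",
    "evaluate_propensities",
    "read_network",
    "write_network",
    "network_to_dict",
    "network_from_dict",
]

SCHEMA_VERSION = 1

_FACTOR_KINDS = ("linear", "hill_act", "hill_rep", "michaelis")


class NetworkValidationError(ValueError):
    """A network, reaction or propensity violates a structural contract."""


class CompositionError(ValueError):
    """Plant and controller cannot be wired together as requested."""


# --------------------------------------------------------------------------
# propensity factors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Factor:
    """One multiplicative term of a propensity, depending on one species.

    kind:
      * ``linear``    -- x**power
      * ``hill_act``  -- (x/kappa)**n / (1 + (x/kappa)**n)
      * ``hill_rep``  -- 1 / (1 + (x/kappa)**n)
      * ``michaelis`` -- x / (x + kappa)
    """

    species: str
    kind: str = "linear"
    kappa: float = 1.0
    n: float = 1.0
    power: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _FACTOR_KINDS:
            raise NetworkValidationError(
                f"unknown factor kind {self.kind!r}; expected one of {_FACTOR_KINDS}"
            )
        if self.kind in ("hill_act", "hill_rep", "michaelis") and self.kappa < 0:
            raise NetworkValidationError(f"factor on {self.species}: kappa must be >= 0")
        if self.kind in ("hill_act", "hill_rep") and self.n < 1:
            raise NetworkValidationError(f"factor on {self.species}: Hill n must be >= 1")
        if self.kind == "linear" and self.power < 1:
            raise NetworkValidationError("linear factor power must be >= 1")

    @property
    def vanishes_at_zero(self) -> bool:
        """True if the factor evaluates to 0 when its species is 0."""
        return self.kind in ("linear", "hill_act", "michaelis")

    def value(self, x: float) -> float:
        if self.kind == "linear":
            return x ** self.power
        if self.kind == "michaelis":
            denom = x + self.kappa
            return x / denom if denom > 0 else 0.0
        q = (x / self.kappa) ** self.n if self.kappa > 0 else (math.inf if x > 0 else 0.0)
        if self.kind == "hill_act":
            return q / (1.0 + q) if math.isfinite(q) else 1.0
        # hill_rep
        return 1.0 / (1.0 + q) if math.isfinite(q) else 0.0

    def derivative(self, x: float) -> float:
        if self.kind == "linear":
            return self.power * x ** (self.power - 1)
        if self.kind == "michaelis":
            denom = x + self.kappa
            return self.kappa / denom ** 2 if denom > 0 else 0.0
        if self.kappa <= 0:
            return 0.0
        q = (x / self.kappa) ** self.n
        if x == 0.0:
            if self.n == 1:
                slope = 1.0 / self.kappa
                return slope if self.kind == "hill_act" else -slope
            return 0.0
        dq = self.n * q / x
        if self.kind == "hill_act":
            return dq / (1.0 + q) ** 2
        return -dq / (1.0 + q) ** 2


@dataclass(frozen=True)
class Propensity:
    """rate * product of factors; ``form`` names the biochemical reading."""

    rate: float
    factors: tuple[Factor, ...] = ()
    form: str = "mass_action"

    def __post_init__(self) -> None:
        if not (self.rate >= 0.0 and math.isfinite(self.rate)):
            raise NetworkValidationError(f"propensity rate must be nonnegative and finite, got {self.rate}")

    def species_names(self) -> tuple[str, ...]:
        return tuple(f.species for f in self.factors)

    def value(self, state: Mapping[str, float]) -> float:
        v = self.rate
        for f in self.factors:
            if v == 0.0:
                return 0.0
            v *= f.value(state[f.species])
        return v

    def gradient(self, state: Mapping[str, float]) -> dict[str, float]:
        """d(propensity)/d(species) for every species appearing in a factor."""
        vals = [f.value(state[f.species]) for f in self.factors]
        grad: dict[str, float] = {}
        for i, f in enumerate(self.factors):
            g = self.rate * f.derivative(state[f.species])
            for j, vj in enumerate(vals):
                if j != i:
                    g *= vj
            grad[f.species] = grad.get(f.species, 0.0) + g
        return grad

    def with_rate(self, rate: float) -> "Propensity":
        return replace(self, rate=rate)


def mass_action(rate: float, *species: str, orders: Mapping[str, int] | None = None) -> Propensity:
    orders = dict(orders or {})
    for s in species:
        orders[s] = orders.get(s, 0) + 1
    factors = tuple(Factor(s, "linear", power=p) for s, p in orders.items())
    return Propensity(rate, factors, form="mass_action")


def hill_repression(rate: float, species: str, kappa: float, n: float = 1.0,
                    modifiers: Sequence[str] = ()) -> Propensity:
    factors = (Factor(species, "hill_rep", kappa=kappa, n=n),) + tuple(
        Factor(m) for m in modifiers)
    return Propensity(rate, factors, form="hill_repression")


def hill_activation(rate: float, species: str, kappa: float, n: float = 1.0,
                    modifiers: Sequence[str] = ()) -> Propensity:
    factors = (Factor(species, "hill_act", kappa=kappa, n=n),) + tuple(
        Factor(m) for m in modifiers)
    return Propensity(rate, factors, form="hill_activation")


def saturating_degradation(rate: float, substrate: str, kappa: float,
                           modifiers: Sequence[str] = ()) -> Propensity:
    """Michaelis-type degradation: rate * prod(modifiers) * x/(x+kappa)."""
    factors = (Factor(substrate, "michaelis", kappa=kappa),) + tuple(
        Factor(m) for m in modifiers)
    return Propensity(rate, factors, form="saturating_degradation")


def custom_composite(rate: float, factors: Iterable[Factor]) -> Propensity:
    return Propensity(rate, tuple(factors), form="custom_composite")


# --------------------------------------------------------------------------
# reactions and networks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    label: str
    stoich: Mapping[str, int]
    propensity: Propensity

    def __post_init__(self) -> None:
        for s, c in self.stoich.items():
            if not isinstance(c, (int, np.integer)):
                raise NetworkValidationError(
                    f"reaction {self.label!r}: stoichiometry for {s} must be an integer, got {c!r}")
        object.__setattr__(self, "stoich", dict(self.stoich))

    @property
    def reactants(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.stoich.items() if c < 0)


@dataclass(frozen=True)
class ReactionNetwork:
    """Validated BCRN with species order fixed at construction."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    input_species: str | None = None
    output_species: str | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise NetworkValidationError("duplicate species names")
        idx = {s: i for i, s in enumerate(self.species)}
        object.__setattr__(self, "_index", idx)
        for r in self.reactions:
            for s in r.stoich:
                if s not in idx:
                    raise NetworkValidationError(
                        f"reaction {r.label!r}: stoichiometry references undeclared species {s!r}")
            for s in r.propensity.species_names():
                if s not in idx:
                    raise NetworkValidationError(
                        f"reaction {r.label!r}: propensity references undeclared species {s!r}")
            # nonnegativity guarantee: every consumed species must make the
            # propensity vanish when it reaches zero copies
            covered = {f.species for f in r.propensity.factors if f.vanishes_at_zero}
            for s in r.reactants:
                if s not in covered:
                    raise NetworkValidationError(
                        f"reaction {r.label!r}: consumes {s!r} but its propensity does not "
                        f"vanish at {s}=0")
        for attr in ("input_species", "output_species"):
            v = getattr(self, attr)
            if v is not None and v not in idx:
                raise NetworkValidationError(f"{attr} {v!r} not among species")

    # --- basic structure ---------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self._index[name]

    @property
    def input_index(self) -> int:
        if self.input_species is None:
            raise NetworkValidationError("network declares no input species")
        return self._index[self.input_species]

    @property
    def output_index(self) -> int:
        if self.output_species is None:
            raise NetworkValidationError("network declares no output species")
        return self._index[self.output_species]

    def stoichiometry(self) -> np.ndarray:
        """L x K integer stoichiometry matrix (one column per reaction)."""
        S = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for k, r in enumerate(self.reactions):
            for s, c in r.stoich.items():
                S[self._index[s], k] = c
        return S

    # --- evaluation ---------------------------------------------------------
    def _state_map(self, state: Sequence[float]) -> dict[str, float]:
        return {s: float(state[i]) for i, s in enumerate(self.species)}

    def propensities(self, state: Sequence[float]) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species,):
            raise NetworkValidationError(
                f"state has length {state.shape}, expected {self.n_species}")
        if np.any(state < 0):
            raise NetworkValidationError("state must be nonnegative")
        m = self._state_map(state)
        return np.array([r.propensity.value(m) for r in self.reactions], dtype=float)

    def propensity_jacobian(self, state: Sequence[float]) -> np.ndarray:
        """K x L matrix of exact partial derivatives of the propensities."""
        state = np.asarray(state, dtype=float)
        m = self._state_map(state)
        out = np.zeros((self.n_reactions, self.n_species))
        for k, r in enumerate(self.reactions):
            for s, g in r.propensity.gradient(m).items():
                out[k, self._index[s]] += g
        return out

    def rhs(self, state: Sequence[float]) -> np.ndarray:
        """Deterministic right-hand side S @ lambda(x)."""
        return self.stoichiometry() @ self.propensities(state)

    def jacobian(self, state: Sequence[float]) -> np.ndarray:
        """Exact Jacobian of the deterministic dynamics, S @ dlambda/dx."""
        return self.stoichiometry() @ self.propensity_jacobian(state)

    # --- editing ------------------------------------------------------------
    def with_rate(self, reaction_label: str, rate: float) -> "ReactionNetwork":
        """Copy of the network with one reaction's rate constant replaced."""
        new = []
        hit = False
        for r in self.reactions:
            if r.label == reaction_label:
                new.append(Reaction(r.label, r.stoich, r.propensity.with_rate(rate)))
                hit = True
            else:
                new.append(r)
        if not hit:
            raise KeyError(f"no reaction labelled {reaction_label!r}")
        return replace(self, reactions=tuple(new), _index={})

    def rate_of(self, reaction_label: str) -> float:
        for r in self.reactions:
            if r.label == reaction_label:
                return r.propensity.rate
        raise KeyError(f"no reaction labelled {reaction_label!r}")


@dataclass(frozen=True)
class ClosedLoopNetwork(ReactionNetwork):
    """Plant + controller with the stoichiometry partition of the framework.

    Plant species come first (input X_1 at index 0 by convention, output X_L
    at ``n_plant - 1`` unless the plant declares otherwise), controller
    species Z_1..Z_M after them.  Controller reactions occupy the trailing
    columns of the closed-loop stoichiometry matrix.
    """

    n_plant: int = 0
    n_plant_reactions: int = 0
    controller_meta: dict = field(default_factory=dict, compare=False)

    @property
    def plant_species(self) -> tuple[str, ...]:
        return self.species[: self.n_plant]

    @property
    def controller_species(self) -> tuple[str, ...]:
        return self.species[self.n_plant:]

    @property
    def controller_reactions(self) -> tuple[Reaction, ...]:
        return self.reactions[self.n_plant_reactions:]

    def partition(self) -> dict[str, np.ndarray]:
        """Rows S_1 (input), S_L (output), S_c (controller) of the controller
        reaction block."""
        S = self.stoichiometry()[:, self.n_plant_reactions:]
        return {
            "S_1": S[self.input_index: self.input_index + 1, :],
            "S_L": S[self.output_index: self.output_index + 1, :],
            "S_c": S[self.n_plant:, :],
        }

    def actuation_value(self, state: Sequence[float]) -> tuple[float, float, float | None]:
        """(u, u_I, u_D) evaluated at a state.

        u is the net rate applied to the plant input species by the
        controller's actuation reactions (h+ - h-); u_I is the contribution
        of the integral channel (the Z_1-driven actuation); u_D the
        derivative channel where the topology defines one, else None.
        """
        m = self._state_map(np.asarray(state, dtype=float))
        u = ui = 0.0
        ud: float | None = None
        has_d = False
        for r in self.controller_reactions:
            role = self.controller_meta.get("roles", {}).get(r.label)
            if role is None:
                continue
            sign = 1.0 if r.stoich.get(self.input_species, 0) > 0 else -1.0
            v = r.propensity.value(m)
            if role in ("act_I", "act_P", "act_D"):
                u += sign * v
            if role == "act_I":
                ui += sign * v
            if role == "act_D":
                ud = (ud or 0.0) + sign * v
                has_d = True
        if not has_d:
            ud = None
        return u, ui, ud


# --------------------------------------------------------------------------
# the spec operations
# --------------------------------------------------------------------------

def build_reaction_network(species: Sequence[str],
                           reactions: Sequence[Reaction],
                           input_species: str | None = None,
                           output_species: str | None = None) -> ReactionNetwork:
    return ReactionNetwork(tuple(species), tuple(reactions),
                           input_species=input_species, output_species=output_species)


def compose_closed_loop(plant: ReactionNetwork, controller) -> ClosedLoopNetwork:
    """Wire a controller (a ControllerSpec) in feedback with a plant.

    The controller may only sense the plant output and actuate the plant
    input; any propensity referencing another plant species is a composition
    error.
    """
    from .controllers import ControllerSpec  # local import to avoid a cycle

    if not isinstance(controller, ControllerSpec):
        raise TypeError("controller must be a ControllerSpec")
    if plant.input_species is None or plant.output_species is None:
        raise CompositionError("plant must declare input and output species")
    frag = controller.compile(plant.input_species, plant.output_species)
    allowed = set(frag.species) | {plant.input_species, plant.output_species}
    for r in frag.reactions:
        for s in set(r.stoich) | set(r.propensity.species_names()):
            if s in plant.species and s not in (plant.input_species, plant.output_species):
                raise CompositionError(
                    f"controller reaction {r.label!r} touches plant species {s!r}; only the "
                    f"declared input {plant.input_species!r} and output "
                    f"{plant.output_species!r} are accessible")
            if s not in allowed:
                raise CompositionError(
                    f"controller reaction {r.label!r} references unknown species {s!r}")
        for s, c in r.stoich.items():
            if c != 0 and s == plant.output_species:
                raise CompositionError(
                    f"controller reaction {r.label!r} changes the output species; sensing "
                    "must be catalytic")
    species = plant.species + frag.species
    reactions = plant.reactions + frag.reactions
    return ClosedLoopNetwork(
        species=tuple(species), reactions=tuple(reactions),
        input_species=plant.input_species, output_species=plant.output_species,
        n_plant=plant.n_species, n_plant_reactions=plant.n_reactions,
        controller_meta={"roles": frag.roles, "spec": controller},
    )


def evaluate_propensities(network: ReactionNetwork, state: Sequence[float]) -> np.ndarray:
    return network.propensities(state)


# --------------------------------------------------------------------------
# JSON serialization (schema 1)
# --------------------------------------------------------------------------

def _propensity_to_dict(p: Propensity) -> dict:
    if p.form == "mass_action":
        return {"form": "mass_action", "params": {"rate": p.rate},
                "modifiers": [f.species for f in p.factors for _ in range(f.power)]}
    if p.form in ("hill_repression", "hill_activation"):
        main = p.factors[0]
        return {"form": p.form, "species": main.species,
                "params": {"rate": p.rate, "kappa": main.kappa, "n": main.n},
                "modifiers": [f.species for f in p.factors[1:]]}
    if p.form == "saturating_degradation":
        main = p.factors[0]
        return {"form": p.form, "species": main.species,
                "params": {"rate": p.rate, "kappa": main.kappa},
                "modifiers": [f.species for f in p.factors[1:]]}
    return {"form": "custom_composite", "params": {"rate": p.rate},
            "factors": [{"species": f.species, "kind": f.kind, "kappa": f.kappa,
                         "n": f.n, "power": f.power} for f in p.factors]}


def _propensity_from_dict(d: dict, where: str) -> Propensity:
    form = d.get("form")
    params = d.get("params", {})
    try:
        rate = float(params["rate"])
    except KeyError as e:
        raise NetworkValidationError(f"{where}: propensity params missing 'rate'") from e
    mods = list(d.get("modifiers", []))
    if form == "mass_action":
        orders: dict[str, int] = {}
        for s in mods:
            orders[s] = orders.get(s, 0) + 1
        return mass_action(rate, orders=orders)
    if form == "hill_repression":
        return hill_repression(rate, d["species"], float(params["kappa"]),
                               float(params.get("n", 1)), mods)
    if form == "hill_activation":
        return hill_activation(rate, d["species"], float(params["kappa"]),
                               float(params.get("n", 1)), mods)
    if form == "saturating_degradation":
        return saturating_degradation(rate, d["species"], float(params["kappa"]), mods)
    if form == "custom_composite":
        factors = [Factor(f["species"], f.get("kind", "linear"), float(f.get("kappa", 1.0)),
                          float(f.get("n", 1.0)), int(f.get("power", 1)))
                   for f in d.get("factors", [])]
        return custom_composite(rate, factors)
    raise NetworkValidationError(f"{where}: unknown propensity form {form!r}")


def network_to_dict(net: ReactionNetwork) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "species": list(net.species),
        "input": net.input_species,
        "output": net.output_species,
        "reactions": [
            {"label": r.label, "stoich": {s: int(c) for s, c in r.stoich.items() if c != 0},
             "propensity": _propensity_to_dict(r.propensity)}
            for r in net.reactions
        ],
    }


def network_from_dict(d: dict) -> ReactionNetwork:
    if d.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise NetworkValidationError(f"unsupported schema version {d.get('schema')!r}")
    species = d["species"]
    reactions = []
    for i, rd in enumerate(d.get("reactions", [])):
        where = f"reactions[{i}] ({rd.get('label', '?')})"
        stoich = {}
        for s, c in rd.get("stoich", {}).items():
            if float(c) != int(c):
                raise NetworkValidationError(f"{where}: non-integer stoichiometry {c!r} for {s}")
            stoich[s] = int(c)
        prop = _propensity_from_dict(rd.get("propensity", {}), where)
        reactions.append(Reaction(rd.get("label", f"R{i + 1}"), stoich, prop))
    return build_reaction_network(species, reactions,
                                  input_species=d.get("input"),
                                  output_species=d.get("output"))


def write_network(net: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=2)


def read_network(path) -> ReactionNetwork:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise NetworkValidationError(f"malformed network JSON: {e}") from e
    return network_from_dict(d)
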