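"""Plant fixtures: the gene-expression module, unstable chains, random chains.

The two-species gene expression network (mRNA X1 translated to protein X2) is
the workhorse plant of the deterministic and stochastic stability studies.
The six-species chain with output-to-X2 feedback degradation reproduces the
unstable plant used to stress the higher-order PID designs; its default rates
are chosen (and documented in the methods note) so that the open loop is
unstable and a standalone antithetic integral controller cannot stabilize it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import (
    ReactionNetwork,
    Reaction,
    build_reaction_network,
    mass_action,
    saturating_degradation,
)

__all__ = [
    "PlantSpec",
    "DisturbanceEvent",
    "gene_expression_plant",
    "chain_feedback_plant",
    "random_plant",
    "CHAIN6_DEFAULTS",
]


@dataclass(frozen=True)
class PlantSpec:
    """Chain plant: X_i -> X_i + X_{i+1} at k_i, X_i -> 0 at gamma_i, with an
    optional feedback degradation of X_2 by the output at gamma_F.

    The feedback is bilinear (gamma_F * x2 * xL) when ``kappa_F`` is None;
    with a finite ``kappa_F`` it is protease-like and saturates in its
    substrate, gamma_F * xL * x2/(x2 + kappa_F).  Only the saturating form
    can destabilize the open loop: for the bilinear form the DC loop gain is
    gamma_F*x6bar/(gamma2 + gamma_F*x6bar) < 1 at any rates, so the loop is
    structurally stable.
    """

    L: int
    k: tuple[float, ...]        # length L-1 production rates
    gamma: tuple[float, ...]    # length L degradation rates
    gamma_F: float = 0.0
    kappa_F: float | None = None

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("a chain plant needs at least 2 species")
        if len(self.k) != self.L - 1 or len(self.gamma) != self.L:
            raise ValueError(f"need {self.L - 1} production and {self.L} degradation rates")
        if any(v < 0 for v in self.k) or any(v < 0 for v in self.gamma) or self.gamma_F < 0:
            raise ValueError("plant rates must be nonnegative")
        if self.gamma_F > 0 and self.L < 3:
            raise ValueError("feedback degradation of X2 by the output needs L >= 3")

    def build(self) -> ReactionNetwork:
        return chain_feedback_plant(self.L, self.k, self.gamma, self.gamma_F,
                                    self.kappa_F)


@dataclass(frozen=True)
class DisturbanceEvent:
    """A step change of one rate constant at a given time.

    ``target`` addresses the reaction by label (e.g. ``"X2_deg"`` for a plant
    degradation step, ``"ref"`` for a setpoint step through mu).
    """

    time: float
    target: str
    value: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("disturbance time must be >= 0")
        if self.value < 0:
            raise ValueError("disturbed rate must stay nonnegative")


def gene_expression_plant(k1: float, gamma1: float, gamma2: float) -> ReactionNetwork:
    """mRNA/protein pair: X1 -> X1 + X2 at k1, X_i -> 0 at gamma_i."""
    reactions = (
        Reaction("X1_to_X2", {"X2": +1}, mass_action(k1, "X1")),
        Reaction("X1_deg", {"X1": -1}, mass_action(gamma1, "X1")),
        Reaction("X2_deg", {"X2": -1}, mass_action(gamma2, "X2")),
    )
    return build_reaction_network(("X1", "X2"), reactions,
                                  input_species="X1", output_species="X2")


def chain_feedback_plant(L: int, k: Sequence[float], gamma: Sequence[float],
                         gamma_F: float = 0.0,
                         kappa_F: float | None = None) -> ReactionNetwork:
    """Catalytic chain X1 -> X2 -> ... -> XL, with optional output feedback
    X_L catalytically degrading X_2 at gamma_F (saturating in X2 when
    kappa_F is given)."""
    spec_check = PlantSpec(L, tuple(float(v) for v in k), tuple(float(v) for v in gamma),
                           float(gamma_F),
                           None if kappa_F is None else float(kappa_F))
    species = tuple(f"X{i + 1}" for i in range(L))
    reactions: list[Reaction] = []
    for i in range(L - 1):
        reactions.append(Reaction(f"X{i + 1}_to_X{i + 2}", {species[i + 1]: +1},
                                  mass_action(spec_check.k[i], species[i])))
    for i in range(L):
        reactions.append(Reaction(f"X{i + 1}_deg", {species[i]: -1},
                                  mass_action(spec_check.gamma[i], species[i])))
    if gamma_F > 0:
        if kappa_F is None:
            fb = mass_action(spec_check.gamma_F, "X2", species[-1])
        else:
            fb = saturating_degradation(spec_check.gamma_F, "X2",
                                        spec_check.kappa_F, modifiers=[species[-1]])
        reactions.append(Reaction("fb_deg", {"X2": -1}, fb))
    return build_reaction_network(species, reactions,
                                  input_species="X1", output_species=species[-1])


#: default rates for the 6-species unstable chain: a weakly damped cascade
#: with strong, substrate-saturated (protease-like) output feedback onto X2.
#: At operating inputs around u ~ 1-5 the open-loop fixed point has a complex
#: eigenvalue pair with positive real part, and no integral-only gain k
#: stabilizes the closed loop.
CHAIN6_DEFAULTS = {
    "k": (1.0, 1.0, 1.0, 1.0, 1.0),
    "gamma": (0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
    "gamma_F": 1.0,
    "kappa_F": 0.01,
}


def random_plant(seed: int, L: int = 3,
                 k_range: tuple[float, float] = (0.5, 2.0),
                 gamma_range: tuple[float, float] = (0.5, 2.0)) -> ReactionNetwork:
    """Seeded random chain plant with log-uniform rates (no feedback), used
    for robust-perfect-adaptation property tests."""
    rng = np.random.default_rng(seed)

    def logu(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    k = logu(*k_range, L - 1)
    gamma = logu(*gamma_range, L)
    return chain_feedback_plant(L, k, gamma, 0.0)
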