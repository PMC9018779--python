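"""Deterministic closed-loop engine: ODE integration, fixed points, metrics.

The closed-loop dynamics are dx/dt = S_cl @ lambda_cl(x).  Integration uses a
stiff-capable adaptive solver with the exact analytic Jacobian (the
sequestration rate eta may be as large as 1e6).  Scheduled rate steps
(disturbances) are applied by restarting the integration at each event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ClosedLoopNetwork, ReactionNetwork
from .plants import DisturbanceEvent

__all__ = [
    "Trajectory",
    "TransientMetrics",
    "IntegrationError",
    "FixedPointError",
    "simulate_ode",
    "find_fixed_point",
    "transient_metrics",
    "performance_index",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    def __init__(self, msg, last_state=None, last_time=None):
        super().__init__(msg)
        self.last_state = last_state
        self.last_time = last_time


class FixedPointError(RuntimeError):
    """Fixed-point search failed; the loop may be unstable or unbounded."""


@dataclass
class Trajectory:
    """Time series of all species plus derived control signals."""

    t: np.ndarray
    x: np.ndarray                 # (n_time, n_species)
    species: tuple[str, ...]
    u: np.ndarray | None = None
    u_i: np.ndarray | None = None
    u_d: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def output(self, network: ReactionNetwork) -> np.ndarray:
        return self.x[:, network.output_index]

    def final_state(self) -> np.ndarray:
        return self.x[-1]

    def to_frame(self):
        import pandas as pd

        d = {"time": self.t}
        for i, s in enumerate(self.species):
            d[s] = self.x[:, i]
        for name, v in (("u", self.u), ("u_I", self.u_i), ("u_D", self.u_d)):
            if v is not None:
                d[name] = v
        return pd.DataFrame(d)


@dataclass(frozen=True)
class TransientMetrics:
    settling_time: float
    overshoot_pct: float
    rise_time: float
    steady_state_error: float
    settled: bool


def _integrate_segment(net: ReactionNetwork, x0, t0, t1, rtol, atol, n_eval):
    S = net.stoichiometry().astype(float)

    def rhs(t, x):
        return S @ net.propensities(np.maximum(x, 0.0))

    def jac(t, x):
        return S @ net.propensity_jacobian(np.maximum(x, 0.0))

    t_eval = np.linspace(t0, t1, max(int(n_eval), 2))
    sol = solve_ivp(rhs, (t0, t1), x0, method="LSODA", jac=jac,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}",
                               last_state=sol.y[:, -1] if sol.y.size else x0,
                               last_time=sol.t[-1] if sol.t.size else t0)
    if np.min(sol.y) < -10.0 * atol:
        raise IntegrationError(
            f"state went negative beyond tolerance (min {np.min(sol.y):.3e}); "
            "the model violates nonnegativity",
            last_state=sol.y[:, -1], last_time=sol.t[-1])
    return sol.t, np.clip(sol.y.T, 0.0, None)


def simulate_ode(network: ReactionNetwork, x0: Sequence[float], horizon: float,
                 disturbances: Sequence[DisturbanceEvent] = (),
                 rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                 n_eval: int = 2000) -> Trajectory:
    """Integrate the deterministic dynamics, restarting at each disturbance."""
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (network.n_species,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({network.n_species},)")
    if np.any(x0 < 0):
        raise ValueError("x0 must be nonnegative")
    events = sorted(disturbances, key=lambda d: d.time)
    for d in events:
        if d.time > horizon:
            raise ValueError(f"disturbance at t={d.time} beyond horizon {horizon}")

    times = [0.0] + [d.time for d in events] + [horizon]
    net = network
    ts, xs = [], []
    x = x0
    applied = []
    for i in range(len(times) - 1):
        if i > 0:
            net = net.with_rate(events[i - 1].target, events[i - 1].value)
            applied.append(events[i - 1])
        t0, t1 = times[i], times[i + 1]
        if t1 <= t0:
            continue
        frac = max((t1 - t0) / horizon, 1e-6)
        t_seg, x_seg = _integrate_segment(net, x, t0, t1, rtol, atol,
                                          max(2, int(n_eval * frac)))
        if ts:
            t_seg, x_seg = t_seg[1:], x_seg[1:]
        ts.append(t_seg)
        xs.append(x_seg)
        x = x_seg[-1]

    t = np.concatenate(ts)
    xmat = np.vstack(xs)
    u = ui = ud = None
    if isinstance(network, ClosedLoopNetwork):
        vals = [network.actuation_value(row) for row in xmat]
        u = np.array([v[0] for v in vals])
        ui = np.array([v[1] for v in vals])
        if vals and vals[0][2] is not None:
            ud = np.array([v[2] for v in vals])
    return Trajectory(t, xmat, network.species, u, ui, ud,
                      meta={"rtol": rtol, "atol": atol, "events": applied,
                            "final_network": net})


def find_fixed_point(network: ReactionNetwork, guess: Sequence[float] | None = None,
                     presim_horizon: float = 200.0, tol: float = 1e-12) -> np.ndarray:
    """Solve S_cl @ lambda_cl(x) = 0, seeded from a long integration.

    Raises FixedPointError when the damped root search does not converge,
    which typically signals an unstable or divergent closed loop.
    """
    S = network.stoichiometry().astype(float)
    if guess is None:
        guess = np.ones(network.n_species)
    guess = np.asarray(guess, dtype=float)
    try:
        traj = simulate_ode(network, guess, presim_horizon, rtol=1e-6, atol=1e-9,
                            n_eval=50)
        seed = traj.final_state()
        if not np.all(np.isfinite(seed)) or np.max(seed) > 1e12:
            raise FixedPointError("trajectory diverged; no finite fixed point reached")
    except IntegrationError:
        seed = guess

    def fun(x):
        return S @ network.propensities(np.maximum(x, 0.0))

    def jac(x):
        return S @ network.propensity_jacobian(np.maximum(x, 0.0))

    sol = root(fun, seed, jac=jac, method="hybr", tol=tol)
    x = np.maximum(sol.x, 0.0)
    res = np.linalg.norm(fun(x), ord=np.inf)
    scale = max(1.0, float(np.max(np.abs(network.propensities(x)))))
    if not sol.success or res > 1e-8 * scale:
        raise FixedPointError(
            f"no fixed point found (residual {res:.2e}); the closed loop may be unstable")
    return x


def transient_metrics(traj: Trajectory, r: float, band: float = 0.02,
                      output_index: int | None = None,
                      output_name: str | None = None) -> TransientMetrics:
    """Settling time (entry into +-band*r, forever within the horizon),
    percent overshoot, 10-90% rise time and final tracking error."""
    if r <= 0:
        raise ValueError("setpoint r must be positive")
    if output_index is None:
        if output_name is not None:
            output_index = traj.species.index(output_name)
        else:
            output_index = len(traj.species) - 1
    y = traj.x[:, output_index]
    t = traj.t

    inside = np.abs(y - r) <= band * r
    if inside[-1]:
        # last index after which the trajectory never leaves the band
        out = np.where(~inside)[0]
        i0 = out[-1] + 1 if out.size else 0
        settling = float(t[i0])
        settled = True
    else:
        settling = float(t[-1])
        settled = False

    overshoot = float(max((np.max(y) - r) / r * 100.0, 0.0))

    def first_crossing(level):
        above = y >= level
        idx = np.where(above)[0]
        if idx.size == 0:
            return None
        i = idx[0]
        if i == 0:
            return float(t[0])
        # linear interpolation between samples
        y0, y1 = y[i - 1], y[i]
        if y1 == y0:
            return float(t[i])
        return float(t[i - 1] + (level - y0) / (y1 - y0) * (t[i] - t[i - 1]))

    t10 = first_crossing(0.1 * r)
    t90 = first_crossing(0.9 * r)
    if y[0] >= 0.9 * r:
        rise = 0.0
    elif t10 is None or t90 is None:
        rise = float(t[-1])
    else:
        rise = max(t90 - t10, 0.0)

    sse = float(abs(y[-1] - r))
    return TransientMetrics(settling, overshoot, rise, sse, settled)


def performance_index(metrics: TransientMetrics, w_overshoot: float = 1.0,
                      w_settling: float = 1.0, w_rise: float = 1.0,
                      t_ref: float | None = None,
                      unsettled_penalty: float = 10.0) -> float:
    """Scalar J combining overshoot, settling and rise time (smaller is
    better); unsettled responses incur a fixed documented penalty."""
    if t_ref is None:
        t_ref = max(metrics.settling_time, 1.0)
    J = (w_overshoot * metrics.overshoot_pct / 100.0
         + w_settling * metrics.settling_time / t_ref
         + w_rise * metrics.rise_time / t_ref)
    if not metrics.settled:
        J += unsettled_penalty
    return float(J)
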