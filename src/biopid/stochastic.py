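"""Exact stochastic simulation (Gillespie direct method), stationary moments,
the moment-closure variance approximation, and power-spectral-density
analysis of single-cell trajectories.

The SSA core is compiled with numba; propensities are evaluated from the same
closed factor vocabulary the deterministic engine uses, so a network object
drives both interpretations unchanged.  Moment estimation is time-weighted
(holding times), never event-weighted, and standard errors come from batch
means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.signal import find_peaks, periodogram

from .network import ReactionNetwork

__all__ = [
    "JumpTrajectory",
    "StationaryMoments",
    "ssa_simulate",
    "ssa_resample",
    "stationary_moments",
    "ensemble_moments",
    "analytic_variance_class1",
    "power_spectral_density",
    "SsaError",
    "compile_ssa",
]


class SsaError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# propensity table compilation
# --------------------------------------------------------------------------

_KIND_CODE = {"linear": 0, "hill_act": 1, "hill_rep": 2, "michaelis": 3}


def compile_ssa(network: ReactionNetwork):
    """Flatten a network into the arrays the numba kernels consume."""
    K, L = network.n_reactions, network.n_species
    S = network.stoichiometry().T.copy()          # (K, L)
    rates = np.empty(K)
    offs = [0]
    fs, fk, fkap, fn, fp = [], [], [], [], []
    for r in network.reactions:
        rates[offs.__len__() - 1] = r.propensity.rate
        for f in r.propensity.factors:
            fs.append(network.species_index(f.species))
            fk.append(_KIND_CODE[f.kind])
            fkap.append(f.kappa)
            fn.append(f.n)
            fp.append(f.power)
        offs.append(len(fs))
    return (S.astype(np.int64), rates,
            np.asarray(offs, dtype=np.int64),
            np.asarray(fs, dtype=np.int64), np.asarray(fk, dtype=np.int64),
            np.asarray(fkap, dtype=np.float64), np.asarray(fn, dtype=np.float64),
            np.asarray(fp, dtype=np.int64))


@njit(cache=True)
def _props(x, rates, offs, fs, fk, fkap, fn, fp, out):
    K = rates.shape[0]
    for k in range(K):
        v = rates[k]
        for j in range(offs[k], offs[k + 1]):
            if v == 0.0:
                break
            xi = x[fs[j]]
            kind = fk[j]
            if kind == 0:
                for _ in range(fp[j]):
                    v *= xi
            elif kind == 3:
                d = xi + fkap[j]
                v = v * xi / d if d > 0.0 else 0.0
            else:
                if fkap[j] <= 0.0:
                    q = 1e300 if xi > 0.0 else 0.0
                else:
                    q = (xi / fkap[j]) ** fn[j]
                if kind == 1:
                    v *= q / (1.0 + q)
                else:
                    v *= 1.0 / (1.0 + q)
        out[k] = v
    return out


@njit(cache=True)
def _ssa_path(S, rates, offs, fs, fk, fkap, fn, fp, x0, t_end, seed, max_events):
    np.random.seed(seed)
    L = x0.shape[0]
    K = rates.shape[0]
    x = x0.astype(np.float64)
    lam = np.empty(K)
    times = np.empty(max_events + 1)
    states = np.empty((max_events + 1, L), dtype=np.int64)
    times[0] = 0.0
    for i in range(L):
        states[0, i] = int(x0[i])
    t = 0.0
    n = 0
    status = 0
    while t < t_end:
        _props(x, rates, offs, fs, fk, fkap, fn, fp, lam)
        tot = 0.0
        for k in range(K):
            tot += lam[k]
        if tot <= 0.0:
            break
        if tot > 1e12:
            status = 1
            break
        t += -np.log(np.random.random()) / tot
        if t >= t_end:
            break
        if n >= max_events:
            status = 2
            break
        u = np.random.random() * tot
        acc = 0.0
        kk = K - 1
        for k in range(K):
            acc += lam[k]
            if u < acc:
                kk = k
                break
        for i in range(L):
            x[i] += S[kk, i]
        n += 1
        times[n] = t
        for i in range(L):
            states[n, i] = int(x[i])
    return times[: n + 1], states[: n + 1], status


@njit(cache=True)
def _ssa_batch_moments(S, rates, offs, fs, fk, fkap, fn, fp, x0, t_end,
                       burn_in, n_batches, seed):
    """Time-weighted per-batch first and second moments over (burn_in, t_end]."""
    np.random.seed(seed)
    L = x0.shape[0]
    K = rates.shape[0]
    x = x0.astype(np.float64)
    lam = np.empty(K)
    batch_len = (t_end - burn_in) / n_batches
    m1 = np.zeros((n_batches, L))
    m2 = np.zeros((n_batches, L))
    t = 0.0
    status = 0
    n_events = 0
    while t < t_end:
        _props(x, rates, offs, fs, fk, fkap, fn, fp, lam)
        tot = 0.0
        for k in range(K):
            tot += lam[k]
        if tot <= 0.0:
            t_next = t_end
            kk = -1
        else:
            if tot > 1e12:
                status = 1
                break
            t_next = t + (-np.log(np.random.random()) / tot)
            kk = -2
        # accumulate holding time over batches
        a = t if t > burn_in else burn_in
        b = t_next if t_next < t_end else t_end
        if b > a:
            ia = int((a - burn_in) / batch_len)
            while a < b:
                edge = burn_in + (ia + 1) * batch_len
                seg = (b if b < edge else b) - a
                if edge < b:
                    seg = edge - a
                for i in range(L):
                    m1[ia, i] += x[i] * seg
                    m2[ia, i] += x[i] * x[i] * seg
                a += seg
                ia += 1
                if ia >= n_batches:
                    break
        if kk == -1 or t_next >= t_end:
            break
        u = np.random.random() * tot
        acc = 0.0
        kk = K - 1
        for k in range(K):
            acc += lam[k]
            if u < acc:
                kk = k
                break
        for i in range(L):
            x[i] += S[kk, i]
        t = t_next
        n_events += 1
    return m1 / batch_len, m2 / batch_len, status, n_events


@njit(cache=True)
def _ssa_grid(S, rates, offs, fs, fk, fkap, fn, fp, x0, grid, seed):
    np.random.seed(seed)
    L = x0.shape[0]
    K = rates.shape[0]
    x = x0.astype(np.float64)
    lam = np.empty(K)
    out = np.empty((grid.shape[0], L))
    t = 0.0
    gi = 0
    status = 0
    while gi < grid.shape[0]:
        _props(x, rates, offs, fs, fk, fkap, fn, fp, lam)
        tot = 0.0
        for k in range(K):
            tot += lam[k]
        if tot <= 0.0:
            t_next = grid[-1] + 1.0
        else:
            if tot > 1e12:
                status = 1
                break
            t_next = t + (-np.log(np.random.random()) / tot)
        while gi < grid.shape[0] and grid[gi] < t_next:
            for i in range(L):
                out[gi, i] = x[i]
            gi += 1
        if tot <= 0.0:
            break
        u = np.random.random() * tot
        acc = 0.0
        kk = K - 1
        for k in range(K):
            acc += lam[k]
            if u < acc:
                kk = k
                break
        for i in range(L):
            x[i] += S[kk, i]
        t = t_next
    return out, status


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

@dataclass
class JumpTrajectory:
    """Event-resolved sample path of the reaction-network Markov chain."""

    t: np.ndarray                 # event times, t[0] = 0
    x: np.ndarray                 # (n_events+1, L) integer states
    species: tuple[str, ...]
    seed: int
    t_end: float
    meta: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.t) - 1

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Zero-order-hold values on a uniform grid (grid <= t_end)."""
        idx = np.searchsorted(self.t, grid, side="right") - 1
        return self.x[np.clip(idx, 0, len(self.t) - 1)]


@dataclass(frozen=True)
class StationaryMoments:
    species: tuple[str, ...]
    mean: np.ndarray
    variance: np.ndarray
    se_mean: np.ndarray
    se_variance: np.ndarray
    burn_in: float
    n_batches: int
    flags: dict = field(default_factory=dict)


def ssa_simulate(network: ReactionNetwork, x0: Sequence[float], t_end: float,
                 seed: int, max_events: int = 5_000_000) -> JumpTrajectory:
    """Statistically exact path of the CTMC defined by (S, lambda)."""
    x0 = np.asarray(x0)
    if np.any(x0 < 0) or np.any(x0 != np.floor(x0)):
        raise ValueError("x0 must be nonnegative integers")
    tables = compile_ssa(network)
    t, x, status = _ssa_path(*tables, x0.astype(np.int64), float(t_end),
                             int(seed) & 0x7FFFFFFF, int(max_events))
    if status == 1:
        raise SsaError("propensity overflow (total rate > 1e12)")
    if status == 2:
        raise SsaError(f"event budget ({max_events}) exhausted before t_end")
    return JumpTrajectory(t, x, network.species, int(seed), float(t_end))


def ssa_resample(network: ReactionNetwork, x0, grid: np.ndarray, seed: int) -> np.ndarray:
    """SSA sampled on a time grid without storing the event path."""
    tables = compile_ssa(network)
    out, status = _ssa_grid(*tables, np.asarray(x0, dtype=np.int64),
                            np.asarray(grid, dtype=float), int(seed) & 0x7FFFFFFF)
    if status == 1:
        raise SsaError("propensity overflow (total rate > 1e12)")
    return out


def stationary_moments(trajectories: Sequence[JumpTrajectory], burn_in: float,
                       n_batches: int = 8) -> StationaryMoments:
    """Time-weighted stationary moments pooled across trajectories, with
    batch-means standard errors."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    first = trajectories[0]
    L = first.x.shape[1]
    bm1, bm2 = [], []
    for tr in trajectories:
        if tr.t_end <= burn_in:
            raise ValueError("burn-in consumes the whole trajectory")
        edges = np.linspace(burn_in, tr.t_end, n_batches + 1)
        t = np.append(tr.t, tr.t_end)
        for b in range(n_batches):
            a, bnd = edges[b], edges[b + 1]
            i0 = np.searchsorted(t, a, side="right") - 1
            i1 = min(np.searchsorted(t, bnd, side="right") - 1, len(t) - 2)
            idx = np.arange(i0, i1 + 1)
            seg_t = np.clip(t[idx], a, bnd)
            seg_end = np.clip(t[idx + 1], a, bnd)
            w = seg_end - seg_t
            states = tr.x[idx].astype(float)
            T = w.sum()
            if T <= 0:
                continue
            bm1.append((states * w[:, None]).sum(axis=0) / T)
            bm2.append((states ** 2 * w[:, None]).sum(axis=0) / T)
    bm1 = np.asarray(bm1)
    bm2 = np.asarray(bm2)
    return _combine_batches(first.species, bm1, bm2, burn_in)


def _combine_batches(species, bm1, bm2, burn_in, flags=None) -> StationaryMoments:
    nb = bm1.shape[0]
    mean = bm1.mean(axis=0)
    second = bm2.mean(axis=0)
    var = np.maximum(second - mean ** 2, 0.0)
    se_mean = bm1.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full_like(mean, np.nan)
    bvar = np.maximum(bm2 - bm1 ** 2, 0.0)
    se_var = bvar.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full_like(mean, np.nan)
    return StationaryMoments(tuple(species), mean, var, se_mean, se_var,
                             burn_in, nb, flags or {})


def ensemble_moments(network: ReactionNetwork, x0, t_end: float, burn_in: float,
                     n_traj: int, seed: int, n_batches: int = 4) -> StationaryMoments:
    """Driver: n_traj independent SSA runs, each contributing time-weighted
    batch moments (memory-light; paths are not stored)."""
    if t_end <= burn_in:
        raise ValueError("burn-in consumes the whole trajectory")
    tables = compile_ssa(network)
    x0 = np.asarray(x0, dtype=np.int64)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_traj)
    bm1, bm2 = [], []
    events = 0
    for s in seeds:
        m1, m2, status, nev = _ssa_batch_moments(*tables, x0, float(t_end),
                                                 float(burn_in), int(n_batches), int(s))
        if status == 1:
            raise SsaError("propensity overflow during ensemble run")
        bm1.append(m1)
        bm2.append(m2)
        events += nev
    bm1 = np.concatenate(bm1, axis=0)
    bm2 = np.concatenate(bm2, axis=0)
    return _combine_batches(network.species, bm1, bm2, burn_in,
                            flags={"n_traj": n_traj, "events": events})


# --------------------------------------------------------------------------
# moment-closure stationary variance (Class-1 aPI on the gene plant)
# --------------------------------------------------------------------------

def analytic_variance_class1(spec, plant: ReactionNetwork) -> dict:
    """Approximate stationary variance of the output under Class-1 aPI
    control of the gene-expression plant.

    Moment closure: the CME first/second-moment hierarchy is closed by
    linearizing every non-affine propensity (the bilinear sequestration and
    the Hill/Michaelis inhibition terms) about the stationary mean, which
    reduces the stationary second moments to a Lyapunov equation
    J Sigma + Sigma J' + S diag(lambda) S' = 0 evaluated at the fixed point.
    Past the ergodicity threshold (additive inhibition with alpha >=
    alpha_TH) the result is flagged rather than returned silently.
    """
    from .linear import alpha_threshold, analytic_fixed_point, closed_loop_stability
    from .network import compose_closed_loop
    from scipy.linalg import solve_continuous_lyapunov

    if plant.n_species != 2:
        raise ValueError("the closure is derived for the two-species gene plant")
    if spec.topology not in ("AI", "API_CLASS1"):
        raise ValueError("closure covers the standalone aI and Class-1 aPI designs")
    flags = {}
    if spec.mechanism == "ADDITIVE" and spec.alpha > 0:
        k1 = plant.rate_of("X1_to_X2")
        g1 = plant.rate_of("X1_deg")
        g2 = plant.rate_of("X2_deg")
        ath = alpha_threshold(g1, g2, k1, spec.setpoint(), spec.kappa, spec.n)
        if spec.alpha >= ath:
            import warnings as _w
            _w.warn("alpha >= alpha_TH: ergodicity is lost; variance flagged",
                    stacklevel=2)
            return {"variance": np.nan, "mean": np.nan,
                    "flags": {"ergodicity_lost": True, "alpha_TH": ath}}
    cl = compose_closed_loop(plant, spec)
    xbar = analytic_fixed_point(spec, plant)
    rep = closed_loop_stability(spec, plant, point=xbar)
    if not rep.stable:
        flags["unstable_fixed_point"] = True
    J = cl.jacobian(xbar)
    lam = cl.propensities(xbar)
    S = cl.stoichiometry().astype(float)
    D = S @ np.diag(lam) @ S.T
    Sigma = solve_continuous_lyapunov(J, -D)
    i_out = cl.output_index
    return {"variance": float(Sigma[i_out, i_out]),
            "mean": float(xbar[i_out]),
            "covariance": Sigma, "fixed_point": xbar, "flags": flags}


# --------------------------------------------------------------------------
# power spectral density
# --------------------------------------------------------------------------

def power_spectral_density(signals: np.ndarray, sample_dt: float,
                           prominence_rel: float = 3.0) -> dict:
    """Averaged windowed periodogram across trajectories + peak report.

    ``signals`` is (n_traj, n_samples) on a uniform grid.  Each trajectory is
    mean-removed and Hann-windowed; the peak detector reports the most
    prominent interior peak and whether its prominence exceeds
    ``prominence_rel`` times the median spectral level.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] < 2:
        raise ValueError("need at least 2 samples per trajectory")
    psds = []
    for row in signals:
        f, p = periodogram(row - row.mean(), fs=1.0 / sample_dt, window="hann",
                           detrend=False)
        psds.append(p)
    psds = np.asarray(psds)
    mean_psd = psds.mean(axis=0)
    se_psd = (psds.std(axis=0, ddof=1) / np.sqrt(len(psds))
              if len(psds) > 1 else np.zeros_like(mean_psd))
    interior = mean_psd[1:]
    level = np.median(interior) + 1e-300
    peaks, props = find_peaks(interior, prominence=0.0)
    report = {"freq": None, "prominence": 0.0, "significant": False}
    if peaks.size:
        best = int(np.argmax(props["prominences"]))
        report = {
            "freq": float(f[1:][peaks[best]]),
            "prominence": float(props["prominences"][best] / level),
            "significant": bool(props["prominences"][best] / level > prominence_rel),
        }
    return {"freqs": f, "psd": mean_psd, "se": se_psd, "peak": report}
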