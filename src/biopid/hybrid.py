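"""Sampled-data hybrid loop: an in-silico stochastic controller driving a
(simulated or replayed) single-cell plant at fixed sampling intervals.

The controller network is simulated by SSA with the measured output held
constant over each interval (zero-order hold).  Actuation is carried by an
additional in-silico species X0 whose abundance sets the applied input
intensity (in the optogenetic platform this is the blue-light level); the
plant receives the intensity as a zero-order production of its input species,
constant over the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .controllers import ControllerSpec
from .network import ReactionNetwork, Reaction, build_reaction_network, mass_action
from .stochastic import compile_ssa, _ssa_grid, power_spectral_density

__all__ = [
    "HybridLoopConfig",
    "build_insilico_controller",
    "hybrid_step",
    "run_hybrid_experiment",
]

MEAS = "XLmeas"     # frozen measurement slot (no reaction changes it)
ACT = "X0"          # in-silico actuation species


@dataclass(frozen=True)
class HybridLoopConfig:
    controller: ControllerSpec
    plant: ReactionNetwork | None = None
    sampling_interval: float = 2.0
    horizon: float = 240.0
    n_cells: int = 8
    intensity_scale: float = 1.0       # intensity = scale * X0 abundance
    x0_decay: float = 1.0
    measurement_csv: object = None     # (time, cell_id, measurement) replay frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.intensity_scale < 0:
            raise ValueError("intensity map must be nonnegative")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


def build_insilico_controller(spec: ControllerSpec, x0_decay: float = 1.0) -> ReactionNetwork:
    """Controller network with actuation rerouted into the species X0 and the
    sensed output replaced by the frozen measurement slot."""
    frag = spec.compile(plant_input=ACT, plant_output=MEAS)
    reactions = list(frag.reactions) + [
        Reaction("x0_decay", {ACT: -1}, mass_action(x0_decay, ACT))
    ]
    return build_reaction_network((ACT, MEAS) + frag.species, reactions,
                                  input_species=ACT, output_species=MEAS)


def hybrid_step(ctrl_net: ReactionNetwork, state: np.ndarray, measurement: float,
                interval: float, seed: int, intensity_scale: float = 1.0,
                stochastic: bool = True):
    """Advance the controller by one sampling interval with the measurement
    zero-order-held; returns (new_state, intensity)."""
    if measurement < 0:
        raise ValueError("measurement must be nonnegative")
    state = np.asarray(state, dtype=float).copy()
    im = ctrl_net.species_index(MEAS)
    if stochastic:
        state[im] = round(measurement)
        tables = compile_ssa(ctrl_net)
        out, status = _ssa_grid(*tables, state.astype(np.int64),
                                np.array([interval]), int(seed) & 0x7FFFFFFF)
        if status != 0:
            raise RuntimeError("controller SSA overflow")
        new = out[0].astype(float)
    else:
        state[im] = measurement
        S = ctrl_net.stoichiometry().astype(float)

        def rhs(t, x):
            return S @ ctrl_net.propensities(np.maximum(x, 0.0))

        sol = solve_ivp(rhs, (0.0, interval), state, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        new = np.maximum(sol.y[:, -1], 0.0)
    intensity = intensity_scale * new[ctrl_net.species_index(ACT)]
    return new, float(intensity)


def _plant_with_input(plant: ReactionNetwork) -> ReactionNetwork:
    """Plant plus a zero-order input production whose rate is set per step."""
    rxn = Reaction("u_in", {plant.input_species: +1}, mass_action(0.0))
    return replace(plant, reactions=plant.reactions + (rxn,), _index={})


def run_hybrid_experiment(config: HybridLoopConfig) -> dict:
    """Simulate N independent cells in closed loop with per-cell in-silico
    controllers; returns per-cell output traces, the mean response and a
    pooled PSD report."""
    import pandas as pd

    n_steps = int(np.floor(config.horizon / config.sampling_interval))
    t_grid = np.arange(n_steps + 1) * config.sampling_interval
    ctrl_net = build_insilico_controller(config.controller, config.x0_decay)
    rng = np.random.default_rng(config.seed)

    replay = None
    if config.measurement_csv is not None:
        replay = (config.measurement_csv if isinstance(config.measurement_csv, pd.DataFrame)
                  else pd.read_csv(config.measurement_csv))
        for cell, grp in replay.groupby("cell_id"):
            dt = np.diff(np.sort(grp["time"].to_numpy()))
            if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError(f"replay for cell {cell} is not uniformly sampled")
    elif config.plant is None:
        raise ValueError("config needs either a simulated plant or a measurement CSV")

    outputs = np.zeros((config.n_cells, n_steps + 1))
    intensities = np.zeros((config.n_cells, n_steps + 1))
    plant_net = _plant_with_input(config.plant) if config.plant is not None else None

    for c in range(config.n_cells):
        cseed = rng.integers(0, 2 ** 31 - 1)
        crng = np.random.default_rng(cseed)
        ctrl_state = np.zeros(ctrl_net.n_species)
        for s, v in config.controller.compile(ACT, MEAS).initial.items():
            ctrl_state[ctrl_net.species_index(s)] = v
        if plant_net is not None:
            plant_state = np.zeros(plant_net.n_species)
            out_idx = plant_net.output_index
            outputs[c, 0] = plant_state[out_idx]
        else:
            cells = sorted(replay["cell_id"].unique())
            series = replay[replay["cell_id"] == cells[c % len(cells)]]
            meas_series = series.sort_values("time")["measurement"].to_numpy()
            outputs[c, 0] = meas_series[0]

        for step in range(n_steps):
            y = outputs[c, step]
            ctrl_state, intensity = hybrid_step(
                ctrl_net, ctrl_state, y, config.sampling_interval,
                seed=int(crng.integers(0, 2 ** 31 - 1)),
                intensity_scale=config.intensity_scale)
            intensities[c, step + 1] = intensity
            if plant_net is not None:
                net = plant_net.with_rate("u_in", intensity)
                tables = compile_ssa(net)
                out, status = _ssa_grid(*tables, plant_state.astype(np.int64),
                                        np.array([config.sampling_interval]),
                                        int(crng.integers(0, 2 ** 31 - 1)))
                if status != 0:
                    raise RuntimeError("plant SSA overflow")
                plant_state = out[0].astype(float)
                outputs[c, step + 1] = plant_state[out_idx]
            else:
                outputs[c, step + 1] = meas_series[min(step + 1, len(meas_series) - 1)]

    mean = outputs.mean(axis=0)
    se = outputs.std(axis=0, ddof=1) / np.sqrt(config.n_cells) if config.n_cells > 1 \
        else np.zeros_like(mean)
    # PSD over the second half (past the transient)
    half = (n_steps + 1) // 2
    psd = power_spectral_density(outputs[:, half:], config.sampling_interval)
    return {
        "t": t_grid,
        "outputs": outputs,
        "intensities": intensities,
        "mean": mean,
        "se": se,
        "psd": psd,
        "seed": config.seed,
    }
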