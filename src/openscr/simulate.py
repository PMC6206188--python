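"""Simulation of open-population SCR datasets with full ground truth.

The default configuration reproduces a canonical camera-trap benchmark
design: five annual primary periods, an average population of 40
individuals on a 10 x 10 unit state space, a centered 7 x 7 trap grid with
unit spacing, five sampling occasions per year, survival 0.75, baseline
encounter rate 0.5 and detection scale 0.5.  Recruitment is balanced
against mortality each year so the expected population size stays at the
target, which is what makes averaged bias metrics interpretable against a
single true value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    EncounterData,
    LatentState,
    MovementModel,
    Parameters,
    StateSpace,
    TrapArray,
    _as_movement,
    detection_prob,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "make_grid",
    "make_state_space",
    "simulate_dynamics",
    "simulate_centers",
    "simulate_detections",
    "simulate_scenario",
]


@dataclass
class SimulationConfig:
    """Data-generating design for one simulated study.

    Defaults are the benchmark design described in the module docstring.
    ``gen_buffer_mult`` expresses the data-generating state-space buffer as
    a multiple of ``sigma_p`` (4 x 0.5 = 2 units around the 7 x 7 grid
    recovers the 10 x 10 generating state space).
    """

    T: int = 5
    M: int = 150
    target_N: int = 40
    phi: float = 0.75
    lambda0: float = 0.5
    sigma_p: float = 0.5
    sigma_s: float = 0.5          # random-walk SD, i.e. variance 0.25
    movement_model: MovementModel | str = MovementModel.CONSTANT
    K: int = 5
    grid_nx: int = 7
    grid_ny: int = 7
    grid_spacing: float = 1.0
    gen_buffer_mult: float = 4.0
    p_jump: float = 0.1           # markovian_jump only: P(uniform relocation)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.movement_model = _as_movement(self.movement_model)
        if self.target_N > self.M:
            raise ValueError("target_N cannot exceed the augmented size M")
        if min(self.T, self.M, self.K, self.grid_nx, self.grid_ny) < 1:
            raise ValueError("T, M, K and grid dimensions must be >= 1")

    def parameters(self, gamma=None) -> Parameters:
        return Parameters(
            phi=self.phi,
            gamma=np.zeros(self.T) if gamma is None else gamma,
            lambda0=self.lambda0,
            sigma_p=self.sigma_p,
            sigma_s=self.sigma_s,
            movement_model=self.movement_model,
        )


@dataclass
class SimulatedDataset:
    """A simulated dataset plus the latent truth that generated it."""

    config: SimulationConfig
    traps: TrapArray
    state_space: StateSpace
    data: EncounterData          # observed individuals only
    truth: LatentState           # all M augmented individuals
    params: Parameters           # includes the realized gamma[t]
    N: np.ndarray                # (T,) true abundance per period
    D: np.ndarray                # (T,) true density per period
    observed_index: np.ndarray = field(default_factory=lambda: np.array([], int))


def make_grid(nx: int, ny: int, spacing: float = 1.0,
              center: tuple[float, float] = (0.0, 0.0),
              K: int | np.ndarray = 1, T: int = 1) -> TrapArray:
    """Regular ``nx x ny`` trap grid centered at ``center``.

    ``K`` may be a scalar (uniform effort for all traps and periods) or a
    full ``(nx * ny, T)`` effort matrix.
    """
    if nx < 1 or ny < 1 or spacing <= 0:
        raise ValueError("grid needs nx, ny >= 1 and positive spacing")
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing + center[0]
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing + center[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    J = nx * ny
    effort = np.asarray(K, dtype=np.int64)
    if effort.ndim == 0:
        effort = np.full((J, T), int(effort), dtype=np.int64)
    return TrapArray(
        trap_id=np.arange(1, J + 1),
        x=gx.ravel(), y=gy.ravel(), effort=effort,
    )


def make_state_space(traps: TrapArray, buffer: float) -> StateSpace:
    """Trap bounding box expanded by ``buffer`` on every side."""
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    return StateSpace(
        xmin=float(traps.x.min() - buffer),
        xmax=float(traps.x.max() + buffer),
        ymin=float(traps.y.min() - buffer),
        ymax=float(traps.y.max() + buffer),
        buffer=float(buffer),
    )


def simulate_dynamics(config: SimulationConfig, rng: np.random.Generator):
    """Simulate alive histories ``z`` balancing recruitment against deaths.

    Period 1 sets exactly ``target_N`` randomly chosen individuals alive.
    For ``t >= 2`` survivors are Bernoulli(phi) draws from the alive set,
    and the conditional entrance probability is::

        gamma_t = (N_{t-1} - survivors_t) / n_available

    (clamped to [0, 1]) so that the expected number of recruits from the
    never-yet-alive pool replaces the deaths exactly.  Returns
    ``(z, alpha, gamma)``.
    """
    M, T, N0 = config.M, config.T, config.target_N
    z = np.zeros((M, T), dtype=np.int8)
    gamma = np.zeros(T)
    first = rng.choice(M, size=N0, replace=False)
    z[first, 0] = 1
    gamma[0] = N0 / M
    ever = z[:, 0].astype(bool).copy()
    for t in range(1, T):
        alive_prev = np.flatnonzero(z[:, t - 1])
        survived = alive_prev[rng.random(alive_prev.size) < config.phi]
        z[survived, t] = 1
        available = np.flatnonzero(~ever)
        deficit = alive_prev.size - survived.size
        if available.size == 0:
            if deficit > 0:
                import warnings

                warnings.warn("recruitment pool exhausted; gamma_t set to 0")
            gamma[t] = 0.0
        else:
            gamma[t] = min(max(deficit / available.size, 0.0), 1.0)
            recruits = available[rng.random(available.size) < gamma[t]]
            z[recruits, t] = 1
            ever[recruits] = True
    alpha = np.ones((M, T), dtype=np.int8)
    alpha[:, 1:] = (np.cumsum(z[:, :-1], axis=1) == 0).astype(np.int8)
    return z, alpha, gamma


def _uniform_point(S: StateSpace, rng: np.random.Generator) -> np.ndarray:
    return np.array([
        rng.uniform(S.xmin, S.xmax),
        rng.uniform(S.ymin, S.ymax),
    ])


def _truncated_step(prev: np.ndarray, sigma_s: float, S: StateSpace,
                    rng: np.random.Generator) -> np.ndarray:
    # rejection sampling against S: exact draw from the truncated normal
    while True:
        cand = prev + rng.normal(0.0, sigma_s, size=2)
        if S.xmin <= cand[0] <= S.xmax and S.ymin <= cand[1] <= S.ymax:
            return cand


def simulate_centers(z: np.ndarray, model: MovementModel | str, S: StateSpace,
                     sigma_s: float | None, rng: np.random.Generator,
                     p_jump: float = 0.1) -> np.ndarray:
    """Simulate activity centers for every individual from first entry on.

    Upon first entry the center is uniform over S.  Afterwards it stays
    fixed (constant), resamples uniformly (independent), or takes truncated
    Gaussian random-walk steps (markovian; with probability ``p_jump`` per
    step, the markovian_jump variant relocates uniformly instead).
    Centers are NaN before first entry and for never-alive individuals.
    """
    model = _as_movement(model)
    M, T = z.shape
    s = np.full((M, T, 2), np.nan)
    for i in range(M):
        alive = np.flatnonzero(z[i])
        if alive.size == 0:
            continue
        f = int(alive[0])
        s[i, f] = _uniform_point(S, rng)
        for t in range(f + 1, T):
            if model is MovementModel.CONSTANT:
                s[i, t] = s[i, f]
            elif model is MovementModel.INDEPENDENT:
                s[i, t] = _uniform_point(S, rng)
            elif model is MovementModel.MARKOVIAN:
                s[i, t] = _truncated_step(s[i, t - 1], sigma_s, S, rng)
            else:  # markovian_jump
                if rng.random() < p_jump:
                    s[i, t] = _uniform_point(S, rng)
                else:
                    s[i, t] = _truncated_step(s[i, t - 1], sigma_s, S, rng)
    return s


def simulate_detections(s: np.ndarray, z: np.ndarray, traps: TrapArray,
                        lambda0: float, sigma_p: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Binomial(K[j,t], p(d)) counts for alive individuals, zeros otherwise."""
    M, T = z.shape
    J = traps.n_traps
    y = np.zeros((M, J, T), dtype=np.int64)
    coords = traps.coords()
    for t in range(T):
        alive = np.flatnonzero(z[:, t])
        if alive.size == 0:
            continue
        d = np.hypot(
            s[alive, t, 0][:, None] - coords[None, :, 0],
            s[alive, t, 1][:, None] - coords[None, :, 1],
        )
        p = detection_prob(d, lambda0, sigma_p)
        y[alive, :, t] = rng.binomial(traps.effort[None, :, t], p)
    return y


def simulate_scenario(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate one complete dataset under ``config``.

    Unobserved individuals are stripped from the returned encounter data
    (they would not be identifiable in the field) but retained in the
    latent truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    traps = make_grid(config.grid_nx, config.grid_ny, config.grid_spacing,
                      center=(0.0, 0.0), K=config.K, T=config.T)
    S = make_state_space(traps, config.gen_buffer_mult * config.sigma_p)
    z, alpha, gamma = simulate_dynamics(config, rng)
    s = simulate_centers(z, config.movement_model, S, config.sigma_s, rng,
                         p_jump=config.p_jump)
    y = simulate_detections(s, z, traps, config.lambda0, config.sigma_p, rng)
    observed = np.flatnonzero(y.sum(axis=(1, 2)) > 0)
    data = EncounterData(y=y[observed], M=config.M,
                         individual_id=np.arange(1, observed.size + 1))
    truth = LatentState(z=z, s=s)
    params = replace(config.parameters(gamma=gamma))
    N = z.sum(axis=0).astype(float)
    return SimulatedDataset(
        config=config, traps=traps, state_space=S, data=data, truth=truth,
        params=params, N=N, D=N / S.area, observed_index=observed,
    )
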