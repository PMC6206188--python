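"""Bayesian estimation of open-population SCR models.

Two model variants are available:

* :class:`OpenSCRJollySeber` — the full open model with data augmentation:
  survival ``phi``, per-period conditional entrance probabilities
  ``gamma_t``, detection parameters ``lambda0`` and ``sigma_p``, the
  movement model for activity centers, and derived abundance
  ``N_t = sum_i z_{i,t}`` and density ``D_t = N_t / area(S)``.
* :class:`OpenSCRCormackJollySeber` — conditions on first capture and
  estimates survival (plus detection/movement) only; no recruitment, no
  augmentation, no abundance.

Both are scikit-learn-style estimators (``fit`` populates attributes with
a trailing underscore); ``fit_open_scr`` and ``fit_cjs`` are thin
functional wrappers.  Inference is Metropolis-within-Gibbs (see
``_sampler``); priors are deliberately vague: Uniform(0,1) on
probabilities, Uniform(0, 10) on ``lambda0`` and Uniform(0, max
state-space side) on the spatial scales.

Under the markovian movement model the sampler treats every individual's
center path as starting uniformly in period 1 and random-walking
thereafter, independently of the alive state.  Periods in which an
individual is not alive contribute no detection likelihood, so this
convention leaves the posterior of the identified parameters unchanged
while decoupling the center prior from the latent trajectories — which is
what makes the exact joint trajectory update possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _sampler
from .model import (
    EncounterData,
    MovementModel,
    StateSpace,
    TrapArray,
    _as_movement,
)
from .simulate import make_state_space

__all__ = [
    "FitConfig",
    "PosteriorSamples",
    "OpenSCRJollySeber",
    "OpenSCRCormackJollySeber",
    "fit_open_scr",
    "fit_cjs",
    "unequal_intervals",
    "gelman_rubin",
    "summarize_posterior",
]

_MOVEMENT_CODE = {
    MovementModel.CONSTANT: _sampler.CONSTANT,
    MovementModel.INDEPENDENT: _sampler.INDEPENDENT,
    MovementModel.MARKOVIAN: _sampler.MARKOVIAN,
}


@dataclass
class FitConfig:
    """MCMC and model configuration for one fit.

    ``n_iter`` counts total iterations per chain including the
    ``n_burnin`` warm-up; every ``thin``-th post-burn-in draw is retained.
    ``state_space`` is the analysis state space (it may legitimately
    differ from the one that generated the data — that sensitivity is the
    whole point of the buffer experiments).
    """

    movement_model: MovementModel | str = MovementModel.CONSTANT
    M: int = 150
    state_space: StateSpace | None = None
    n_chains: int = 3
    n_iter: int = 10500
    n_burnin: int = 500
    thin: int = 2
    seed: int = 0
    delta_t: np.ndarray | None = None
    lambda0_max: float = 10.0
    sigma_p_max: float | None = None   # default: max state-space side
    sigma_s_max: float | None = None
    keep_z: bool = False
    # used by enumeration and quadrature cross-checks: freeze parts of
    # the model at their initial values
    fix_centers: bool = False
    fix_detection: bool = False
    fix_z: bool = False
    init_lambda0: float | None = None
    init_sigma_p: float | None = None
    init_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.movement_model = _as_movement(self.movement_model)
        if self.movement_model is MovementModel.MARKOVIAN_JUMP:
            raise ValueError(
                "markovian_jump is a data-generating scenario only; fit with "
                "constant, independent or markovian")
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws with chain structure.

    Scalar parameters have shape ``(n_chains, n_draws)``; per-period
    quantities ``(n_chains, n_draws, T)``.  ``sigma_s`` is None except
    under the markovian movement model, ``N``/``D`` are None for the CJS
    variant.
    """

    phi: np.ndarray
    lambda0: np.ndarray
    sigma_p: np.ndarray
    gamma: np.ndarray | None
    sigma_s: np.ndarray | None
    N: np.ndarray | None
    state_space: StateSpace | None
    movement_model: MovementModel
    M: int | None = None
    z: np.ndarray | None = None
    saturated: bool = False

    @property
    def n_chains(self) -> int:
        return self.phi.shape[0]

    @property
    def n_draws(self) -> int:
        return self.phi.shape[1]

    @property
    def D(self) -> np.ndarray | None:
        if self.N is None or self.state_space is None:
            return None
        return self.N / self.state_space.area

    def scalars(self) -> dict[str, np.ndarray]:
        """All tracked quantities as named (n_chains, n_draws) arrays."""
        out: dict[str, np.ndarray] = {
            "phi": self.phi, "lambda0": self.lambda0, "sigma_p": self.sigma_p,
        }
        if self.sigma_s is not None:
            out["sigma_s"] = self.sigma_s
        if self.gamma is not None:
            for t in range(self.gamma.shape[2]):
                out[f"gamma[{t + 1}]"] = self.gamma[:, :, t]
        if self.N is not None:
            D = self.D
            for t in range(self.N.shape[2]):
                out[f"N[{t + 1}]"] = self.N[:, :, t]
                out[f"D[{t + 1}]"] = D[:, :, t]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """One row per retained iteration x chain, one column per scalar."""
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws),
                "iteration": np.tile(np.arange(self.n_draws), self.n_chains)}
        for name, arr in self.scalars().items():
            cols[name] = arr.reshape(-1)
        return pd.DataFrame(cols)


def summarize_posterior(samples: "PosteriorSamples | Mapping[str, np.ndarray]"
                        ) -> pd.DataFrame:
    """Posterior mean, SD and central 95% credible interval per parameter."""
    if isinstance(samples, PosteriorSamples):
        samples = samples.scalars()
    rows = {}
    for name, arr in samples.items():
        flat = np.asarray(arr, dtype=float).reshape(-1)
        q = np.quantile(flat, [0.025, 0.5, 0.975])
        rows[name] = {
            "mean": flat.mean(), "sd": flat.std(ddof=1) if flat.size > 1 else 0.0,
            "q2.5": q[0], "median": q[1], "q97.5": q[2],
        }
    return pd.DataFrame(rows).T


def _psrf(chains: np.ndarray) -> float:
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(samples: "PosteriorSamples | Mapping[str, np.ndarray]"
                 ) -> dict[str, float]:
    """Potential scale reduction factor (plain Gelman-Rubin) per parameter.

    Requires at least two chains; values near 1 indicate the chains agree,
    values above ~1.1 flag non-convergence.
    """
    if isinstance(samples, PosteriorSamples):
        samples = samples.scalars()
    out = {}
    for name, arr in samples.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("gelman_rubin needs >= 2 chains per parameter")
        out[name] = _psrf(arr)
    return out


def unequal_intervals(config: FitConfig, delta_t) -> FitConfig:
    """Configure unequal primary-period spacing.

    ``delta_t[t]`` is the interval length between periods ``t`` and
    ``t+1``; survival over it is ``phi ** delta_t[t]`` and the reported
    ``phi`` stays per unit interval (annual, for yearly units).
    """
    delta_t = np.asarray(delta_t, dtype=float)
    if delta_t.ndim != 1 or (delta_t <= 0).any():
        raise ValueError("delta_t must be a 1-D vector of positive lengths")
    return replace(config, delta_t=delta_t)


# ---------------------------------------------------------------------------


def _canonical_order(y: np.ndarray) -> np.ndarray:
    """Order individuals by their encounter history so that relabelled
    input reaches the sampler in an identical layout (exchangeability)."""
    if y.shape[0] == 0:
        return np.arange(0)
    flat = y.reshape(y.shape[0], -1)
    return np.lexsort(flat.T[::-1])


def _init_centers(y: np.ndarray, traps: TrapArray, S: StateSpace,
                  rng: np.random.Generator,
                  shared: bool) -> tuple[np.ndarray, np.ndarray]:
    """Initial activity centers at detection-weighted trap locations.

    ``shared`` (constant movement) forces one common location per
    individual across all periods.  This is a state-validity requirement,
    not a tuning choice: the constant-model center update evaluates
    proposals against the cached per-period likelihoods, and a
    period-inconsistent start can dominate every single shared location,
    leaving the individual frozen in a configuration the model cannot
    actually represent.
    """
    M, J, T = y.shape
    coords = traps.coords()
    if shared:
        sx = np.repeat(rng.uniform(S.xmin, S.xmax, size=(M, 1)), T, axis=1)
        sy = np.repeat(rng.uniform(S.ymin, S.ymax, size=(M, 1)), T, axis=1)
    else:
        sx = rng.uniform(S.xmin, S.xmax, size=(M, T))
        sy = rng.uniform(S.ymin, S.ymax, size=(M, T))
    tot = y.sum(axis=2)                       # (M, J)
    detected = tot.sum(axis=1) > 0
    for i in np.flatnonzero(detected):
        overall = coords.T @ tot[i] / tot[i].sum()
        for t in range(T):
            if shared:
                cx, cy = overall
            else:
                w = y[i, :, t]
                if w.sum() > 0:
                    cx, cy = coords.T @ w / w.sum()
                else:
                    cx, cy = overall
            sx[i, t] = np.clip(cx, S.xmin, S.xmax)
            sy[i, t] = np.clip(cy, S.ymin, S.ymax)
    return sx, sy


def _run_fit(data: EncounterData, traps: TrapArray, config: FitConfig,
             cjs: bool) -> PosteriorSamples:
    data.validate_against(traps)
    T = traps.n_periods
    S = config.state_space
    if S is None:
        raise ValueError("FitConfig.state_space is required")
    if not S.contains_traps(traps):
        raise ValueError("state space must contain all traps")
    delta_t = (np.ones(T - 1) if config.delta_t is None
               else np.asarray(config.delta_t, dtype=float))
    if delta_t.shape != (T - 1,):
        raise ValueError(
            f"delta_t must have length T-1={T - 1}, got {delta_t.shape[0]}")

    order = _canonical_order(data.y)
    y_obs = data.y[order]
    if cjs:
        y = y_obs.astype(np.int64)
        M = data.n_observed
        if M == 0:
            raise ValueError("CJS model needs at least one observed individual")
    else:
        M = config.M
        if M < data.n_observed:
            raise ValueError("augmented size M below number observed")
        y = np.zeros((M, traps.n_traps, T), dtype=np.int64)
        y[: data.n_observed] = y_obs
    first_det = np.where(y.sum(axis=1) > 0, 1, 0).argmax(axis=1)

    sigp_max = config.sigma_p_max or S.max_side
    sigs_max = config.sigma_s_max or S.max_side
    movement = _MOVEMENT_CODE[MovementModel(config.movement_model)]
    n_keep = (config.n_iter - config.n_burnin + config.thin - 1) // config.thin

    nn = _trap_scale(traps, S)
    chains = []
    for c in range(config.n_chains):
        chain_seed = int((config.seed + c) % (2 ** 31 - 1))
        rng = np.random.default_rng(chain_seed)
        sx, sy = _init_centers(
            y, traps, S, rng,
            shared=MovementModel(config.movement_model) is MovementModel.CONSTANT)
        if config.init_centers is not None:
            sx = np.ascontiguousarray(config.init_centers[..., 0], dtype=float)
            sy = np.ascontiguousarray(config.init_centers[..., 1], dtype=float)
        z = np.zeros((M, T), dtype=np.int8)
        for i in range(M):
            if y[i].sum() > 0:
                det = np.flatnonzero(y[i].sum(axis=0) > 0)
                z[i, det[0]: det[-1] + 1] = 1
        phi0 = rng.uniform(0.3, 0.9)
        lam0 = (config.init_lambda0 if config.init_lambda0 is not None
                else rng.uniform(0.2, 1.5))
        sigp0 = (config.init_sigma_p if config.init_sigma_p is not None
                 else nn * rng.uniform(0.4, 1.2))
        sigs0 = nn * rng.uniform(0.4, 1.2)

        out_phi = np.empty(n_keep)
        out_gamma = np.empty((n_keep, T))
        out_lam0 = np.empty(n_keep)
        out_sigp = np.empty(n_keep)
        out_sigs = np.empty(n_keep)
        out_N = np.empty((n_keep, T))
        out_z = (np.zeros((n_keep, M, T), dtype=np.int8) if config.keep_z
                 else np.zeros((1, 1, 1), dtype=np.int8))
        kept, *_ = _sampler.run_sampler(
            y, np.ascontiguousarray(traps.effort),
            np.ascontiguousarray(traps.x), np.ascontiguousarray(traps.y),
            S.xmin, S.xmax, S.ymin, S.ymax,
            movement, delta_t,
            cjs, first_det.astype(np.int64),
            z, sx, sy,
            phi0, lam0, sigp0, sigs0,
            config.lambda0_max, sigp_max, sigs_max,
            config.n_iter, config.n_burnin, config.thin, chain_seed,
            config.fix_centers, config.fix_detection, config.fix_z,
            out_phi, out_gamma, out_lam0, out_sigp, out_sigs, out_N, out_z,
            config.keep_z,
        )
        chains.append((out_phi[:kept], out_gamma[:kept], out_lam0[:kept],
                       out_sigp[:kept], out_sigs[:kept], out_N[:kept],
                       out_z[:kept] if config.keep_z else None))

    stack = lambda k: np.stack([ch[k] for ch in chains])
    movement_enum = MovementModel(config.movement_model)
    post = PosteriorSamples(
        phi=stack(0),
        gamma=None if cjs else stack(1),
        lambda0=stack(2),
        sigma_p=stack(3),
        sigma_s=stack(4) if movement_enum is MovementModel.MARKOVIAN else None,
        N=None if cjs else stack(5),
        state_space=S,
        movement_model=movement_enum,
        M=None if cjs else M,
        z=stack(6) if config.keep_z else None,
    )
    if not cjs and post.N is not None and (post.N.max(axis=2) >= M - 1).mean() > 0.01:
        post.saturated = True
        warnings.warn(
            "posterior abundance piles up near the augmented size M; "
            "increase M", stacklevel=2)
    return post


def _trap_scale(traps: TrapArray, S: StateSpace) -> float:
    """Mean nearest-neighbour trap distance (initialization scale)."""
    if traps.n_traps < 2:
        return S.max_side / 10.0
    coords = traps.coords()
    d = np.hypot(coords[:, None, 0] - coords[None, :, 0],
                 coords[:, None, 1] - coords[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def fit_open_scr(data: EncounterData, traps: TrapArray,
                 config: FitConfig) -> PosteriorSamples:
    """Fit the full (Jolly-Seber, data-augmented) open SCR model by MCMC."""
    return _run_fit(data, traps, config, cjs=False)


def fit_cjs(data: EncounterData, traps: TrapArray,
            config: FitConfig) -> PosteriorSamples:
    """Fit the survival-only (Cormack-Jolly-Seber) open SCR model by MCMC."""
    return _run_fit(data, traps, config, cjs=True)


# ---------------------------------------------------------------------------
# sklearn-style estimators


class _OpenSCRBase(BaseEstimator):
    _cjs = False

    def __init__(self, movement_model="constant", buffer=2.0,
                 state_space=None, M=150, n_chains=3, n_iter=10500,
                 n_burnin=500, thin=2, seed=0, delta_t=None,
                 lambda0_max=10.0, sigma_p_max=None, sigma_s_max=None,
                 keep_z=False):
        self.movement_model = movement_model
        self.buffer = buffer
        self.state_space = state_space
        self.M = M
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.seed = seed
        self.delta_t = delta_t
        self.lambda0_max = lambda0_max
        self.sigma_p_max = sigma_p_max
        self.sigma_s_max = sigma_s_max
        self.keep_z = keep_z

    def _config(self, traps: TrapArray) -> FitConfig:
        S = self.state_space or make_state_space(traps, self.buffer)
        return FitConfig(
            movement_model=self.movement_model, M=self.M, state_space=S,
            n_chains=self.n_chains, n_iter=self.n_iter,
            n_burnin=self.n_burnin, thin=self.thin, seed=self.seed,
            delta_t=self.delta_t, lambda0_max=self.lambda0_max,
            sigma_p_max=self.sigma_p_max, sigma_s_max=self.sigma_s_max,
            keep_z=self.keep_z,
        )

    def fit(self, X: EncounterData, traps: TrapArray):
        """Run the MCMC on encounter data ``X`` observed at ``traps``."""
        config = self._config(traps)
        post = _run_fit(X, traps, config, cjs=self._cjs)
        self.config_ = config
        self.posterior_ = post
        self.summary_ = summarize_posterior(post)
        self.rhat_ = (gelman_rubin(post) if config.n_chains >= 2 else None)
        self.phi_mean_ = float(post.phi.mean())
        self.lambda0_mean_ = float(post.lambda0.mean())
        self.sigma_p_mean_ = float(post.sigma_p.mean())
        self.sigma_s_mean_ = (float(post.sigma_s.mean())
                              if post.sigma_s is not None else None)
        if post.N is not None:
            self.N_mean_ = post.N.mean(axis=(0, 1))
            self.D_mean_ = post.D.mean(axis=(0, 1))
        return self


class OpenSCRJollySeber(_OpenSCRBase):
    """Open-population SCR model with data augmentation.

    Estimates survival, per-period recruitment, detection, movement and
    abundance/density.  ``buffer`` (in coordinate units) builds the
    analysis state space around the trap array unless an explicit
    ``state_space`` is given.
    """

    _cjs = False


class OpenSCRCormackJollySeber(_OpenSCRBase):
    """Survival-only open SCR model conditioning on first capture."""

    _cjs = True

    def __init__(self, movement_model="constant", buffer=2.0,
                 state_space=None, n_chains=3, n_iter=10500, n_burnin=500,
                 thin=2, seed=0, delta_t=None, lambda0_max=10.0,
                 sigma_p_max=None, sigma_s_max=None, keep_z=False):
        super().__init__(
            movement_model=movement_model, buffer=buffer,
            state_space=state_space, M=0, n_chains=n_chains, n_iter=n_iter,
            n_burnin=n_burnin, thin=thin, seed=seed, delta_t=delta_t,
            lambda0_max=lambda0_max, sigma_p_max=sigma_p_max,
            sigma_s_max=sigma_s_max, keep_z=keep_z)
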