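"""Core probability model for open-population spatial capture-recapture (SCR).

An open (Jolly-Seber-type) SCR model observes counts ``y[i, j, t]`` of
individual ``i`` at trap ``j`` during primary period ``t``.  Conditional on
the individual being alive (``z[i, t] = 1``) and on its latent activity
center ``s[i, t]``, counts are Binomial over the ``K[j, t]`` days the trap
was active, with a detection probability that declines with the distance
between trap and activity center.  Between primary periods individuals
survive with probability ``phi``, previously-unrecruited individuals enter
with conditional entrance probability ``gamma[t]``, and activity centers
either stay put (constant), resample uniformly over the state space
(independent), or follow a Gaussian random walk truncated to the state
space (markovian).

Everything in this module is a pure, stateless function of its arguments;
the simulator and the MCMC sampler both build on it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MovementModel",
    "TrapArray",
    "StateSpace",
    "EncounterData",
    "LatentState",
    "Parameters",
    "detection_prob",
    "observation_logpmf",
    "transition_prob",
    "interval_survival",
    "movement_logdensity",
    "derived_abundance",
    "density",
]


class MovementModel(str, enum.Enum):
    """How activity centers change between primary periods."""

    CONSTANT = "constant"
    INDEPENDENT = "independent"
    MARKOVIAN = "markovian"
    #: Markovian walk with occasional long-distance relocations (uniform
    #: redraw with probability ``p_jump``); generation-only scenario used in
    #: movement-misspecification experiments.
    MARKOVIAN_JUMP = "markovian_jump"


def _as_movement(model: "MovementModel | str") -> MovementModel:
    if isinstance(model, MovementModel):
        return model
    try:
        return MovementModel(str(model).lower())
    except ValueError:
        raise ValueError(
            f"unknown movement model {model!r}; expected one of "
            f"{[m.value for m in MovementModel]}"
        ) from None


@dataclass
class TrapArray:
    """Planar trap coordinates plus per-period sampling effort.

    Parameters
    ----------
    trap_id : array-like of str or int, shape (J,)
    x, y : float arrays, shape (J,)
        Planar coordinates in arbitrary units (km for field data).
    effort : int array, shape (J, T)
        ``effort[j, t]`` = number of days trap ``j`` was active in primary
        period ``t``.  Zero is allowed (trap not deployed that period).
    """

    trap_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    effort: np.ndarray

    def __post_init__(self) -> None:
        self.trap_id = np.asarray(self.trap_id)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.effort = np.atleast_2d(np.asarray(self.effort, dtype=np.int64))
        if len({self.x.shape[0], self.y.shape[0], self.trap_id.shape[0],
                self.effort.shape[0]}) != 1:
            raise ValueError("trap_id, x, y and effort must share the trap axis")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("trap coordinates must be finite")
        if (self.effort < 0).any():
            raise ValueError("effort K[j,t] must be non-negative")
        if len(np.unique(self.trap_id)) != self.n_traps:
            raise ValueError("duplicate trap_id")
        if not (self.effort.sum(axis=0) > 0).all():
            raise ValueError("every primary period needs at least one active trap")

    @property
    def n_traps(self) -> int:
        return self.x.shape[0]

    @property
    def n_periods(self) -> int:
        return self.effort.shape[1]

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class StateSpace:
    """Rectangular spatial domain S over which activity centers live."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    #: optional provenance: the buffer width (same units as coordinates)
    #: used to build the rectangle around the trap array.
    buffer: float | None = None

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("state space must have positive extent")

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def max_side(self) -> float:
        return max(self.xmax - self.xmin, self.ymax - self.ymin)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.xmin) & (x <= self.xmax)
            & (y >= self.ymin) & (y <= self.ymax)
        )

    def contains_traps(self, traps: TrapArray) -> bool:
        return bool(self.contains(traps.x, traps.y).all())


@dataclass
class EncounterData:
    """Detection counts for the observed individuals, ready for augmentation.

    ``y[i, j, t]`` is the number of days individual ``i`` was recorded at
    trap ``j`` in period ``t`` (at most one record per trap-day, hence
    ``y <= K``).  ``M`` is the augmented population size: the model adds
    ``M - n_observed`` all-zero encounter histories representing
    hypothetical individuals that may or may not have been part of the
    population.
    """

    y: np.ndarray
    M: int
    individual_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.ndim != 3:
            raise ValueError("y must be (n_observed, n_traps, n_periods)")
        if (self.y < 0).any():
            raise ValueError("counts must be non-negative")
        if self.n_observed and not (self.y.sum(axis=(1, 2)) > 0).all():
            raise ValueError("every observed individual needs >= 1 detection")
        if self.M < self.n_observed:
            raise ValueError("augmented size M must be >= n_observed")
        if self.individual_id is None:
            self.individual_id = np.arange(self.n_observed)
        self.individual_id = np.asarray(self.individual_id)

    @property
    def n_observed(self) -> int:
        return self.y.shape[0]

    @property
    def n_periods(self) -> int:
        return self.y.shape[2]

    def validate_against(self, traps: TrapArray) -> None:
        if self.y.shape[1] != traps.n_traps:
            raise ValueError("trap axis of y does not match trap array")
        if self.y.shape[2] != traps.n_periods:
            raise ValueError("period axis of y does not match trap effort")
        if (self.y > traps.effort[None, :, :]).any():
            raise ValueError("counts exceed trap effort (y > K)")

    def augmented(self) -> np.ndarray:
        """Return the (M, J, T) count array with all-zero rows appended."""
        full = np.zeros((self.M, self.y.shape[1], self.y.shape[2]), np.int64)
        full[: self.n_observed] = self.y
        return full


@dataclass
class LatentState:
    """Full latent state for M (augmented) individuals over T periods."""

    z: np.ndarray          # (M, T) binary alive indicator
    s: np.ndarray          # (M, T, 2) activity centers (NaN where undefined)
    alpha: np.ndarray = field(init=False)   # (M, T) recruitment availability
    first_entry: np.ndarray = field(init=False)  # (M,) period index or -1

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int8)
        self.s = np.asarray(self.s, dtype=float)
        M, T = self.z.shape
        ever = np.cumsum(self.z, axis=1)
        # available for recruitment at t iff never alive in 1..t-1
        self.alpha = np.ones((M, T), dtype=np.int8)
        self.alpha[:, 1:] = (ever[:, :-1] == 0).astype(np.int8)
        alive_any = self.z.any(axis=1)
        self.first_entry = np.where(alive_any, self.z.argmax(axis=1), -1)
        # dead-forever: z may never return to 1 after a 1->0 transition
        for i in range(M):
            row = self.z[i]
            if row.any():
                on = np.flatnonzero(row)
                if not (np.diff(on) == 1).all():
                    raise ValueError("invalid life history: revival after death")


@dataclass
class Parameters:
    """Demographic, detection and movement parameters.

    ``phi`` is per-unit-interval survival; over an interval of length
    ``delta_t`` survival is ``phi ** delta_t``.  ``gamma[t]`` is the
    conditional entrance probability for period ``t`` (``gamma[0]`` doubles
    as the initial inclusion probability).  ``lambda0`` is the baseline
    daily encounter rate at distance zero and ``sigma_p`` the spatial scale
    of the detection kernel.  ``sigma_s`` is the per-axis SD of the
    between-period Gaussian random walk (markovian model only).
    """

    phi: float
    gamma: np.ndarray
    lambda0: float
    sigma_p: float
    sigma_s: float | None = None
    movement_model: MovementModel = MovementModel.CONSTANT
    delta_t: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.movement_model = _as_movement(self.movement_model)
        if not (0.0 < self.phi < 1.0):
            raise ValueError("phi must be in (0, 1)")
        if ((self.gamma < 0.0) | (self.gamma > 1.0)).any():
            raise ValueError("gamma must be in [0, 1]")
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be positive")
        if not self.sigma_p > 0:
            raise ValueError("sigma_p must be positive")
        if self.movement_model in (MovementModel.MARKOVIAN,
                                   MovementModel.MARKOVIAN_JUMP):
            if self.sigma_s is None or not self.sigma_s > 0:
                raise ValueError("markovian movement requires sigma_s > 0")
        if self.delta_t is not None:
            self.delta_t = np.asarray(self.delta_t, dtype=float)
            if (self.delta_t <= 0).any():
                raise ValueError("delta_t must be positive")


# ---------------------------------------------------------------------------
# operations


def detection_prob(d, lambda0, sigma_p):
    """Per-day detection probability at distance ``d`` from the activity center.

    Complementary log-log form of the half-normal encounter-rate model::

        p = 1 - exp(-lambda0 * exp(-d^2 / (2 sigma_p^2)))

    which is the probability of at least one detection in a day when
    encounters occur at Poisson rate ``lambda0 * exp(-d^2/(2 sigma_p^2))``.
    Strictly decreasing in ``d``, strictly increasing in ``lambda0``, and
    always inside (0, 1).
    """
    d = np.asarray(d, dtype=float)
    if not np.isfinite(d).all() or (d < 0).any():
        raise ValueError("distance must be finite and non-negative")
    if not (np.isfinite(lambda0) and lambda0 > 0):
        raise ValueError("lambda0 must be positive and finite")
    if not (np.isfinite(sigma_p) and sigma_p > 0):
        raise ValueError("sigma_p must be positive and finite")
    out = -np.expm1(-lambda0 * np.exp(-(d ** 2) / (2.0 * sigma_p ** 2)))
    return out if out.ndim else float(out)


def observation_logpmf(y, K, z, p):
    """Log-probability of count ``y`` out of ``K`` trap-days.

    Dead or not-yet-recruited individuals (``z = 0``) produce zero counts
    with probability one; alive individuals produce Binomial(K, p) counts.
    """
    y = int(y)
    K = int(K)
    if y < 0 or y > K:
        raise ValueError(f"count y={y} outside Binomial support [0, {K}]")
    if not z:
        return 0.0 if y == 0 else -math.inf
    return float(stats.binom.logpmf(y, K, p))


def transition_prob(z_prev, alpha, phi_interval, gamma_t):
    """P(z_t = 1) given the previous alive state and recruitment availability.

    Survivors persist with probability ``phi_interval``; available
    (never-yet-alive) individuals enter with probability ``gamma_t``; dead
    individuals stay dead.
    """
    if z_prev and alpha:
        raise ValueError("z_prev=1 and alpha=1 are mutually exclusive")
    if z_prev:
        return float(phi_interval)
    if alpha:
        return float(gamma_t)
    return 0.0


def interval_survival(phi_unit, delta_t):
    """Survival over an interval of length ``delta_t``: ``phi ** delta_t``."""
    if not (0.0 < phi_unit < 1.0):
        raise ValueError("phi_unit must be in (0, 1)")
    if not delta_t > 0:
        raise ValueError("delta_t must be positive")
    return float(phi_unit) ** float(delta_t)


def truncated_normal_mass(mu, sigma, lo, hi):
    """Probability mass of N(mu, sigma^2) inside [lo, hi] (vectorized)."""
    mu = np.asarray(mu, dtype=float)
    return stats.norm.cdf((hi - mu) / sigma) - stats.norm.cdf((lo - mu) / sigma)


def movement_logdensity(s_t, s_prev, model, sigma_s, S: StateSpace):
    """Log-density of an activity center transition between primary periods.

    constant
        point mass at ``s_prev`` (0 if ``s_t == s_prev`` else -inf).
    independent
        uniform over S: ``-log(area(S))``.
    markovian
        bivariate normal centered at ``s_prev`` with per-axis SD
        ``sigma_s``, truncated to S; on a rectangle the normalizing mass
        factorizes into two 1-D truncated-normal masses, which are computed
        exactly so the density integrates to one over S.
    """
    model = _as_movement(model)
    s_t = np.asarray(s_t, dtype=float)
    s_prev = np.asarray(s_prev, dtype=float)
    for pt in (s_t, s_prev):
        if not S.contains(pt[0], pt[1]):
            raise ValueError(f"point {pt} outside the state space")
    if model is MovementModel.CONSTANT:
        return 0.0 if np.array_equal(s_t, s_prev) else -math.inf
    if model is MovementModel.INDEPENDENT:
        return -math.log(S.area)
    if sigma_s is None or not sigma_s > 0:
        raise ValueError("markovian movement requires sigma_s > 0")
    logpdf = (
        stats.norm.logpdf(s_t[0], s_prev[0], sigma_s)
        + stats.norm.logpdf(s_t[1], s_prev[1], sigma_s)
    )
    mass_x = truncated_normal_mass(s_prev[0], sigma_s, S.xmin, S.xmax)
    mass_y = truncated_normal_mass(s_prev[1], sigma_s, S.ymin, S.ymax)
    return float(logpdf - math.log(mass_x) - math.log(mass_y))


def derived_abundance(z):
    """Abundance, recruits and per-capita recruitment from alive indicators.

    Returns ``(N, R, per_capita)`` where ``N[t] = sum_i z[i, t]``, ``R[t]``
    counts first entries at ``t`` and ``per_capita[t] = R[t] / N[t-1]``
    (NaN for the first period, where it is undefined).
    """
    z = np.asarray(z)
    if not np.isin(z, (0, 1)).all():
        raise ValueError("z must be binary")
    N = z.sum(axis=0).astype(float)
    ever_before = np.zeros_like(z)
    ever_before[:, 1:] = np.cumsum(z[:, :-1], axis=1)
    R = ((z == 1) & (ever_before == 0)).sum(axis=0).astype(float)
    per_capita = np.full(z.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_capita[1:] = np.where(N[:-1] > 0, R[1:] / N[:-1], np.nan)
    return N, R, per_capita


def density(N_t, S: StateSpace, scale: float = 1.0):
    """Population density ``N_t / area(S)``, optionally rescaled.

    ``scale=100.0`` reports individuals per 100 area units (the convention
    for tigers per 100 km^2).
    """
    if S.area <= 0:
        raise ValueError("state space area must be positive")
    return np.asarray(N_t, dtype=float) / S.area * scale
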