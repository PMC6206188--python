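import itertools
import math

import numpy as np
import pytest
from hypothesis import settings
from scipy import stats
from scipy.special import betaln

from openscr.infer import FitConfig, fit_open_scr
from openscr.model import EncounterData, StateSpace, TrapArray, detection_prob
from openscr.simulate import SimulationConfig, make_state_space, simulate_scenario

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One benchmark-design dataset (constant movement), reused read-only."""
    return simulate_scenario(SimulationConfig(movement_model="constant",
                                              seed=20240917))


@pytest.fixture(scope="session")
def short_fit(default_dataset):
    """A short matched fit of the default dataset, reused read-only."""
    sim = default_dataset
    config = FitConfig(movement_model="constant", M=150,
                       state_space=make_state_space(sim.traps, 2.0),
                       n_chains=2, n_iter=1500, n_burnin=500, thin=2,
                       seed=42, keep_z=True)
    return fit_open_scr(sim.data, sim.traps, config)


# ---------------------------------------------------------------------------
# brute-force posterior enumeration for the tiny two-period instance


TINY_K = 5
TINY_LAMBDA0 = 0.5
TINY_SIGMA_P = 0.5
# individual states over T=2 as (z1, z2)
TINY_STATES = [(0, 0), (1, 0), (0, 1), (1, 1)]


def tiny_instance():
    """T=2, one trap, M=3 (two observed): small enough to enumerate."""
    traps = TrapArray(trap_id=[1], x=[0.0], y=[0.0],
                      effort=np.full((1, 2), TINY_K))
    y = np.zeros((2, 1, 2), dtype=int)
    y[0, 0, 0] = 2
    y[1, 0, 1] = 3
    data = EncounterData(y=y, M=3)
    S = StateSpace(-1.0, 1.0, -1.0, 1.0)
    return traps, data, S


def enumerate_tiny_posterior():
    """Exact posterior over the 4^3 joint z-configurations.

    Centers are fixed at the trap, detection parameters known, so the only
    unknowns are (z, phi, gamma_1, gamma_2); phi and gamma_t integrate out
    analytically against their Uniform(0,1) priors via Beta functions.
    """
    traps, data, _ = tiny_instance()
    M = 3
    p = detection_prob(0.0, TINY_LAMBDA0, TINY_SIGMA_P)
    y = np.zeros((M, 1, 2), dtype=int)
    y[: data.n_observed] = data.y

    def obs_ll(i, st):
        tot = 0.0
        for t in range(2):
            if st[t] == 1:
                tot += stats.binom.logpmf(y[i, 0, t], TINY_K, p)
            elif y[i, 0, t] > 0:
                return -np.inf
        return tot

    logpost = {}
    for combo in itertools.product(range(4), repeat=M):
        ll = sum(obs_ll(i, TINY_STATES[c]) for i, c in enumerate(combo))
        if ll == -np.inf:
            continue
        z1 = [TINY_STATES[c][0] for c in combo]
        z2 = [TINY_STATES[c][1] for c in combo]
        n1 = sum(z1)
        ll += betaln(1 + n1, 1 + M - n1)          # gamma_1 integral
        surv = sum(a and b for a, b in zip(z1, z2))
        died = sum(a and not b for a, b in zip(z1, z2))
        ll += betaln(1 + surv, 1 + died)          # phi integral
        avail = sum(1 - a for a in z1)
        rec = sum((not a) and b for a, b in zip(z1, z2))
        ll += betaln(1 + rec, 1 + avail - rec)    # gamma_2 integral
        logpost[combo] = ll
    mx = max(logpost.values())
    Z = sum(math.exp(v - mx) for v in logpost.values())
    return {k: math.exp(v - mx) / Z for k, v in logpost.items()}


def tiny_mcmc_config(n_draws, seed):
    _, _, S = tiny_instance()
    return FitConfig(
        movement_model="constant", M=3, state_space=S, n_chains=1,
        n_iter=n_draws + 5000, n_burnin=5000, thin=1, seed=seed, keep_z=True,
        fix_centers=True, fix_detection=True,
        init_lambda0=TINY_LAMBDA0, init_sigma_p=TINY_SIGMA_P,
        init_centers=np.zeros((3, 2, 2)))


def tiny_mcmc_distribution(n_draws=100_000, seed=5):
    """Empirical distribution over joint z-configs from the MCMC sampler.

    The sampler orders individuals canonically by encounter history (the
    row detected in period 2 sorts first), so indices are mapped back to
    the original labels before tallying.
    """
    traps, data, _ = tiny_instance()
    post = fit_open_scr(data, traps, tiny_mcmc_config(n_draws, seed))
    smap = {s: k for k, s in enumerate(TINY_STATES)}
    z = post.z[0]
    counts = {}
    for draw in z:
        codes = [smap[(int(draw[i, 0]), int(draw[i, 1]))] for i in range(3)]
        key = (codes[1], codes[0], codes[2])   # undo the canonical sort
        counts[key] = counts.get(key, 0) + 1
    n = len(z)
    return {k: v / n for k, v in counts.items()}


def total_variation(p, q):
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
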