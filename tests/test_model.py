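import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import integrate

from openscr.model import (
    EncounterData,
    LatentState,
    MovementModel,
    Parameters,
    StateSpace,
    TrapArray,
    density,
    derived_abundance,
    detection_prob,
    interval_survival,
    movement_logdensity,
    observation_logpmf,
    transition_prob,
)


class TestDetectionProb:
    @pytest.mark.parametrize("d,lam0,sigp,expected", [
        (0.0, 0.5, 0.5, 1 - math.exp(-0.5)),          # kernel collapses to 1
        (0.5, 0.5, 0.5, 1 - math.exp(-0.5 * math.exp(-0.5))),
        (1e6, 0.5, 0.5, 0.0),                          # vanishes at distance
    ])
    def test_closed_form(self, d, lam0, sigp, expected):
        assert detection_prob(d, lam0, sigp) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_reference_values(self):
        # independent numeric evaluation: 1 - exp(-0.5) and
        # 1 - exp(-0.5 * e^{-0.5})
        assert detection_prob(0.0, 0.5, 0.5) == pytest.approx(0.393469, abs=1e-6)
        assert detection_prob(0.5, 0.5, 0.5) == pytest.approx(0.261597, abs=1e-6)

    @given(st.floats(0.01, 20.0), st.floats(0.01, 9.9), st.floats(0.05, 5.0))
    def test_decreasing_in_distance_and_bounded(self, d, lam0, sigp):
        p = detection_prob(d, lam0, sigp)
        assert 0.0 <= p < 1.0
        assert p < detection_prob(d * 0.9, lam0, sigp) + 1e-15

    @given(st.floats(0.0, 5.0), st.floats(0.01, 5.0), st.floats(0.05, 5.0))
    def test_increasing_in_lambda0(self, d, lam0, sigp):
        assume(d ** 2 / (2 * sigp ** 2) < 500)   # kernel above underflow
        assert (detection_prob(d, lam0 * 1.1, sigp)
                > detection_prob(d, lam0, sigp))

    @pytest.mark.parametrize("bad", [
        dict(d=-0.1, lambda0=0.5, sigma_p=0.5),
        dict(d=np.nan, lambda0=0.5, sigma_p=0.5),
        dict(d=1.0, lambda0=0.0, sigma_p=0.5),
        dict(d=1.0, lambda0=0.5, sigma_p=-1.0),
    ])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            detection_prob(bad["d"], bad["lambda0"], bad["sigma_p"])


class TestObservationLogpmf:
    def test_dead_individuals_yield_zero_counts(self):
        assert observation_logpmf(0, 5, 0, 0.9) == 0.0
        assert observation_logpmf(1, 5, 0, 0.9) == -math.inf

    def test_alive_binomial(self):
        # brute-force pmf: C(5,2) p^2 (1-p)^3 at p = 0.26166
        p = 0.26166
        expected = math.log(10 * p ** 2 * (1 - p) ** 3)
        assert observation_logpmf(2, 5, 1, p) == pytest.approx(expected,
                                                               abs=1e-9)
        assert observation_logpmf(3, 5, 1, 0.0) == -math.inf

    def test_count_outside_support(self):
        with pytest.raises(ValueError):
            observation_logpmf(6, 5, 1, 0.3)


class TestTransitions:
    def test_transition_prob_cases(self):
        assert transition_prob(1, 0, 0.75, 0.1) == 0.75
        assert transition_prob(0, 0, 0.75, 0.1) == 0.0
        assert transition_prob(0, 1, 0.75, 0.1) == 0.1
        with pytest.raises(ValueError):
            transition_prob(1, 1, 0.75, 0.1)

    @pytest.mark.parametrize("phi,dt,expected", [
        (0.75, 1.0, 0.75),
        (0.75, 2.0, 0.5625),
        (0.9, 0.5, 0.9 ** 0.5),
    ])
    def test_interval_survival(self, phi, dt, expected):
        assert interval_survival(phi, dt) == pytest.approx(expected, rel=1e-12)

    def test_interval_survival_identity_exact(self):
        assert interval_survival(0.75, 1.0) == 0.75


class TestMovementDensity:
    S = StateSpace(0.0, 10.0, 0.0, 10.0)

    def test_independent_uniform(self):
        got = movement_logdensity((3, 3), (7, 7), "independent", None, self.S)
        assert got == pytest.approx(-math.log(100.0))

    def test_constant_point_mass(self):
        assert movement_logdensity((3, 3), (3, 3), "constant", None, self.S) == 0.0
        assert movement_logdensity((3, 3), (3, 4), "constant", None,
                                   self.S) == -math.inf

    def test_markovian_interior_matches_bivariate_normal(self):
        # boundary >= 6 sigma away: truncation mass is 1 to double precision
        got = movement_logdensity((5.5, 5.0), (5.0, 5.0), "markovian", 0.5,
                                  self.S)
        expected = math.log(1 / (2 * math.pi * 0.25) * math.exp(-0.5))
        assert got == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-0.951583, abs=1e-6)

    def test_markovian_mode_at_previous_center(self):
        at_prev = movement_logdensity((5, 5), (5, 5), "markovian", 0.3, self.S)
        off = movement_logdensity((5.4, 5), (5, 5), "markovian", 0.3, self.S)
        assert at_prev > off

    @pytest.mark.parametrize("s_prev,sigma_s", [
        ((5.0, 5.0), 0.5),
        ((0.2, 0.3), 0.5),     # near a corner: truncation mass far below 1
        ((9.9, 5.0), 2.0),
    ])
    def test_markovian_integrates_to_one(self, s_prev, sigma_s):
        S = self.S

        def f(yv, xv):
            return math.exp(movement_logdensity((xv, yv), s_prev,
                                                "markovian", sigma_s, S))

        total, err = integrate.dblquad(f, S.xmin, S.xmax, S.ymin, S.ymax,
                                       epsabs=1e-8)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_point_outside_domain(self):
        with pytest.raises(ValueError):
            movement_logdensity((11, 5), (5, 5), "independent", None, self.S)


class TestDerivedQuantities:
    def test_abundance_recruits_per_capita(self):
        z = np.array([[1, 1], [0, 1], [1, 0]])
        N, R, pc = derived_abundance(z)
        assert N.tolist() == [2.0, 2.0]
        assert R.tolist() == [2.0, 1.0]
        assert np.isnan(pc[0]) and pc[1] == pytest.approx(0.5)

    def test_abundance_degenerate(self):
        N, R, _ = derived_abundance(np.zeros((4, 3), dtype=int))
        assert N.tolist() == [0, 0, 0] and R.tolist() == [0, 0, 0]
        _, R1, _ = derived_abundance(np.array([[1, 1]]))
        assert R1.tolist() == [1.0, 0.0]

    def test_density(self):
        S = StateSpace(0, 10, 0, 10)
        assert density(40, S) == pytest.approx(0.40)
        assert density(0, S) == 0.0
        S2 = StateSpace(0, 23.18, 0, 10.0)
        assert density(13, S2, scale=100.0) == pytest.approx(5.61, abs=5e-3)


class TestContainers:
    def test_trap_array_invariants(self):
        with pytest.raises(ValueError):
            TrapArray(trap_id=[1, 1], x=[0, 1], y=[0, 1],
                      effort=np.ones((2, 2), int))
        with pytest.raises(ValueError):
            TrapArray(trap_id=[1, 2], x=[0, 1], y=[0, 1],
                      effort=-np.ones((2, 2), int))
        with pytest.raises(ValueError):   # a period with zero total effort
            TrapArray(trap_id=[1, 2], x=[0, 1], y=[0, 1],
                      effort=np.array([[1, 0], [1, 0]]))

    def test_encounter_data_invariants(self):
        y = np.zeros((2, 1, 2), dtype=int)
        y[0, 0, 0] = 1
        with pytest.raises(ValueError):   # second individual never detected
            EncounterData(y=y, M=5)
        y[1, 0, 1] = 7
        traps = TrapArray(trap_id=[1], x=[0.0], y=[0.0],
                          effort=np.full((1, 2), 5))
        data = EncounterData(y=y, M=5)
        with pytest.raises(ValueError):   # y > K
            data.validate_against(traps)

    def test_latent_state_rejects_revival(self):
        z = np.array([[1, 0, 1]])
        with pytest.raises(ValueError):
            LatentState(z=z, s=np.zeros((1, 3, 2)))

    def test_latent_state_alpha_definition(self):
        z = np.array([[0, 1, 1], [0, 0, 0], [1, 1, 0]])
        ls = LatentState(z=z, s=np.zeros((3, 3, 2)))
        assert ls.alpha.tolist() == [[1, 1, 0], [1, 1, 1], [1, 0, 0]]
        assert ls.first_entry.tolist() == [1, -1, 0]

    def test_parameters_validation(self):
        with pytest.raises(ValueError):
            Parameters(phi=1.2, gamma=[0.1], lambda0=0.5, sigma_p=0.5)
        with pytest.raises(ValueError):
            Parameters(phi=0.75, gamma=[0.1], lambda0=0.5, sigma_p=0.5,
                       movement_model=MovementModel.MARKOVIAN, sigma_s=None)
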