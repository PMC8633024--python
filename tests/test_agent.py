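import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from reciprosim.agent import (
    SUSCEPTIBLE_MIXTURE,
    UNSUSCEPTIBLE_MIXTURE,
    AgentParams,
    agent_estimate,
    agent_final_decision,
    sample_influence,
    transition_schedule,
)
from reciprosim.design import Condition

N_DRAWS = 100_000


@pytest.fixture(scope="module")
def params():
    return AgentParams()


def mixture_mean(mixture):
    # Independent analytic oracle: sum of p * interval midpoint.
    return sum(p * (lo + hi) / 2 for p, (lo, hi) in mixture)


class TestAgentEstimate:
    def test_sd_matches_spec(self, params):
        rng = np.random.default_rng(0)
        draws = np.array(
            [agent_estimate(12.0, 40.0, params, rng).value for _ in range(N_DRAWS)]
        )
        # Monte-Carlo SE of a sample SD is ~ sd / sqrt(2N).
        se = 1.52 / np.sqrt(2 * N_DRAWS)
        assert draws.std(ddof=1) == pytest.approx(1.52, abs=3 * se)

    def test_mean_centred_on_truth(self, params):
        rng = np.random.default_rng(1)
        draws = np.array(
            [agent_estimate(12.0, 40.0, params, rng).value for _ in range(N_DRAWS)]
        )
        se = 1.52 / np.sqrt(N_DRAWS)
        assert draws.mean() == pytest.approx(12.0, abs=4 * se)

    def test_resampling_halves_band_mass(self, params):
        # Closed-form oracle: draws land within 0.5 cm of the participant
        # with the unconstrained Gaussian band mass m; half of those are
        # redrawn outside, so the returned fraction is m / 2.
        m = sps.norm.cdf(0.5, 0, 1.52) - sps.norm.cdf(-0.5, 0, 1.52)
        expected = m / 2
        rng = np.random.default_rng(2)
        draws = np.array(
            [agent_estimate(12.0, 12.0, params, rng).value for _ in range(N_DRAWS)]
        )
        frac = np.mean(np.abs(draws - 12.0) < 0.5)
        se = np.sqrt(expected * (1 - expected) / N_DRAWS)
        assert frac == pytest.approx(expected, abs=4 * se)

    def test_resampled_flag(self, params):
        rng = np.random.default_rng(3)
        results = [agent_estimate(12.0, 12.0, params, rng) for _ in range(5000)]
        resampled = [r for r in results if r.resampled]
        assert resampled
        assert all(abs(r.value - 12.0) >= 0.5 for r in resampled)

    def test_invalid_stimulus(self, params):
        with pytest.raises(ValueError):
            agent_estimate(-1.0, 10.0, params, np.random.default_rng(0))


class TestSampleInfluence:
    @pytest.mark.parametrize(
        "condition, mixture",
        [
            (Condition.SUSCEPTIBLE, SUSCEPTIBLE_MIXTURE),
            (Condition.UNSUSCEPTIBLE, UNSUSCEPTIBLE_MIXTURE),
        ],
    )
    def test_interval_frequencies_chi2(self, params, condition, mixture):
        rng = np.random.default_rng(10)
        draws = [sample_influence(condition, params, rng) for _ in range(N_DRAWS)]
        counts = np.bincount([d.interval_index for d in draws], minlength=len(mixture))
        expected = np.array([p for p, _ in mixture]) * N_DRAWS
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < sps.chi2.isf(0.01, df=len(mixture) - 1)

    def test_susceptible_top_band_mass(self, params):
        rng = np.random.default_rng(11)
        draws = np.array(
            [sample_influence(Condition.SUSCEPTIBLE, params, rng).i for _ in range(N_DRAWS)]
        )
        se = np.sqrt(0.45 * 0.55 / N_DRAWS)
        assert np.mean(draws >= 0.75) == pytest.approx(0.45, abs=3 * se)

    def test_unsusceptible_bottom_band_mass(self, params):
        rng = np.random.default_rng(12)
        draws = np.array(
            [sample_influence(Condition.UNSUSCEPTIBLE, params, rng).i for _ in range(N_DRAWS)]
        )
        se = np.sqrt(0.8 * 0.2 / N_DRAWS)
        assert np.mean(draws < 0.25) == pytest.approx(0.80, abs=3 * se)

    @pytest.mark.parametrize(
        "condition, mixture",
        [
            (Condition.SUSCEPTIBLE, SUSCEPTIBLE_MIXTURE),
            (Condition.UNSUSCEPTIBLE, UNSUSCEPTIBLE_MIXTURE),
        ],
    )
    def test_mean_matches_analytic(self, params, condition, mixture):
        rng = np.random.default_rng(13)
        draws = np.array(
            [sample_influence(condition, params, rng).i for _ in range(N_DRAWS)]
        )
        assert draws.mean() == pytest.approx(mixture_mean(mixture), abs=0.005)

    def test_analytic_means_frozen(self):
        assert mixture_mean(SUSCEPTIBLE_MIXTURE) == pytest.approx(0.675)
        assert mixture_mean(UNSUSCEPTIBLE_MIXTURE) == pytest.approx(0.1875)

    def test_interval_means_are_midpoints(self, params):
        rng = np.random.default_rng(14)
        draws = [sample_influence(Condition.SUSCEPTIBLE, params, rng) for _ in range(N_DRAWS)]
        for idx, (p, (lo, hi)) in enumerate(SUSCEPTIBLE_MIXTURE):
            vals = np.array([d.i for d in draws if d.interval_index == idx])
            se = (hi - lo) / np.sqrt(12 * len(vals))
            assert vals.mean() == pytest.approx((lo + hi) / 2, abs=4 * se)

    def test_final_inherits_last_condition(self, params):
        rng = np.random.default_rng(15)
        draws = np.array(
            [
                sample_influence(
                    Condition.FINAL, params, rng, last_condition=Condition.UNSUSCEPTIBLE
                ).i
                for _ in range(20_000)
            ]
        )
        assert np.mean(draws < 0.25) == pytest.approx(0.80, abs=0.02)

    def test_final_without_last_condition_raises(self, params):
        with pytest.raises(ValueError, match="last_condition"):
            sample_influence(Condition.FINAL, params, np.random.default_rng(0))

    @pytest.mark.parametrize("bad", [Condition.BASELINE, Condition.TRANSITION])
    def test_invalid_conditions_raise(self, params, bad):
        with pytest.raises(ValueError):
            sample_influence(bad, params, np.random.default_rng(0))


class TestTransitionSchedule:
    def test_s_to_u_counts_and_order(self):
        sched = transition_schedule("S_TO_U")
        assert len(sched) == 11
        assert sched == (
            [(0.75, 1.0)] * 2 + [(0.5, 0.75)] * 2 + [(0.25, 0.5)] * 3 + [(0.0, 0.25)] * 4
        )

    def test_u_to_s_is_reverse(self):
        assert transition_schedule("U_TO_S") == transition_schedule("S_TO_U")[::-1]
        assert transition_schedule("U_TO_S")[:4] == [(0.0, 0.25)] * 4

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            transition_schedule("sideways")


class TestAgentFinalDecision:
    def test_zero_keeps_own(self):
        assert agent_final_decision(10.0, 14.0, 0.0) == 10.0

    def test_one_adopts_partner(self):
        assert agent_final_decision(10.0, 14.0, 1.0) == 14.0

    def test_quarter(self):
        assert agent_final_decision(10.0, 12.0, 0.25) == pytest.approx(10.5)

    @given(
        a=st.floats(1.0, 40.0),
        b=st.floats(1.0, 40.0),
        i=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_decision_on_segment(self, a, b, i):
        f = agent_final_decision(a, b, i)
        assert min(a, b) - 1e-9 <= f <= max(a, b) + 1e-9

    @pytest.mark.parametrize("i", [-0.1, 1.1])
    def test_out_of_range_influence(self, i):
        with pytest.raises(ValueError):
            agent_final_decision(10.0, 12.0, i)


def test_agent_params_validation():
    with pytest.raises(ValueError):
        AgentParams(estimate_sd=-1.0)
    with pytest.raises(ValueError, match="sum"):
        AgentParams(mixtures={Condition.SUSCEPTIBLE: ((0.5, (0.0, 0.5)),)})
    with pytest.raises(ValueError, match="overlap"):
        AgentParams(
            mixtures={
                Condition.SUSCEPTIBLE: ((0.5, (0.0, 0.5)), (0.5, (0.4, 0.9))),
            }
        )
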