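"""Decision-tree model: exact enumeration, limits, noise marginal, simulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from searchgain import generative_model as gm
from searchgain.task_core import ParticipantProfile


def brute_force_first_target_fixation(n_elements: int, n_targets: int) -> float:
    """Expected index of the first target under a uniform inspection order.

    Enumerates all placements of the targets among the element
    positions; by exchangeability this equals the mean over all
    orderings.
    """
    firsts = [
        min(c) + 1
        for c in itertools.combinations(range(n_elements), n_targets)
    ]
    return float(np.mean(firsts))


class TestBiasTransform:
    def test_zero_gain_gives_neutral_bias(self):
        b = gm.bias_from_noisy_gain(0.0, 0.5)
        assert b.b == pytest.approx(0.5)
        assert b.w == pytest.approx(1.0)

    def test_large_gain_saturates(self):
        assert gm.bias_from_noisy_gain(1e6, 0.5).b == pytest.approx(1.0)
        assert np.isinf(gm.bias_from_noisy_gain(1e9, 1e-9).w)

    def test_one_sd_gain(self):
        b = gm.bias_from_noisy_gain(0.5, 0.5)
        assert b.b == pytest.approx(0.8413, abs=1e-4)
        assert b.w == pytest.approx(b.b / (1 - b.b))
        assert b.w == pytest.approx(5.30, abs=0.02)

    def test_zero_noise_is_a_step(self):
        assert gm.bias_from_noisy_gain(0.3, 0.0).b == 1.0
        assert gm.bias_from_noisy_gain(-0.3, 0.0).b == 0.0
        assert gm.bias_from_noisy_gain(0.0, 0.0).b == 0.5


class TestEnumerateTree:
    @pytest.mark.parametrize("e,d", [(1, 9), (3, 7), (5, 5), (8, 2)])
    def test_neutral_weight_is_a_coin_flip(self, e, d):
        assert gm.enumerate_tree(e, d, 1.0).p_choose_easy == pytest.approx(0.5)

    def test_infinite_weight_singleton_easy_set(self):
        t = gm.enumerate_tree(1, 9, np.inf)
        assert t.p_choose_easy == 1.0
        assert t.expected_fixations == 1.0

    def test_expected_fixations_matches_two_target_enumeration(self):
        # first of 2 targets among 10 uniformly ordered elements
        oracle = brute_force_first_target_fixation(10, 2)
        assert oracle == pytest.approx(11 / 3)
        for e in (2, 5, 9):
            t = gm.enumerate_tree(e, 10 - e, 1.0)
            assert t.expected_fixations == pytest.approx(oracle, abs=1e-12)

    @given(
        e=st.integers(1, 9),
        d=st.integers(1, 9),
        w=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_conservation_symmetry_and_bounds(self, e, d, w):
        t = gm.enumerate_tree(e, d, w)
        acc = gm._tree_expectations(e, d, np.array([w]))
        assert acc["p_total"][0] == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= t.p_choose_easy <= 1.0
        assert 1.0 <= t.expected_fixations <= 9.0
        assert t.expected_fix_easy + t.expected_fix_difficult == pytest.approx(
            t.expected_fixations, abs=1e-10
        )
        mirror = gm.enumerate_tree(d, e, 1.0 / w)
        assert t.p_choose_easy == pytest.approx(1 - mirror.p_choose_easy, abs=1e-10)

    def test_monotone_in_weight(self):
        for e, d in [(2, 8), (5, 5), (7, 3)]:
            ps = [gm.enumerate_tree(e, d, w).p_choose_easy
                  for w in (0.0, 0.3, 1.0, 3.0, 10.0, np.inf)]
            assert np.all(np.diff(ps) >= -1e-12)

    def test_no_path_exceeds_nine_fixations(self):
        # the DP grid bounds the depth at 8 distractor removals + target
        t = gm.enumerate_tree(9, 1, 1.0)
        assert t.expected_fixations <= 9.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gm.enumerate_tree(0, 5, 1.0)
        with pytest.raises(ValueError):
            gm.enumerate_tree(5, 5, -0.5)


class TestMarginalPredictions:
    def test_noiseless_argmax_limit(self, profile):
        # positive gain difference, vanishing noise: always choose easy
        p = gm.marginal_predictions((2, 8), profile, sigma_d=0.0, sigma_f=1e-9)
        assert p.p_choose_easy == pytest.approx(1.0, abs=1e-9)
        assert p.p_fix_chosen == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_condition_stays_balanced(self, profile):
        for sd, sf in [(0.1, 0.3), (1.0, 0.5), (0.0, 2.0)]:
            p = gm.marginal_predictions((5, 5), profile, sigma_d=sd, sigma_f=sf,
                                        delta_g=0.0)
            assert p.p_choose_easy == pytest.approx(0.5, abs=1e-9)

    def test_zero_decision_noise_is_single_tree_evaluation(self, profile):
        p = gm.marginal_predictions((6, 4), profile, sigma_d=0.0, sigma_f=0.4)
        dg = gm.delta_g_vector(profile)[5]
        w = gm.bias_from_noisy_gain(float(dg), 0.4).w
        t = gm.enumerate_tree(6, 4, w)
        assert p.p_choose_easy == pytest.approx(t.p_choose_easy, abs=1e-12)
        assert p.p_fix_chosen == pytest.approx(t.p_fix_chosen, abs=1e-12)

    def test_quadrature_matches_monte_carlo(self, profile, rng):
        n = 40_000
        cond, sd, sf = (6, 4), 0.3, 0.6
        pred = gm.marginal_predictions(cond, profile, sd, sf)
        draws = [gm.simulate_trial(cond, profile, sd, sf, rng) for _ in range(n)]
        p_hat = np.mean([t.chosen_target == "easy" for t in draws])
        se = np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(p_hat - pred.p_choose_easy) < 3 * se
        fix_ratio = np.array([t.fixations_on_chosen / t.n_fixations for t in draws])
        se_fix = fix_ratio.std(ddof=1) / np.sqrt(n)
        assert abs(fix_ratio.mean() - pred.p_fix_chosen) < 3 * se_fix


class TestSimulateTrial:
    def test_forced_easy_singleton(self, profile, rng):
        t = gm.simulate_trial((1, 9), profile, sigma_d=0.0, sigma_f=1e-12,
                              rng=rng, delta_g=10.0)
        assert t.sequence == (("easy", "target"),)
        assert t.chosen_target == "easy"

    def test_sequence_terminates_at_first_target(self, profile, rng):
        for _ in range(200):
            t = gm.simulate_trial((4, 6), profile, rng=rng)
            roles = [r for _, r in t.sequence]
            assert roles[-1] == "target"
            assert "target" not in roles[:-1]
            assert t.n_fixations <= 9
            # removed distractors are never revisited: per-set fixation
            # counts never exceed the set sizes
            assert t.fixations_on_easy <= 4
            assert t.n_fixations - t.fixations_on_easy <= 6

    def test_reproducible_under_seed(self, profile):
        a = gm.simulate_trial((5, 5), profile, rng=np.random.default_rng(3))
        b = gm.simulate_trial((5, 5), profile, rng=np.random.default_rng(3))
        assert a == b


def test_position_blindness_of_predictions(profile):
    """Predictions depend only on (ne, nd, w); there is no position input."""
    p1 = gm.marginal_predictions((3, 7), profile)
    p2 = gm.marginal_predictions((3, 7), profile)
    assert p1 == p2


def test_prediction_frame_schema(profile):
    df = gm.prediction_frame(profile)
    assert list(df["condition_ne"]) == list(range(1, 10))
    assert set(df.columns) >= {"p_choose_easy", "p_fix_chosen", "expected_gain"}
    assert df["p_choose_easy"].between(0, 1).all()
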