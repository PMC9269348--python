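"""The time-cumulative fatigue model: levels, thresholds, decisions."""

import itertools

import numpy as np
import pytest

from fatiguekit.accumulation import (
    SegmentDecisions,
    candidate_thresholds,
    cumulative_levels,
    decide_window,
    fatigue_accumulation,
    logistic,
    overall_accuracy,
    run_segmented_detection,
    select_threshold,
)

SIG1 = 1.0 / (1.0 + np.exp(-1.0))


def brute_force_af(x):
    """Direct term-by-term evaluation of the accumulation sum."""
    n = len(x)
    return sum(
        xi * logistic(xi) - (1 - xi) * logistic(xi) for xi in x
    ) / n


class TestLogistic:
    def test_zero_and_one(self):
        assert logistic(0.0) == 0.5
        assert logistic(1.0) == pytest.approx(0.731, abs=5e-4)

    def test_symmetry_identity(self):
        for x in (-3.0, -0.5, 0.2, 4.0):
            assert logistic(x) + logistic(-x) == pytest.approx(1.0)

    def test_monotone_vectorized(self):
        xs = np.linspace(-5, 5, 50)
        assert np.all(np.diff(logistic(xs)) > 0)


class TestSegmentDecisions:
    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            SegmentDecisions((0, 2, 1))

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError):
            SegmentDecisions((1,))

    def test_k_counts_fatigue_segments(self):
        assert SegmentDecisions((1, 0, 1, 1)).k == 3


class TestFatigueAccumulation:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ((0, 0, 0), -0.5),
            ((1, 0, 0), -0.089),
            ((1, 1, 0), 0.321),
            ((1, 1, 1), 0.731),
        ],
    )
    def test_printed_three_segment_values(self, x, expected):
        assert fatigue_accumulation(SegmentDecisions(x)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_matches_brute_force_for_all_vectors_up_to_n10(self):
        """Exhaustive cross-check of the closed form against direct
        term-by-term evaluation over every 0/1 vector, n <= 10."""
        for n in range(2, 11):
            for x in itertools.product((0, 1), repeat=n):
                seg = SegmentDecisions(x)
                assert fatigue_accumulation(seg) == pytest.approx(
                    brute_force_af(x), abs=1e-12
                )

    def test_permutation_invariant_and_monotone_in_k(self):
        vals = {}
        for x in itertools.permutations((1, 1, 0, 0, 0)):
            vals[x] = fatigue_accumulation(SegmentDecisions(x))
        assert len(set(vals.values())) == 1
        by_k = [
            fatigue_accumulation(SegmentDecisions((1,) * k + (0,) * (5 - k)))
            for k in range(6)
        ]
        assert np.all(np.diff(by_k) > 0)
        assert by_k[0] == -0.5 and by_k[-1] == pytest.approx(SIG1)


class TestCumulativeLevels:
    def test_three_segment_levels(self):
        assert np.allclose(
            cumulative_levels(3), [-0.5, -0.089, 0.321, 0.731], atol=1e-3
        )

    def test_two_segment_levels(self):
        # direct evaluation: (-0.5, (sig(1)-0.5)/2, sig(1))
        assert np.allclose(
            cumulative_levels(2), [-0.5, (SIG1 - 0.5) / 2, SIG1], atol=1e-12
        )

    def test_arithmetic_progression_any_n(self):
        for n in (2, 4, 7, 10):
            levels = cumulative_levels(n)
            gaps = np.diff(levels)
            assert np.allclose(gaps, (SIG1 + 0.5) / n)
            assert levels[0] == -0.5 and levels[-1] == pytest.approx(SIG1)

    def test_levels_equal_accumulation_values(self):
        """Levels enumerate exactly the attainable a_F values per k."""
        for n in range(2, 11):
            levels = cumulative_levels(n)
            for k in range(n + 1):
                x = (1,) * k + (0,) * (n - k)
                assert fatigue_accumulation(SegmentDecisions(x)) == pytest.approx(
                    levels[k], abs=1e-12
                )

    def test_n_leq_1_rejected(self):
        with pytest.raises(ValueError):
            cumulative_levels(1)


class TestCandidateThresholds:
    def test_three_segment_candidates(self):
        assert np.allclose(
            candidate_thresholds(3), [-0.295, 0.116, 0.526], atol=1e-3
        )

    def test_two_segment_candidates(self):
        levels = cumulative_levels(2)
        expected = [(levels[0] + levels[1]) / 2, (levels[1] + levels[2]) / 2]
        assert np.allclose(candidate_thresholds(2), expected)
        assert np.allclose(candidate_thresholds(2), [-0.192, 0.423], atol=1e-3)

    def test_candidates_interleave_levels(self):
        for n in (2, 3, 5, 10):
            levels = cumulative_levels(n)
            thetas = candidate_thresholds(n)
            assert len(thetas) == n
            assert np.all(levels[:-1] < thetas) and np.all(thetas < levels[1:])


class TestDecideWindow:
    def test_single_noisy_segment_filtered(self):
        res = decide_window(SegmentDecisions((1, 0, 0)), 0.116)
        assert res.a_f == pytest.approx(-0.089, abs=1e-3)
        assert not res.fatigue and res.state == "awake"

    def test_two_fatigue_segments_flagged(self):
        res = decide_window(SegmentDecisions((1, 1, 0)), 0.116)
        assert res.a_f == pytest.approx(0.321, abs=1e-3)
        assert res.fatigue

    def test_all_awake_below_any_threshold(self):
        res = decide_window(SegmentDecisions((0, 0, 0)), -0.295)
        assert not res.fatigue

    def test_counting_rule_equivalence_exhaustive(self):
        """With theta = j-th candidate, the decision equals the counting
        rule 'fatigue iff k >= j+1' — for every n <= 10 and vector x."""
        for n in range(2, 11):
            thetas = candidate_thresholds(n)
            for j, theta in enumerate(thetas):
                for x in itertools.product((0, 1), repeat=n):
                    seg = SegmentDecisions(x)
                    assert decide_window(seg, theta).fatigue == (seg.k >= j + 1)


class TestSelectThreshold:
    def test_separated_k_distributions_give_perfect_candidate(self):
        windows, labels = [], []
        for k in (0, 1):
            windows += [SegmentDecisions((1,) * k + (0,) * (3 - k))] * 10
            labels += [0] * 10
        for k in (2, 3):
            windows += [SegmentDecisions((1,) * k + (0,) * (3 - k))] * 10
            labels += [1] * 10
        theta, table = select_threshold(windows, labels, 3)
        assert theta == pytest.approx(0.116, abs=1e-3)
        assert table.loc[table["threshold"].round(3) == 0.116, "accuracy"].iloc[0] == 1.0

    def test_tie_break_smallest_candidate(self):
        windows = [SegmentDecisions((1, 1, 1))] * 5 + [SegmentDecisions((0, 0, 0))] * 5
        labels = [1] * 5 + [0] * 5
        theta, table = select_threshold(windows, labels, 3)
        assert np.allclose(table["accuracy"], 1.0)
        assert theta == pytest.approx(candidate_thresholds(3)[0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([SegmentDecisions((0, 0, 0))] * 3, [0, 0, 0], 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([], [], 3)


class TestNoiseFiltering:
    def test_monte_carlo_matches_closed_form(self):
        """Awake windows with i.i.d. segment-flip noise p=0.1: the
        cumulative decision at theta=0.116 (n=3) false-alarms with
        probability 3p^2(1-p) + p^3 = 0.028; a 10,000-window Monte Carlo
        estimate must agree within 3 standard errors."""
        p, n_windows = 0.1, 10_000
        closed_form = 3 * p**2 * (1 - p) + p**3
        rng = np.random.default_rng(12)
        flips = rng.random((n_windows, 3)) < p
        alarms = 0
        for row in flips:
            seg = SegmentDecisions(tuple(int(v) for v in row))
            alarms += decide_window(seg, 0.116).fatigue
        rate = alarms / n_windows
        se = np.sqrt(closed_form * (1 - closed_form) / n_windows)
        assert abs(rate - closed_form) <= 3 * se
        assert closed_form == pytest.approx(0.028, abs=5e-4)


class TestRunSegmentedDetection:
    def test_partition_arithmetic(self, stream_model):
        """60 s at 30 fps with n=3 gives 600-frame segments."""
        from fatiguekit.temporal import FrameSeries

        series = FrameSeries(
            eye_closed=np.zeros(1800, dtype=bool),
            mouth_open=np.zeros(1800, dtype=bool),
            t0=1 / 30,
        )
        decisions = run_segmented_detection(series, 60.0, 3, stream_model)
        assert len(decisions) == 1
        assert decisions[0].segment_states == (0, 0, 0)
        assert not decisions[0].fatigue

    def test_single_segment_rejected(self, stream_model):
        from fatiguekit.temporal import FrameSeries

        series = FrameSeries(
            eye_closed=np.zeros(100, dtype=bool),
            mouth_open=np.zeros(100, dtype=bool),
            t0=1 / 30,
        )
        with pytest.raises(ValueError):
            run_segmented_detection(series, 2.0, 1, stream_model)

    def test_short_segments_warn(self, stream_model):
        from fatiguekit.temporal import FrameSeries

        series = FrameSeries(
            eye_closed=np.zeros(900, dtype=bool),
            mouth_open=np.zeros(900, dtype=bool),
            t0=1 / 30,
        )
        with pytest.warns(UserWarning):
            run_segmented_detection(series, 30.0, 10, stream_model)


class TestOverallAccuracy:
    def test_pooled_counts(self):
        assert overall_accuracy([40, 14], [45, 15]) == pytest.approx(0.90)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy([10], [5])
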