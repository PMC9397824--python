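"""Logistic fitting, PSE scoring rules, and adaptive training-set construction."""

import math

import numpy as np
import pytest

from texdisc.psychometrics import (
    RATIO_MAX,
    RATIO_MIN,
    TrialRecord,
    adapt_training_set,
    check_convergence,
    fit_psychometric,
    probability_correct,
    pse_outcome,
)
from texdisc.stimuli import build_default_stimulus_set


def _rec(f_co, correct, idx=0, f_st=164.0):
    return TrialRecord(
        participant="P", session=2, phase="BL", condition="active",
        trial_idx=idx, f_st=f_st, f_co=f_co, combination="St/St/Co",
        odd_index=2, response_index=2 if correct else 0,
    )


def _logistic_records(alpha, beta, n_per_ratio, side, rng, f_st=164.0):
    """Bernoulli records drawn from the generative logistic at the design ratios."""
    recs = []
    for r in (16 / 164, 32 / 164, 48 / 164, 64 / 164):
        p = 1 / (1 + math.exp(-(alpha + beta * r)))
        f_co = f_st * (1 - r) if side == "more_coarse" else f_st * (1 + r)
        for k in range(n_per_ratio):
            recs.append(_rec(f_co, rng.random() < p, idx=len(recs)))
    return recs


class TestProbabilityCorrect:
    def test_simple_proportion(self):
        recs = [_rec(100.0, c) for c in (1, 1, 1, 0, 0)]
        p_i, score = probability_correct(recs)
        assert p_i[100.0] == 0.6
        assert score == 0.6

    def test_all_correct_score_one(self, default_set, rng):
        recs = [
            _rec(s.spatial_frequency, 1, i)
            for i, s in enumerate(default_set.comparisons)
        ]
        _, score = probability_correct(recs)
        assert score == 1.0

    def test_missing_stimulus_listed(self, default_set):
        recs = [_rec(100.0, 1)]
        with pytest.raises(ValueError, match="116"):
            probability_correct(
                recs, [s.spatial_frequency for s in default_set.comparisons]
            )

    def test_unweighted_mean_over_stimuli(self):
        # 1 trial at one stimulus, 3 at another: mean of p_i, not of trials
        recs = [_rec(100.0, 1)] + [_rec(116.0, 0, i) for i in range(1, 4)]
        _, score = probability_correct(recs)
        assert score == 0.5


class TestCheckConvergence:
    @pytest.mark.parametrize(
        "pse, expected",
        [
            (0.2, True),
            (0.5, False),
            (0.098, True),          # inclusive lower edge (printed precision)
            (RATIO_MIN, True),
            (RATIO_MAX, True),
            (0.05, False),
            (None, False),
            (math.nan, False),
        ],
    )
    def test_interval(self, pse, expected):
        assert check_convergence(pse) is expected


class TestFitPsychometric:
    def test_parameter_recovery(self, rng):
        """ML fit recovers the generating PSE on a large single-sided sample."""
        recs = _logistic_records(-2.0, 10.0, 1000, "more_coarse", rng)
        fit = fit_psychometric(recs, "more_coarse")
        assert fit.converged
        assert fit.pse == pytest.approx(0.2, abs=0.01)

    def test_all_correct_not_converged(self):
        recs = [_rec(100.0, 1, i) for i in range(10)] + [
            _rec(148.0, 1, i) for i in range(10, 20)
        ]
        fit = fit_psychometric(recs, "more_coarse")
        assert not fit.converged
        assert fit.pse is None

    def test_negative_slope_not_converged(self, rng):
        recs = _logistic_records(2.0, -10.0, 200, "less_coarse", rng)
        fit = fit_psychometric(recs, "less_coarse")
        assert not fit.converged

    def test_mixed_sides_rejected_without_side(self, rng):
        recs = [_rec(100.0, 1), _rec(228.0, 0, 1)]
        with pytest.raises(ValueError):
            fit_psychometric(recs)


class TestPseOutcome:
    def test_all_correct_phase_floor(self, default_set):
        recs = [
            _rec(s.spatial_frequency, 1, i)
            for i, s in enumerate(default_set.comparisons * 5)
        ]
        assert pse_outcome(recs) == pytest.approx(RATIO_MIN)
        assert round(pse_outcome(recs), 3) == 0.098

    def test_mean_of_two_converged_sides(self, rng):
        mc = _logistic_records(-0.15 * 20, 20.0, 1000, "more_coarse", rng)
        lc = _logistic_records(-0.25 * 20, 20.0, 1000, "less_coarse", rng)
        out = pse_outcome(mc + lc)
        assert out == pytest.approx((0.15 + 0.25) / 2, abs=0.02)

    def test_one_side_unusable_excludes_phase(self, rng):
        mc = _logistic_records(-0.2 * 20, 20.0, 500, "more_coarse", rng)
        lc = [_rec(228.0, 0, i) for i in range(20)]  # all wrong: separation
        assert pse_outcome(mc + lc) is None

    def test_single_side_allowed_behind_flag(self, rng):
        mc = _logistic_records(-0.2 * 20, 20.0, 1000, "more_coarse", rng)
        lc = [_rec(228.0, 0, i) for i in range(20)]
        out = pse_outcome(mc + lc, require_both_sides=False)
        assert out == pytest.approx(0.2, abs=0.02)

    def test_per_side_floor_rule(self, rng):
        mc = [_rec(100.0, 1, i) for i in range(20)]  # all correct on one side
        lc = _logistic_records(-0.25 * 20, 20.0, 1000, "less_coarse", rng)
        out = pse_outcome(mc + lc, all_correct_rule="side")
        assert out == pytest.approx((RATIO_MIN + 0.25) / 2, abs=0.02)

    def test_empty_records(self):
        assert pse_outcome([]) is None


class TestAdaptTrainingSet:
    def test_fixed_point_at_side_center(self, default_set):
        """A PSE at the centre of a side's ratios recovers the baseline side."""
        center = (RATIO_MIN + RATIO_MAX) / 2  # 40/164
        adapted = adapt_training_set(center, center, default_set, True, True)
        mc = [s.spatial_frequency for s in adapted.more_coarse]
        lc = [s.spatial_frequency for s in adapted.less_coarse]
        assert mc == pytest.approx([100.0, 116.0, 132.0, 148.0], abs=1e-9)
        assert lc == pytest.approx([180.0, 196.0, 212.0, 228.0], abs=1e-9)

    def test_fallback_when_nothing_converged(self, default_set):
        adapted = adapt_training_set(None, None, default_set, False, False)
        assert adapted is default_set

    def test_one_side_adapted_one_kept(self, default_set):
        adapted = adapt_training_set(0.15, None, default_set, True, False)
        assert adapted.less_coarse == default_set.less_coarse
        assert adapted.more_coarse != default_set.more_coarse

    @pytest.mark.parametrize("pse", [RATIO_MIN, 0.15, 0.25, RATIO_MAX])
    def test_ratios_positive_bounded_ordered(self, default_set, pse):
        adapted = adapt_training_set(pse, pse, default_set, True, True)
        f_st = default_set.standard.spatial_frequency
        for side, sign in ((adapted.more_coarse, -1), (adapted.less_coarse, 1)):
            ratios = sorted(
                abs(s.spatial_frequency - f_st) / f_st for s in side
            )
            assert all(0 < r <= RATIO_MAX + 1e-12 for r in ratios)
            assert all(b > a for a, b in zip(ratios, ratios[1:]))
            freqs = [s.spatial_frequency for s in side]
            assert all(b > a for a, b in zip(freqs, freqs[1:]))
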