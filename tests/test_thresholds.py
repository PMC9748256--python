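import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import varcalib as vc
from varcalib import (
    CalibrationCurve,
    CalibrationSettings,
    EvidenceIntervals,
    assign_strength,
    bootstrap_bounds,
    build_intervals,
    build_threshold_sets,
    local_posterior_curve,
    select_threshold,
)


def curve_from_bounds(scores, bound_lr, prior=0.5):
    """Construct a curve whose bounds (both sides) encode the given LR values."""
    scores = np.asarray(scores, float)
    bound_post = np.asarray(
        [vc.posterior_from_lr(v, prior) for v in bound_lr], float
    )
    return CalibrationCurve(
        scores=scores,
        epsilon=np.zeros_like(scores),
        pathogenic_count=np.ones_like(scores),
        benign_count=np.ones_like(scores),
        weight=1.0,
        prior=prior,
        posterior=bound_post,
        lr_plus=np.asarray(bound_lr, float),
        bound_pathogenic=bound_post,
        bound_benign=bound_post,
    )


class TestSelectThreshold:
    def test_everywhere_below_cutoff_is_not_met(self):
        curve = curve_from_bounds([1, 2, 3], [1.1, 1.5, 2.0])
        assert select_threshold(curve, 2.406, "pathogenic") is None

    def test_monotone_bounds(self):
        curve = curve_from_bounds([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert select_threshold(curve, 2.406, "pathogenic") == 3.0

    def test_dip_blocks_earlier_thresholds(self):
        curve = curve_from_bounds([1, 2, 3, 4], [3, 2, 3, 4])
        assert select_threshold(curve, 2.406, "pathogenic") == 3.0

    def test_benign_prefix_condition(self):
        curve = curve_from_bounds([1, 2, 3, 4], [0.1, 0.3, 0.5, 2.0])
        # upper bound must stay <= 1/2.406 = 0.4156 for all s <= tau
        assert select_threshold(curve, 2.406, "benign") == 2.0

    def test_empty_curve_rejected(self):
        curve = curve_from_bounds([], [])
        with pytest.raises(ValueError):
            select_threshold(curve, 2.406, "pathogenic")


class TestBuildThresholdSets:
    def test_separated_classes_meet_every_strength(self):
        rng = np.random.default_rng(21)
        path = rng.uniform(10.0, 12.0, 3000)
        ben = rng.uniform(0.0, 2.0, 3000)
        unl = np.concatenate([path, ben])
        settings_ = CalibrationSettings(
            min_labeled_in_window=50, n_bootstrap=200, weight=1.0, random_seed=3
        )
        curve = local_posterior_curve(path, ben, unl, settings_, prior=0.5)
        curve = bootstrap_bounds(curve, path, ben, settings_)
        tp, tb = build_threshold_sets(curve, vc.strength_cutoff_table(0.5, 1124))
        assert tp.met_strengths == vc.STRENGTHS
        assert tb.met_strengths == vc.STRENGTHS

    def test_uninformative_scores_meet_nothing(self):
        rng = np.random.default_rng(22)
        path = rng.normal(0.0, 1.0, 2000)
        ben = rng.normal(0.0, 1.0, 2000)
        unl = np.concatenate([path, ben])
        settings_ = CalibrationSettings(
            min_labeled_in_window=100, n_bootstrap=200, weight=1.0, random_seed=4
        )
        curve = local_posterior_curve(path, ben, unl, settings_, prior=0.5)
        curve = bootstrap_bounds(curve, path, ben, settings_)
        tp, tb = build_threshold_sets(curve, vc.strength_cutoff_table(0.5, 1124))
        assert tp.met_strengths == ()
        assert tb.met_strengths == ()

    def test_gaussian_supporting_threshold_near_analytic(self, gaussian_curve,
                                                         gaussian_config):
        tp, _ = build_threshold_sets(gaussian_curve, gaussian_config)
        analytic = (math.log(2.4063) + 2.0) / 2.0  # 1.439
        assert tp.thresholds["supporting"] == pytest.approx(analytic, abs=0.15)

    def test_nesting_invariant(self, gaussian_threshold_sets):
        tp, tb = gaussian_threshold_sets
        p = [tp.thresholds[s] for s in vc.STRENGTHS if tp.met(s)]
        assert p == sorted(p)
        b = [tb.thresholds[s] for s in vc.STRENGTHS if tb.met(s)]
        assert b == sorted(b, reverse=True)
        # unmet strengths censor everything stronger
        for ts in (tp, tb):
            met = [ts.met(s) for s in vc.STRENGTHS]
            assert met == sorted(met, reverse=True)

    def test_native_scale_reporting_for_flipped_tool(self, gaussian_curve,
                                                     gaussian_config):
        import pandas as pd

        ss = vc.ScoreSet(
            "t", vc.LOWER_IS_PATHOGENIC, pd.Series([0.1], index=["v"]),
            flipped=True,
        )
        tp, _ = build_threshold_sets(gaussian_curve, gaussian_config, score_set=ss)
        tau = tp.thresholds["supporting"]
        assert tp.native_thresholds["supporting"] == pytest.approx(-tau)

    def test_subsampling_never_claims_more_strength(self, gaussian_model):
        """Less data should not (statistically) unlock stronger evidence."""
        import dataclasses

        cfg = vc.strength_cutoff_table(0.5, 1124)
        settings_ = CalibrationSettings(
            min_labeled_in_window=50, n_bootstrap=100, weight=1.0, random_seed=0
        )
        met_full, met_sub = [], []
        for seed in range(20):
            model = dataclasses.replace(
                gaussian_model, n_pathogenic=1500, n_benign=1500,
                n_unlabeled=3000, seed=100 + seed,
            )
            sim = vc.simulate_scores(model)
            rng = np.random.default_rng(seed)

            def n_met(path, ben):
                unl = np.concatenate([path, ben])
                c = local_posterior_curve(path, ben, unl, settings_, prior=0.5)
                c = bootstrap_bounds(c, path, ben, settings_)
                tp, tb = build_threshold_sets(c, cfg)
                return len(tp.met_strengths) + len(tb.met_strengths)

            path, ben = sim.pathogenic_scores, sim.benign_scores
            met_full.append(n_met(path, ben))
            met_sub.append(
                n_met(rng.choice(path, 400, replace=False),
                      rng.choice(ben, 400, replace=False))
            )
        assert np.mean(met_sub) <= np.mean(met_full) + 0.2


class TestAssignStrength:
    @pytest.fixture()
    def intervals(self):
        return EvidenceIntervals(
            pathogenic={"supporting": 1.0, "moderate": 2.0, "strong": 3.0,
                        "very_strong": 4.0},
            benign={"supporting": -1.0, "moderate": -2.0, "strong": -3.0,
                    "very_strong": -4.0},
        )

    def test_extreme_scores(self, intervals):
        assert assign_strength(-9.0, intervals) == "benign_very_strong"
        assert assign_strength(9.0, intervals) == "pathogenic_very_strong"

    def test_missing_is_indeterminate(self, intervals):
        assert assign_strength(None, intervals) == "indeterminate"
        assert assign_strength(float("nan"), intervals) == "indeterminate"

    def test_boundaries_follow_half_open_convention(self, intervals):
        # pathogenic intervals closed on the left
        assert assign_strength(1.0, intervals) == "pathogenic_supporting"
        assert assign_strength(2.0, intervals) == "pathogenic_moderate"
        # benign intervals closed on the right
        assert assign_strength(-1.0, intervals) == "benign_supporting"
        # open indeterminate middle
        assert assign_strength(0.0, intervals) == "indeterminate"
        assert assign_strength(0.999, intervals) == "indeterminate"

    @settings(derandomize=True, max_examples=200)
    @given(score=st.floats(-10, 10))
    def test_partition_is_total_and_single_valued(self, score):
        intervals = EvidenceIntervals(
            pathogenic={"supporting": 1.0, "moderate": 2.0},
            benign={"supporting": -1.0},
        )
        label = assign_strength(score, intervals)
        expected = [
            lab for lab, lo, hi in intervals.bounds()
            if (lo <= score < hi if lab.startswith("pathogenic")
                else lo < score <= hi if lab.startswith("benign")
                else lo < score < hi)
        ]
        assert len(expected) == 1
        assert label == expected[0]

    def test_vectorized_assignment_matches_scalar(self, intervals):
        scores = np.array([-5.0, -1.0, 0.0, 1.5, 4.2, np.nan])
        many = intervals.assign_many(scores)
        singles = [assign_strength(s, intervals) for s in scores]
        assert list(many) == singles

    def test_unmet_strengths_collapse_intervals(self):
        intervals = EvidenceIntervals(
            pathogenic={"supporting": 1.0}, benign={}
        )
        assert assign_strength(50.0, intervals) == "pathogenic_supporting"
        assert assign_strength(-50.0, intervals) == "indeterminate"

    def test_overlapping_direction_thresholds_rejected(self):
        with pytest.raises(ValueError):
            EvidenceIntervals(
                pathogenic={"supporting": -1.0}, benign={"supporting": 1.0}
            )


class TestIntervalBounds:
    def test_bounds_cover_line_in_order(self, gaussian_intervals):
        bounds = gaussian_intervals.bounds()
        assert bounds[0][1] == -math.inf
        assert bounds[-1][2] == math.inf
        for (_, _, hi), (_, lo, _) in zip(bounds, bounds[1:]):
            assert hi == lo
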