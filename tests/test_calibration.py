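import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import varcalib as vc
from varcalib import (
    CalibrationSettings,
    ScoreSet,
    benign_weight,
    bootstrap_bounds,
    local_posterior_curve,
    normalize_orientation,
    window_halfwidth,
)


def _score_set(values, orientation=vc.HIGHER_IS_PATHOGENIC):
    return ScoreSet(
        tool_name="t",
        orientation=orientation,
        scores=pd.Series(values, index=[f"v{i}" for i in range(len(values))]),
    )


class TestOrientation:
    def test_higher_is_identity(self):
        ss = _score_set([0.1, 0.9])
        assert normalize_orientation(ss) is ss

    def test_lower_is_reversed(self):
        ss = _score_set([0.01, 0.5], orientation=vc.LOWER_IS_PATHOGENIC)
        norm = normalize_orientation(ss)
        assert norm.orientation == vc.HIGHER_IS_PATHOGENIC
        # the more pathogenic native score (0.01) now ranks above 0.5
        assert norm.scores.iloc[0] > norm.scores.iloc[1]

    def test_threshold_round_trips_to_native_scale(self):
        ss = _score_set([0.01, 0.5], orientation=vc.LOWER_IS_PATHOGENIC)
        norm = normalize_orientation(ss)
        assert norm.to_native(norm.scores.iloc[0]) == pytest.approx(0.01)

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValueError):
            ScoreSet("t", "sideways", pd.Series([1.0], index=["v"]))

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError):
            ScoreSet(
                "t",
                vc.HIGHER_IS_PATHOGENIC,
                pd.Series([1.0, 2.0], index=["v", "v"]),
            )


class TestWindowHalfwidth:
    def test_degenerate_requirement_gives_zero(self):
        settings_ = CalibrationSettings(
            min_labeled_in_window=1, min_unlabeled_fraction=0.0
        )
        eps = window_halfwidth(2.0, [0.0, 2.0, 4.0], [0.0, 4.0], settings_)
        assert eps == 0.0

    def test_small_example(self):
        settings_ = CalibrationSettings(
            min_labeled_in_window=3, min_unlabeled_fraction=0.5
        )
        labeled = [0.0, 1.0, 2.0, 3.0, 4.0]
        unlabeled = [0.0, 1.0, 2.0, 3.0, 4.0]
        assert window_halfwidth(2.0, labeled, unlabeled, settings_) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_duplicating_labeled_scores_never_widens(self):
        rng = np.random.default_rng(3)
        labeled = rng.normal(size=40)
        unlabeled = rng.normal(size=60)
        settings_ = CalibrationSettings(
            min_labeled_in_window=5, min_unlabeled_fraction=0.1
        )
        doubled = np.repeat(labeled, 2)
        for s in labeled[:10]:
            e1 = window_halfwidth(s, labeled, unlabeled, settings_)
            e2 = window_halfwidth(s, doubled, unlabeled, settings_)
            assert e2 <= e1 + 1e-12

    def test_unsatisfiable_requirement_names_constraint(self):
        settings_ = CalibrationSettings(
            min_labeled_in_window=50, min_unlabeled_fraction=0.0,
            edge_scaling_rule="none",
        )
        with pytest.raises(ValueError, match="min_labeled_in_window"):
            window_halfwidth(0.5, [0.0, 1.0], [0.0, 1.0], settings_)


class TestBenignWeight:
    def test_prior_proportion_gives_unit_weight(self):
        prior = 0.2
        odds = prior / (1 - prior)
        assert benign_weight(1000, int(round(1000 / odds)), prior) == pytest.approx(
            1.0, rel=1e-3
        )

    def test_archive_like_counts(self):
        assert benign_weight(4000, 7834, 0.0441) == pytest.approx(11.068, abs=5e-3)

    def test_zero_benign_count_rejected(self):
        with pytest.raises(ValueError):
            benign_weight(10, 0, 0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        n_p=st.integers(1, 10_000),
        n_b=st.integers(1, 10_000),
        prior=st.floats(0.01, 0.99),
        scale=st.integers(1, 50),
    )
    def test_prior_matching_window(self, n_p, n_b, prior, scale):
        """A window matching the full data's composition posteriors to the prior."""
        w = benign_weight(n_p * scale, n_b * scale, prior)
        posterior = n_p / (n_p + w * n_b)
        assert posterior == pytest.approx(prior, abs=1e-9)


class TestLocalPosteriorCurve:
    def _settings(self, **kw):
        defaults = dict(
            min_labeled_in_window=4,
            min_unlabeled_fraction=0.0,
            n_bootstrap=50,
            weight=1.0,
            random_seed=0,
        )
        defaults.update(kw)
        return CalibrationSettings(**defaults)

    def test_pure_pathogenic_window_gives_posterior_one(self):
        curve = local_posterior_curve(
            [1.0, 1.1, 1.2, 1.3], [], [1.0], self._settings(), prior=0.5
        )
        assert np.all(curve.posterior == 1.0)
        assert np.all(np.isinf(curve.lr_plus))

    def test_window_spanning_everything_gives_half(self):
        curve = local_posterior_curve(
            [0.8, 0.9], [0.1, 0.2], [0.5],
            self._settings(edge_scaling_rule="none"), prior=0.5,
        )
        assert np.allclose(curve.posterior, 0.5)
        assert np.allclose(curve.lr_plus, 1.0)

    def test_midpoint_of_separated_gaussians_is_half(self):
        rng = np.random.default_rng(0)
        path = rng.normal(4.0, 1.0, 10_000)
        ben = rng.normal(0.0, 1.0, 10_000)
        unl = np.concatenate([path, ben])
        settings_ = CalibrationSettings(weight=1.0, n_bootstrap=10)
        curve = local_posterior_curve(path, ben, unl, settings_, prior=0.5)
        idx = int(np.argmin(np.abs(curve.scores - 2.0)))
        assert curve.posterior[idx] == pytest.approx(0.5, abs=0.05)

    def test_gaussian_lr_recovery_closed_form(self):
        """lr+(s) = exp(2s - 2) for N(2,1) vs N(0,1) classes at w = 1."""
        rng = np.random.default_rng(12)
        n = 20_000
        path = rng.normal(2.0, 1.0, n)
        ben = rng.normal(0.0, 1.0, n)
        unl = np.concatenate([path, ben])
        settings_ = CalibrationSettings(weight=1.0, n_bootstrap=10)
        curve = local_posterior_curve(path, ben, unl, settings_, prior=0.5)
        for s in (0.5, 1.0, 1.5):
            idx = int(np.argmin(np.abs(curve.scores - s)))
            analytic = np.exp(2.0 * curve.scores[idx] - 2.0)
            assert curve.lr_plus[idx] == pytest.approx(analytic, rel=0.20)

    def test_estimates_within_unit_interval(self, gaussian_curve):
        assert np.all(gaussian_curve.posterior >= 0.0)
        assert np.all(gaussian_curve.posterior <= 1.0)
        assert np.all(
            np.isfinite(gaussian_curve.lr_plus)
            | (gaussian_curve.posterior == 1.0)
        )

    def test_requires_enough_labeled(self):
        with pytest.raises(ValueError, match="labeled"):
            local_posterior_curve(
                [1.0], [0.0], [0.5],
                CalibrationSettings(min_labeled_in_window=100), prior=0.5,
            )


class TestBootstrapBounds:
    def test_degenerate_single_score_bound_equals_estimate(self):
        settings_ = CalibrationSettings(
            min_labeled_in_window=1,
            min_unlabeled_fraction=0.0,
            n_bootstrap=50,
            weight=1.0,
            random_seed=1,
        )
        curve = local_posterior_curve([1.0] * 5, [], [1.0], settings_, prior=0.5)
        curve = bootstrap_bounds(curve, [1.0] * 5, [], settings_)
        assert np.all(curve.bound_pathogenic == curve.posterior)
        assert np.all(curve.bound_benign == curve.posterior)

    def test_bounds_bracket_point_estimate(self, gaussian_curve):
        assert np.all(gaussian_curve.bound_pathogenic <= gaussian_curve.posterior)
        assert np.all(gaussian_curve.bound_benign >= gaussian_curve.posterior)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        path = rng.normal(1.0, 1.0, 300)
        ben = rng.normal(0.0, 1.0, 300)
        unl = np.concatenate([path, ben])
        settings_ = CalibrationSettings(
            min_labeled_in_window=30, n_bootstrap=100, weight=1.0, random_seed=9
        )
        curves = []
        for _ in range(2):
            c = local_posterior_curve(path, ben, unl, settings_, prior=0.5)
            curves.append(bootstrap_bounds(c, path, ben, settings_))
        np.testing.assert_array_equal(
            curves[0].bound_pathogenic, curves[1].bound_pathogenic
        )

    def test_bound_tightens_with_sample_size(self):
        settings_ = CalibrationSettings(
            min_labeled_in_window=20, n_bootstrap=150, weight=1.0, random_seed=2
        )
        gaps = []
        for n in (100, 10_000):
            rng = np.random.default_rng(4)
            path = rng.normal(2.0, 1.0, n)
            ben = rng.normal(0.0, 1.0, n)
            unl = np.concatenate([path, ben])
            c = local_posterior_curve(path, ben, unl, settings_, prior=0.5)
            c = bootstrap_bounds(c, path, ben, settings_)
            gaps.append(float(np.mean(c.posterior - c.bound_pathogenic)))
        assert gaps[1] < gaps[0]


class TestCalibratePipeline:
    def test_missing_scores_are_excluded(self):
        rng = np.random.default_rng(5)
        n = 400
        scores = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])
        scores[::10] = np.nan
        keys = [f"v{i}" for i in range(2 * n)]
        ss = ScoreSet("t", vc.HIGHER_IS_PATHOGENIC, pd.Series(scores, index=keys))
        labels = pd.Series(["P"] * n + ["B"] * n, index=keys)
        settings_ = CalibrationSettings(
            min_labeled_in_window=30, n_bootstrap=30, weight=1.0, random_seed=0
        )
        curve = vc.calibrate(ss, labels, rng.normal(1, 1.5, 500), settings_, 0.5)
        assert len(curve) == int(np.isfinite(scores).sum())

    def test_lower_is_pathogenic_tool_calibrates_on_flipped_scale(self):
        rng = np.random.default_rng(6)
        n = 300
        # lower native score = more pathogenic (e.g. a p-value style output)
        path_native = rng.beta(1, 8, n)
        ben_native = rng.beta(8, 1, n)
        keys = [f"v{i}" for i in range(2 * n)]
        ss = ScoreSet(
            "t",
            vc.LOWER_IS_PATHOGENIC,
            pd.Series(np.concatenate([path_native, ben_native]), index=keys),
        )
        labels = pd.Series(["P"] * n + ["B"] * n, index=keys)
        settings_ = CalibrationSettings(
            min_labeled_in_window=40, n_bootstrap=30, weight=1.0, random_seed=0
        )
        curve = vc.calibrate(
            ss, labels, rng.beta(2, 2, 400), settings_, 0.5
        )
        # high normalized scores (very negative native) should be pathogenic
        assert curve.posterior[-1] > 0.9
        assert curve.posterior[0] < 0.1
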