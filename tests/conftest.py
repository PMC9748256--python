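import numpy as np
import pytest

from varcalib import (
    CalibrationSettings,
    DistSpec,
    ScoreModel,
    bootstrap_bounds,
    build_intervals,
    build_threshold_sets,
    local_posterior_curve,
    simulate_scores,
    strength_cutoff_table,
)


@pytest.fixture(scope="session")
def gaussian_model():
    """Equal-variance Gaussian classes with closed-form lr+(s) = exp(2s - 2)."""
    return ScoreModel(
        pathogenic=DistSpec("normal", (2.0, 1.0)),
        benign=DistSpec("normal", (0.0, 1.0)),
        n_pathogenic=8000,
        n_benign=8000,
        n_unlabeled=16000,
        alpha=0.5,
        missing_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def gaussian_sim(gaussian_model):
    return simulate_scores(gaussian_model)


@pytest.fixture(scope="session")
def gaussian_settings():
    return CalibrationSettings(n_bootstrap=300, weight=1.0, random_seed=5)


@pytest.fixture(scope="session")
def gaussian_curve(gaussian_sim, gaussian_settings):
    """Bounded calibration curve on the Gaussian fixture (w=1, prior 1/2)."""
    curve = local_posterior_curve(
        gaussian_sim.pathogenic_scores,
        gaussian_sim.benign_scores,
        gaussian_sim.unlabeled_scores,
        gaussian_settings,
        prior=0.5,
    )
    return bootstrap_bounds(
        curve,
        gaussian_sim.pathogenic_scores,
        gaussian_sim.benign_scores,
        gaussian_settings,
    )


@pytest.fixture(scope="session")
def gaussian_config():
    return strength_cutoff_table(0.5, 1124.0)


@pytest.fixture(scope="session")
def gaussian_threshold_sets(gaussian_curve, gaussian_config):
    return build_threshold_sets(gaussian_curve, gaussian_config)


@pytest.fixture(scope="session")
def gaussian_intervals(gaussian_threshold_sets):
    tp, tb = gaussian_threshold_sets
    return build_intervals(tp, tb)
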