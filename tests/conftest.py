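"""Shared fixtures: small synthetic cohorts and processed trials.

Session scope keeps simulation + filtering + detection costs paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from imugait.events import detect_gait_sequence, detect_trial_events
from imugait.preprocess import filter_trial
from imugait.simulate import GroupParams, SimulationSpec, simulate_trial


def zero_noise_spec(stance: float = 0.62, asymmetry: float = 1.0, seed: int = 3) -> SimulationSpec:
    """Deterministic symmetric-by-construction single-subject spec."""
    return SimulationSpec(
        groups={
            "healthy": GroupParams(
                n_subjects=1,
                stride_time_mean=1.2,
                stride_time_sd=0.0,
                stance_fraction_mean=stance,
                stance_fraction_sd=0.0,
                asymmetry_ratio=asymmetry,
            )
        },
        gyro_noise_sd=0.0,
        accel_noise_sd=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def quiet_trial_truth():
    """One zero-noise symmetric healthy trial with ground truth."""
    return simulate_trial(zero_noise_spec(), 0, "healthy")


@pytest.fixture(scope="session")
def quiet_filtered(quiet_trial_truth):
    trial, truth = quiet_trial_truth
    return filter_trial(trial), truth


@pytest.fixture(scope="session")
def quiet_sequence(quiet_filtered):
    filtered, _ = quiet_filtered
    return detect_gait_sequence(filtered)


@pytest.fixture(scope="session")
def quiet_side_events(quiet_filtered):
    filtered, _ = quiet_filtered
    return detect_trial_events(filtered)


@pytest.fixture(scope="session")
def default_trial_processed():
    """A noisy default-parameters stroke trial through filter + detection."""
    spec = SimulationSpec(seed=42)
    trial, truth = simulate_trial(spec, 0, "stroke")
    filtered = filter_trial(trial)
    seq = detect_gait_sequence(filtered)
    return trial, filtered, truth, seq


def small_cohort_spec(seed: int = 5) -> SimulationSpec:
    """Three-group cohort small enough for fast classification tests."""
    groups = {
        "healthy": GroupParams(4, 1.10, 0.03, 0.60, 0.010),
        "stroke": GroupParams(
            4, 1.30, 0.05, 0.62, 0.015,
            asymmetry_ratio=1.10, amplitude_scale=0.6, noise_scale=3.0, stance_shift=0.05,
        ),
        "other_neuro": GroupParams(
            4, 1.20, 0.04, 0.61, 0.012,
            asymmetry_ratio=1.05, amplitude_scale=0.8, noise_scale=2.0,
            stance_shift=0.025, bilateral=True,
        ),
    }
    return SimulationSpec(groups=groups, trials_per_subject=6, seed=seed)


@pytest.fixture(scope="session")
def cohort_pairs():
    """(trial, sequence) pairs of the small three-group cohort."""
    from imugait.events import GaitEventDetector
    from imugait.preprocess import TrialFilter
    from imugait.simulate import simulate_cohort

    trials, truths, labels = simulate_cohort(small_cohort_spec())
    filtered = TrialFilter().fit_transform(trials)
    detector = GaitEventDetector()
    pairs = detector.fit_transform(filtered)
    return pairs, detector.excluded_


@pytest.fixture(scope="session")
def cohort_features_combined(cohort_pairs):
    from imugait.features import build_feature_matrix

    pairs, excluded = cohort_pairs
    return build_feature_matrix(pairs, mode="combined", excluded=excluded)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
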