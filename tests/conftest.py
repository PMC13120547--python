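import dataclasses

import numpy as np
import pytest

from safefall.kinematics import extract_metrics_table
from safefall.pose_io import N_KEYPOINTS, TrackedSequence
from safefall.synthetic_falls import PROFILE_DEFAULTS, CohortSpec, simulate_cohort, simulate_fall


def make_random_sequence(
    rng: np.random.Generator,
    n_frames: int = 40,
    fps: float = 60.0,
    frame_size=(1920, 1080),
    subject_id: str = "R0",
) -> TrackedSequence:
    """A random-walk pose sequence with valid invariants, for property tests."""
    width, height = frame_size
    start = rng.uniform([200, 200], [width - 200, height - 200])
    steps = rng.normal(0, 4, size=(n_frames, N_KEYPOINTS, 2))
    base = start + np.cumsum(steps, axis=0)
    kp = np.empty((n_frames, N_KEYPOINTS, 3))
    kp[:, :, :2] = np.clip(base + rng.normal(0, 30, size=(1, N_KEYPOINTS, 2)), 0, [width, height])
    kp[:, :, 2] = rng.uniform(0.3, 1.0, size=(n_frames, N_KEYPOINTS))
    x_min = kp[:, :, 0].min(axis=1)
    y_min = kp[:, :, 1].min(axis=1)
    bbox = np.stack(
        [
            x_min,
            y_min,
            np.maximum(kp[:, :, 0].max(axis=1) - x_min, 1.0),
            np.maximum(kp[:, :, 1].max(axis=1) - y_min, 1.0),
        ],
        axis=1,
    )
    return TrackedSequence(
        subject_id=subject_id,
        track_id=int(rng.integers(0, 100)),
        fps=fps,
        frame_size=frame_size,
        frame_index=np.arange(n_frames),
        keypoints=kp,
        visibility=rng.random((n_frames, N_KEYPOINTS)) > 0.05,
        bbox=bbox,
        cohort=str(rng.choice(["pre", "post", "unknown"])),
    )


def noiseless_fall(profile: str, seed: int = 3, **overrides) -> TrackedSequence:
    params = dataclasses.replace(
        PROFILE_DEFAULTS[profile],
        keypoint_noise_sd=0.0,
        dropout_rate=0.0,
        seed=seed,
        **overrides,
    )
    return simulate_fall(params)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort at the study sizes, shared across tests."""
    return simulate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def default_metrics(default_cohort):
    return extract_metrics_table(default_cohort)
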