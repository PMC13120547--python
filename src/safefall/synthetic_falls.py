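"""Synthetic backward-fall pose sequences for three motor profiles.

The generator emulates pose-estimator output (17 COCO keypoints per frame at
60 fps, 1920×1080) for the three motor strategies the analysis distinguishes:

``controlled``
    Tuck-and-roll (Ukemi) execution: a short decisive squat lowers the hips,
    the body rolls horizontally across the mat, and the chin is tucked toward
    the chest (small nose-to-sternum distance).
``chaotic``
    High-intensity panic response: a sharp, step-like terminal descent with
    high-frequency limb flailing on wrists, elbows and ankles.
``freezing``
    Passive/stiff response: hesitation, a slow shallow descent, near-zero
    horizontal travel and extended straight arms reaching for the ground
    (FOOSH-like), the hazardous pattern linked to fear of falling.

Each sequence is a deterministic (seeded) closed-form stick-figure template —
torso segment, two 2-segment arms, two 2-segment legs, head offset — with
Gaussian keypoint noise and Bernoulli dropout applied last.  Ground-truth
phase landmarks and the safe/hazardous quality label are stored in sequence
metadata so every downstream stage can be validated against generator truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .pose_io import KP_INDEX, N_KEYPOINTS, TrackedSequence

PROFILES = ("controlled", "chaotic", "freezing")

# --- stick-figure geometry (pixels; roughly child-sized at the study's
#     camera distance) -----------------------------------------------------
TORSO_LEN = 160.0  # mid-hip to mid-shoulder
HEAD_LEN = 55.0  # mid-shoulder to nose
SHOULDER_HW = 45.0
HIP_HW = 32.0


@dataclass(frozen=True)
class ProfileParams:
    """Kinematic template parameters for one motor profile."""

    profile: str
    stance_height: float = 560.0  # hip y at standing (px from frame top)
    squat_duration: float = 0.45  # s, duration of the descent ramp
    descent_depth: float = 380.0  # px, hip drop from stance to ground
    roll_distance_x: float = 350.0  # px, horizontal travel of the roll
    flail_amplitude: float = 0.0  # px, limb flail oscillation
    flail_frequency: float = 0.0  # Hz
    hesitation_delay: float = 0.3  # s before descent onset
    chin_tuck: float = 0.9  # 0..1, 1 = chin fully to chest
    arm_extension: float = 0.1  # 0..1, 1 = straight-arm FOOSH reach
    keypoint_noise_sd: float = 2.0  # px
    dropout_rate: float = 0.02  # per keypoint-frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        for name in (
            "squat_duration",
            "descent_depth",
            "roll_distance_x",
            "flail_amplitude",
            "flail_frequency",
            "hesitation_delay",
            "keypoint_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("chin_tuck", "arm_extension", "dropout_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


#: Default parameter table, one entry per motor profile.  Magnitudes are
#: chosen so the noiseless templates reproduce the qualitative orderings the
#: analysis rests on (descent commitment, movement intensity, neck
#: protection), not any particular absolute value.
PROFILE_DEFAULTS: dict[str, ProfileParams] = {
    "controlled": ProfileParams(
        profile="controlled",
        squat_duration=0.40,
        descent_depth=380.0,
        roll_distance_x=350.0,
        flail_amplitude=0.0,
        flail_frequency=0.0,
        hesitation_delay=0.3,
        chin_tuck=0.9,
        arm_extension=0.1,
    ),
    "chaotic": ProfileParams(
        profile="chaotic",
        squat_duration=0.42,
        descent_depth=300.0,
        roll_distance_x=120.0,
        flail_amplitude=70.0,
        flail_frequency=6.0,
        hesitation_delay=0.15,
        chin_tuck=0.2,
        arm_extension=0.5,
    ),
    "freezing": ProfileParams(
        profile="freezing",
        squat_duration=1.5,
        descent_depth=180.0,
        roll_distance_x=10.0,
        flail_amplitude=0.0,
        flail_frequency=0.0,
        hesitation_delay=1.0,
        chin_tuck=0.05,
        arm_extension=0.9,
    ),
}

#: Default cohort composition.  The pre-intervention cohort is skewed toward
#: chaotic/freezing responses and the post-intervention cohort toward the
#: controlled strategy, mirroring the direction of the intervention effect.
DEFAULT_PRE_MIX = {"chaotic": 0.10, "controlled": 0.55, "freezing": 0.35}
DEFAULT_POST_MIX = {"chaotic": 0.02, "controlled": 0.83, "freezing": 0.15}


@dataclass(frozen=True)
class CohortSpec:
    """Sizes, profile mixes and recording setup for a simulated cohort."""

    n_pre: int = 285
    n_post: int = 130
    pre_mix: dict = field(default_factory=lambda: dict(DEFAULT_PRE_MIX))
    post_mix: dict = field(default_factory=lambda: dict(DEFAULT_POST_MIX))
    fps: float = 60.0
    duration: float = 3.0
    frame_size: tuple[int, int] = (1920, 1080)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre <= 0 or self.n_post <= 0:
            raise ValueError("cohort counts must be > 0")
        for mix in (self.pre_mix, self.post_mix):
            if set(mix) - set(PROFILES):
                raise ValueError(f"unknown profile in mix: {mix}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("profile mix must sum to 1")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """3u² − 2u³ on [0, 1], clamped outside."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _ramp(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    if duration <= 0:
        return (t >= start).astype(float)
    return _smoothstep((t - start) / duration)


def simulate_fall(
    params: ProfileParams,
    fps: float = 60.0,
    duration: float = 3.0,
    frame_size: tuple[int, int] = (1920, 1080),
    start_x: float = 500.0,
    subject_id: str = "S0000",
    track_id: int = 0,
    cohort: str = "unknown",
) -> TrackedSequence:
    """Generate one tracked fall sequence from the stick-figure template.

    Deterministic given ``params.seed``.  Ground-truth phase landmarks
    (descent onset/end, peak-deceleration frame of the noiseless hip
    trajectory) and the quality label (controlled → safe, others →
    hazardous) are stored in ``meta``.
    """
    n = int(round(duration * fps))
    if n < 30:
        raise ValueError("duration * fps must be at least 30 frames")
    width, height = frame_size
    if params.stance_height + params.descent_depth > height - 60:
        raise ValueError(
            "infeasible geometry: descent_depth places the hips outside the frame"
        )
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / fps

    # --- hip (centre-of-mass proxy) trajectory ---------------------------
    u_desc = _ramp(t, params.hesitation_delay, params.squat_duration)
    hip_y = params.stance_height + params.descent_depth * u_desc

    roll_start = params.hesitation_delay + 0.5 * params.squat_duration
    roll_dur = max(0.8, params.squat_duration)
    u_roll = _ramp(t, roll_start, roll_dur)
    hip_x = start_x + params.roll_distance_x * u_roll

    # erratic whole-body sway (chaotic profile): lateral hip oscillation at
    # the flail frequency; x-only so the vertical descent template is intact
    if params.flail_amplitude > 0 and params.flail_frequency > 0:
        gate = np.minimum(3.0 * _ramp(t, params.hesitation_delay,
                                      params.squat_duration + 0.4), 1.0)
        sway_phase = rng.uniform(0, 2 * np.pi)
        hip_x = hip_x + 0.8 * params.flail_amplitude * gate * np.sin(
            2 * np.pi * params.flail_frequency * t + sway_phase
        )

    # --- trunk rotation ---------------------------------------------------
    theta_end = {"controlled": 90.0, "chaotic": 90.0, "freezing": 70.0}[params.profile]
    u_ang = _ramp(t, params.hesitation_delay, params.squat_duration + 0.4)
    theta = np.deg2rad(theta_end * u_ang)
    # lean backward: shoulders move toward -x as the body goes horizontal
    trunk_dir = np.stack([-np.sin(theta), -np.cos(theta)], axis=1)  # unit, y-down

    hip_mid = np.stack([hip_x, hip_y], axis=1)
    sh_mid = hip_mid + TORSO_LEN * trunk_dir

    # --- head: chin tuck pulls the nose toward the sternum ----------------
    tuck = params.chin_tuck * u_ang
    nose = sh_mid + HEAD_LEN * (1.0 - 0.85 * tuck)[:, None] * trunk_dir
    eye_off = np.array([[-12.0, -10.0], [12.0, -10.0]])
    ear_off = np.array([[-22.0, -6.0], [22.0, -6.0]])

    # --- arms: blend hanging → (tucked | extended FOOSH) -------------------
    # relative offsets (x sign mirrored for left/right), y-down pixels
    hang_elbow, hang_wrist = np.array([6.0, 75.0]), np.array([6.0, 65.0])
    tuck_elbow, tuck_wrist = np.array([25.0, 30.0]), np.array([-20.0, -10.0])
    ext_elbow, ext_wrist = np.array([-30.0, 68.0]), np.array([-25.0, 58.0])
    e = params.arm_extension
    fall_elbow = e * ext_elbow + (1 - e) * tuck_elbow
    fall_wrist = e * ext_wrist + (1 - e) * tuck_wrist
    w = u_ang[:, None]
    elbow_rel = (1 - w) * hang_elbow + w * fall_elbow
    wrist_rel = (1 - w) * hang_wrist + w * fall_wrist

    # --- legs: blend standing → folded (fold follows the tuck) ------------
    fold = params.chin_tuck
    stand_knee, stand_ankle = np.array([0.0, 95.0]), np.array([0.0, 90.0])
    fold_knee = fold * np.array([60.0, 30.0]) + (1 - fold) * np.array([20.0, 80.0])
    fold_ankle = fold * np.array([55.0, 10.0]) + (1 - fold) * np.array([15.0, 70.0])
    knee_rel = (1 - w) * stand_knee + w * fold_knee
    ankle_rel = (1 - w) * stand_ankle + w * fold_ankle

    kp = np.zeros((n, N_KEYPOINTS, 3))
    kp[:, :, 2] = 1.0

    def put(name: str, xy: np.ndarray) -> None:
        kp[:, KP_INDEX[name], :2] = xy

    put("nose", nose)
    put("left_eye", nose + eye_off[0])
    put("right_eye", nose + eye_off[1])
    put("left_ear", nose + ear_off[0])
    put("right_ear", nose + ear_off[1])

    side = {"left": -1.0, "right": 1.0}
    for s, sgn in side.items():
        shoulder = sh_mid + np.array([sgn * SHOULDER_HW, 0.0])
        hip = hip_mid + np.array([sgn * HIP_HW, 0.0])
        put(f"{s}_shoulder", shoulder)
        put(f"{s}_hip", hip)
        elb = shoulder + elbow_rel * np.array([sgn, 1.0])
        wri = elb + wrist_rel * np.array([sgn, 1.0])
        put(f"{s}_elbow", elb)
        put(f"{s}_wrist", wri)
        kne = hip + knee_rel * np.array([sgn, 1.0])
        ank = kne + ankle_rel * np.array([sgn, 1.0])
        put(f"{s}_knee", kne)
        put(f"{s}_ankle", ank)

    # --- chaotic flail on distal limb keypoints ---------------------------
    if params.flail_amplitude > 0 and params.flail_frequency > 0:
        gate = np.minimum(3.0 * u_ang, 1.0)
        for name in (
            "left_wrist",
            "right_wrist",
            "left_elbow",
            "right_elbow",
            "left_ankle",
            "right_ankle",
        ):
            phase = rng.uniform(0, 2 * np.pi, size=2)
            osc = params.flail_amplitude * gate
            k = KP_INDEX[name]
            kp[:, k, 0] += osc * np.sin(2 * np.pi * params.flail_frequency * t + phase[0])
            kp[:, k, 1] += 0.6 * osc * np.sin(
                2 * np.pi * params.flail_frequency * t + phase[1]
            )

    # --- ground truth from the noiseless template -------------------------
    meta: dict = {"profile": params.profile}
    vy = np.full(n, np.nan)
    vy[1:] = np.diff(hip_y) * fps
    if np.nanmax(vy) > 1e-9:
        ay = np.full(n, np.nan)
        ay[2:] = np.diff(vy[1:]) * fps
        meta["impact_frame_truth"] = int(np.nanargmax(-ay))
        active = np.flatnonzero(u_desc > 0)
        meta["descent_onset"] = int(active[0])
        done = np.flatnonzero(u_desc >= 1.0)
        meta["descent_end"] = int(done[0]) if done.size else n - 1
    else:
        meta["impact_frame_truth"] = None
        meta["descent_onset"] = None
        meta["descent_end"] = None

    # --- observation noise and dropout (applied last) ---------------------
    if params.keypoint_noise_sd > 0:
        kp[:, :, :2] += rng.normal(0.0, params.keypoint_noise_sd, size=(n, N_KEYPOINTS, 2))
    vis = np.ones((n, N_KEYPOINTS), dtype=bool)
    if params.dropout_rate > 0:
        drop = rng.random((n, N_KEYPOINTS)) < params.dropout_rate
        vis &= ~drop
        kp[drop, 2] = 0.0

    np.clip(kp[:, :, 0], 0.0, width, out=kp[:, :, 0])
    np.clip(kp[:, :, 1], 0.0, height, out=kp[:, :, 1])

    margin = 15.0
    x_min = np.clip(kp[:, :, 0].min(axis=1) - margin, 0, width)
    y_min = np.clip(kp[:, :, 1].min(axis=1) - margin, 0, height)
    x_max = np.clip(kp[:, :, 0].max(axis=1) + margin, 0, width)
    y_max = np.clip(kp[:, :, 1].max(axis=1) + margin, 0, height)
    bbox = np.stack(
        [x_min, y_min, np.maximum(x_max - x_min, 1.0), np.maximum(y_max - y_min, 1.0)],
        axis=1,
    )

    return TrackedSequence(
        subject_id=subject_id,
        track_id=track_id,
        fps=fps,
        frame_size=frame_size,
        frame_index=np.arange(n),
        keypoints=kp,
        visibility=vis,
        bbox=bbox,
        cohort=cohort,
        quality_label="safe" if params.profile == "controlled" else "hazardous",
        meta=meta,
    )


def _jitter(params: ProfileParams, rng: np.random.Generator, scale: float = 1.0) -> ProfileParams:
    """Per-subject anthropometric/behavioural variation around a profile."""

    def ln(sd: float) -> float:
        return float(np.exp(rng.normal(0.0, sd * scale)))

    return dataclasses.replace(
        params,
        stance_height=params.stance_height + float(rng.normal(0, 25 * scale)),
        descent_depth=params.descent_depth * ln(0.12),
        squat_duration=params.squat_duration * ln(0.15),
        roll_distance_x=params.roll_distance_x * ln(0.20),
        hesitation_delay=params.hesitation_delay * ln(0.20),
        flail_amplitude=params.flail_amplitude * ln(0.20),
        chin_tuck=float(np.clip(params.chin_tuck + rng.normal(0, 0.08 * scale), 0, 1)),
        arm_extension=float(
            np.clip(params.arm_extension + rng.normal(0, 0.08 * scale), 0, 1)
        ),
    )


def simulate_cohort(
    spec: CohortSpec,
    param_table: dict[str, ProfileParams] | None = None,
    subject_jitter: float = 1.0,
) -> list[TrackedSequence]:
    """Simulate a pre/post cohort of fall sequences.

    Profiles are drawn from the cohort-specific mixes; each subject gets a
    unique id, a derived RNG seed (stable under generation order) and mild
    anthropometric jitter around the profile template.
    """
    if param_table is None:
        param_table = PROFILE_DEFAULTS
    rng = np.random.default_rng(spec.seed)
    profiles = list(PROFILES)
    seqs: list[TrackedSequence] = []
    total = spec.n_pre + spec.n_post
    for i in range(total):
        cohort = "pre" if i < spec.n_pre else "post"
        mix = spec.pre_mix if cohort == "pre" else spec.post_mix
        p = np.array([mix.get(name, 0.0) for name in profiles])
        profile = profiles[int(rng.choice(len(profiles), p=p))]
        subject_seed = int((spec.seed * 1000003 + 7919 * i + 1) % (2**31 - 1))
        sub_rng = np.random.default_rng(subject_seed)
        params = dataclasses.replace(param_table[profile], seed=subject_seed)
        if subject_jitter > 0:
            params = _jitter(params, sub_rng, subject_jitter)
            # keep jittered geometry inside the frame
            max_drop = spec.frame_size[1] - 60.0 - params.stance_height
            if params.descent_depth > max_drop:
                params = dataclasses.replace(params, descent_depth=max_drop)
        seqs.append(
            simulate_fall(
                params,
                fps=spec.fps,
                duration=spec.duration,
                frame_size=spec.frame_size,
                subject_id=f"S{i:04d}",
                track_id=i,
                cohort=cohort,
            )
        )
    return seqs
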