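"""Synthetic Kinect-style gait simulator with three balance-impairment levels.

The simulator stands in for motion capture of ten adults walking a 4 m
walkway ten times at each of three standardized balance levels (0 = free
walking, 1 = limb weights and restricted knee/elbow flexibility, 2 = level 1
plus hunched posture and restricted vision).  It produces 32-joint skeleton
sequences whose class signal lives where impairment shows up in real gait:

* walking speed and cadence drop with impairment (x-axis progression),
* foot clearance drops (z of ankles/feet during swing),
* trunk flexion rises sharply at level 2 (hunchback),
* lateral sway rises mildly with impairment,
* arm swing varies far more between subjects than between levels, so arm
  joints act mostly as subject-specific distractors.

Each subject has fixed anthropometry and idiosyncratic gait offsets shared
across all levels and trials, which is what makes leave-one-subject-out
evaluation a genuine generalization test.  The walk itself is a deterministic
forward-kinematic model (rigid segments, phase-locked sinusoidal joint
angles) plus independent Gaussian sensor noise on every coordinate.

Axis convention: x = walking direction, y = left-right, z = up-down (meters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import Dataset, SkeletonSequence, FULL32
from .skeleton import Joint, N_JOINTS_FULL

FRAME_COUNT_RANGE = (22, 38)

#: Per-level means for the gait parameters, indexed by balance level 0/1/2,
#: plus the trial-to-trial standard deviation of each parameter.
DEFAULT_LEVEL_PARAMS: dict[str, tuple[tuple[float, float, float], float]] = {
    "speed": ((1.30, 1.05, 0.85), 0.05),          # m/s
    "cadence": ((1.8, 1.6, 1.4), 0.06),           # leg-swing frequency, Hz
    "clearance": ((0.050, 0.030, 0.020), 0.004),  # swing-foot lift, m
    "trunk_flexion_deg": ((5.0, 8.0, 25.0), 2.0),  # forward trunk pitch
    "sway": ((0.020, 0.030, 0.040), 0.005),       # lateral pelvis sway, m
    "arm_swing": ((0.12, 0.10, 0.08), 0.01),      # hand excursion, m
    "bounce": ((0.020, 0.020, 0.020), 0.003),     # vertical pelvis bounce, m
}

#: Between-subject standard deviations of the idiosyncratic offsets.  Arm
#: swing is deliberately 2x its per-level step (0.02 m) so that arm joints
#: carry more identity than impairment signal.
SUBJECT_OFFSET_SD = {
    "speed": 0.06,
    "cadence": 0.06,
    "arm_swing": 0.04,
    "sway": 0.004,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a full dataset generation run."""

    n_subjects: int = 10
    n_trials: int = 10
    walkway_length: float = 4.0
    frame_rate: float = 8.0
    noise_sigma: float = 0.008
    seed: int = 0
    level_params: dict = field(default_factory=lambda: dict(DEFAULT_LEVEL_PARAMS))

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(
                "n_subjects must be >= 2 (leave-one-subject-out evaluation "
                "needs at least two subjects)"
            )
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.walkway_length <= 0 or self.frame_rate <= 0:
            raise ValueError("walkway_length and frame_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class SubjectProfile:
    """Fixed anthropometry and gait idiosyncrasies of one subject."""

    subject_id: int
    pelvis_height: float
    thigh_length: float
    shank_length: float
    hip_half_width: float
    shoulder_half_width: float
    upper_arm_length: float
    forearm_length: float
    speed_offset: float
    cadence_offset: float
    arm_swing_offset: float
    sway_offset: float


@dataclass(frozen=True)
class GaitParams:
    """Trial-level gait parameters after applying a balance level."""

    speed: float                 # v, m/s
    cadence: float               # f, leg-swing frequency, Hz
    step_length: float           # v / f, m
    clearance: float             # c, swing-foot lift, m
    trunk_flexion_deg: float     # forward trunk pitch, degrees
    sway: float                  # lateral pelvis sway amplitude, m
    arm_swing: float             # hand excursion amplitude, m
    bounce: float                # vertical pelvis bounce amplitude, m

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.cadence <= 0 or self.clearance <= 0:
            raise ValueError("speed, cadence and clearance must be positive")
        if not 0.0 <= self.trunk_flexion_deg <= 60.0:
            raise ValueError("trunk_flexion_deg must be within [0, 60]")


def _rng(config_seed: int, *key: int) -> np.random.Generator:
    # Counter-based stream splitting: every (subject, level, trial) cell gets
    # an independent stream, so generation order cannot affect the data.
    return np.random.default_rng([config_seed, *key])


def sample_subject_profile(
    config: SimulationConfig, subject_id: int,
    rng: np.random.Generator | None = None,
) -> SubjectProfile:
    """Draw a subject's anthropometry and idiosyncratic gait offsets.

    Reproducible: the stream is derived from ``(config.seed, subject_id)``,
    so the same pair always yields the same profile.
    """
    if rng is None:
        rng = _rng(config.seed, subject_id)
    return SubjectProfile(
        subject_id=subject_id,
        pelvis_height=max(0.75, rng.normal(0.95, 0.04)),
        thigh_length=max(0.30, rng.normal(0.42, 0.02)),
        shank_length=max(0.30, rng.normal(0.40, 0.02)),
        hip_half_width=max(0.06, rng.normal(0.09, 0.008)),
        shoulder_half_width=max(0.13, rng.normal(0.19, 0.012)),
        upper_arm_length=max(0.22, rng.normal(0.30, 0.015)),
        forearm_length=max(0.18, rng.normal(0.26, 0.015)),
        speed_offset=rng.normal(0.0, SUBJECT_OFFSET_SD["speed"]),
        cadence_offset=rng.normal(0.0, SUBJECT_OFFSET_SD["cadence"]),
        arm_swing_offset=rng.normal(0.0, SUBJECT_OFFSET_SD["arm_swing"]),
        sway_offset=rng.normal(0.0, SUBJECT_OFFSET_SD["sway"]),
    )


def apply_level(
    profile: SubjectProfile, level: int, rng: np.random.Generator,
    level_params: dict | None = None,
) -> GaitParams:
    """Draw trial-level gait parameters for a subject at a balance level."""
    if level not in (0, 1, 2):
        raise ValueError(f"level must be 0, 1 or 2, got {level}")
    lp = level_params if level_params is not None else DEFAULT_LEVEL_PARAMS

    def draw(name: str, lo: float, hi: float = math.inf,
             subject_offset: float = 0.0) -> float:
        means, sd = lp[name]
        return float(np.clip(rng.normal(means[level], sd) + subject_offset, lo, hi))

    speed = draw("speed", 0.30, subject_offset=profile.speed_offset)
    cadence = draw("cadence", 0.50, subject_offset=profile.cadence_offset)
    return GaitParams(
        speed=speed,
        cadence=cadence,
        step_length=speed / cadence,
        clearance=draw("clearance", 0.005),
        trunk_flexion_deg=draw("trunk_flexion_deg", 0.0, 60.0),
        sway=draw("sway", 0.002, subject_offset=profile.sway_offset),
        arm_swing=draw("arm_swing", 0.0, subject_offset=profile.arm_swing_offset),
        bounce=draw("bounce", 0.002),
    )


def _pitch(dx: float, dz: float, theta: float) -> tuple[float, float]:
    # rotate an (x, z) offset forward by theta about the y axis
    return (dx * math.cos(theta) + dz * math.sin(theta),
            -dx * math.sin(theta) + dz * math.cos(theta))


def synthesize_walk(
    profile: SubjectProfile,
    params: GaitParams,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward-kinematic walk: returns a ``(T, 32, 3)`` coordinate array.

    The frame count is ``round(walkway_length / speed * frame_rate)`` clipped
    to the observed envelope of 22-38 frames, so slower (more impaired)
    walks produce more frames.  All skeleton segments are rigid; sensor noise
    is independent zero-mean Gaussian per coordinate.
    """
    v, f = params.speed, params.cadence
    T = int(np.clip(round(config.walkway_length / v * config.frame_rate),
                    FRAME_COUNT_RANGE[0], FRAME_COUNT_RANGE[1]))
    t = np.arange(T) / config.frame_rate
    phase = 2.0 * math.pi * f * t

    theta = math.radians(params.trunk_flexion_deg)
    L_leg = profile.thigh_length + profile.shank_length

    # thigh swing amplitude from step length; knee flexion amplitude from
    # foot clearance: lifting the shank by c requires L_shank*(1-cos b) = c
    alpha_amp = math.asin(min(0.9, params.step_length / (2.0 * L_leg)))
    beta_max = math.acos(np.clip(1.0 - params.clearance / profile.shank_length,
                                 -1.0, 1.0))

    pos = np.zeros((T, N_JOINTS_FULL, 3))

    def put(joint: Joint, x, y, z) -> None:
        pos[:, joint, 0] = x
        pos[:, joint, 1] = y
        pos[:, joint, 2] = z

    # pelvis trajectory: forward progression + sway + bounce
    px = v * t
    py = params.sway * np.sin(phase)
    pz = profile.pelvis_height + params.bounce * np.sin(2.0 * phase)
    put(Joint.PELVIS, px, py, pz)

    # trunk chain, pitched forward by the trunk flexion angle
    trunk_heights = {
        Joint.SPINE_NAVEL: 0.15,
        Joint.SPINE_CHEST: 0.30,
        Joint.NECK: 0.50,
        Joint.HEAD: 0.62,
    }
    for joint, h in trunk_heights.items():
        dx, dz = _pitch(0.0, h, theta)
        put(joint, px + dx, py, pz + dz)

    chest_x = px + _pitch(0.0, 0.30, theta)[0]
    chest_z = pz + _pitch(0.0, 0.30, theta)[1]
    head_x = px + _pitch(0.0, 0.62, theta)[0]
    head_z = pz + _pitch(0.0, 0.62, theta)[1]

    # face joints: rigid offsets from the head, pitched with the trunk
    for joint, (dx0, dy0, dz0) in {
        Joint.NOSE: (0.10, 0.0, 0.02),
        Joint.EYE_LEFT: (0.08, 0.03, 0.05),
        Joint.EYE_RIGHT: (0.08, -0.03, 0.05),
        Joint.EAR_LEFT: (0.0, 0.07, 0.03),
        Joint.EAR_RIGHT: (0.0, -0.07, 0.03),
    }.items():
        dx, dz = _pitch(dx0, dz0, theta)
        put(joint, head_x + dx, py + dy0, head_z + dz)

    # arms: clavicle/shoulder rigid on the chest; elbow/wrist swing
    # anti-phase to the ipsilateral leg
    for side, sign, leg_phase in (("LEFT", 1.0, 0.0), ("RIGHT", -1.0, math.pi)):
        clav = getattr(Joint, f"CLAVICLE_{side}")
        shou = getattr(Joint, f"SHOULDER_{side}")
        elbo = getattr(Joint, f"ELBOW_{side}")
        wris = getattr(Joint, f"WRIST_{side}")
        hand = getattr(Joint, f"HAND_{side}")
        htip = getattr(Joint, f"HANDTIP_{side}")
        thum = getattr(Joint, f"THUMB_{side}")

        dxc, dzc = _pitch(0.0, 0.17, theta)
        put(clav, chest_x + dxc, py + sign * 0.05, chest_z + dzc)
        dxs, dzs = _pitch(0.0, 0.17, theta)
        sx = chest_x + dxs
        sy = py + sign * profile.shoulder_half_width
        sz = chest_z + dzs
        put(shou, sx, sy, sz)

        arm_len = profile.upper_arm_length + profile.forearm_length
        gamma = (params.arm_swing / arm_len) * np.sin(phase + leg_phase + math.pi)
        ex = sx + profile.upper_arm_length * np.sin(gamma)
        ez = sz - profile.upper_arm_length * np.cos(gamma)
        put(elbo, ex, sy, ez)
        wx = ex + profile.forearm_length * np.sin(gamma + 0.30)
        wz = ez - profile.forearm_length * np.cos(gamma + 0.30)
        put(wris, wx, sy, wz)
        put(hand, wx + 0.05, sy, wz - 0.05)
        put(htip, wx + 0.10, sy, wz - 0.08)
        put(thum, wx + 0.03, sy - sign * 0.03, wz - 0.02)

    # legs: rigid thigh/shank with phase-locked hip swing and knee flexion
    for side, sign, leg_phase in (("LEFT", 1.0, 0.0), ("RIGHT", -1.0, math.pi)):
        hip = getattr(Joint, f"HIP_{side}")
        knee = getattr(Joint, f"KNEE_{side}")
        ankle = getattr(Joint, f"ANKLE_{side}")
        foot = getattr(Joint, f"FOOT_{side}")

        hx = px
        hy = py + sign * profile.hip_half_width
        hz = pz - 0.06
        put(hip, hx, hy, hz)

        alpha = alpha_amp * np.sin(phase + leg_phase)
        beta = beta_max * 0.5 * (1.0 - np.cos(phase + leg_phase))
        kx = hx + profile.thigh_length * np.sin(alpha)
        kz = hz - profile.thigh_length * np.cos(alpha)
        put(knee, kx, hy, kz)
        ax = kx + profile.shank_length * np.sin(alpha - beta)
        az = kz - profile.shank_length * np.cos(alpha - beta)
        put(ankle, ax, hy, az)
        put(foot, ax + 0.12, hy, az - 0.05)

    pos += rng.normal(0.0, config.noise_sigma, size=pos.shape) \
        if config.noise_sigma > 0 else 0.0
    return pos


def generate_dataset(config: SimulationConfig | None = None) -> Dataset:
    """Generate the full synthetic dataset: subjects x trials x 3 levels.

    Deterministic given ``config`` (including its seed); provenance records
    the configuration.  The default configuration yields 10 x 10 x 3 = 300
    sequences of 22-38 frames each.
    """
    if config is None:
        config = SimulationConfig()
    samples = []
    for subject_id in range(config.n_subjects):
        profile = sample_subject_profile(config, subject_id)
        for level in (0, 1, 2):
            for trial_id in range(config.n_trials):
                rng = _rng(config.seed, subject_id, level, trial_id)
                params = apply_level(profile, level, rng,
                                     level_params=config.level_params)
                frames = synthesize_walk(profile, params, config, rng)
                samples.append(SkeletonSequence(
                    subject_id=subject_id, trial_id=trial_id, level=level,
                    frames=frames, joint_set=FULL32,
                ))
    cfg = asdict(config)
    cfg["level_params"] = {k: [list(v[0]), v[1]]
                           for k, v in config.level_params.items()}
    return Dataset(samples=samples, provenance={
        "generator": "gaitbalance.simulator.generate_dataset",
        "config": cfg,
        "seed": config.seed,
    })
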