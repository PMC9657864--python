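"""Synthetic skeleton-motion generator.

The generator produces labeled keypoint streams with the kinematic structure
that separates falls from activities of daily living (ADLs): during a fall
the trunk rotates rapidly from vertical toward (and slightly past)
horizontal while the hips give way, so the nose-line angular rate spikes and
the nose descends past hip height (the nose/hip ratio R crosses 1); during
ADLs — standing, walking, sitting down, bending over, or a stumble that is
recovered — angular rates stay bounded and the nose stays above the hip.

The body is abstracted as a two-rod chain: hip -> shoulder (trunk rod) ->
nose (neck rod), held collinear, pivoting about the hip with a smooth
raised-cosine lean profile per scenario; falls additionally translate and
drop the hip. Per-frame Gaussian jitter on every coordinate stands in for
pose-estimation error; timestamps carry small jitter around the nominal
frame period to mimic a real ~18 Hz capture.

``fall_peak_angular_rate`` and ``adl_max_angular_rate`` are defined on the
*observable* the downstream features measure — the angular rate of the
nose-to-origin line — and each trial's motion duration is calibrated
numerically so the noiseless profile peaks at the configured rate. This
makes the separation between the two classes a single, directly meaningful
knob.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .io_keypoints import DEFAULT_ACTIVITY_MAP, KeypointFrame, KeypointSequence

ALL_SCENARIOS = (
    "stand",
    "walk",
    "sit",
    "bend_intentional",
    "near_fall_recovered",
    "fall_forward",
    "fall_sideward",
)

#: Activity code written for each scenario (UP-Fall convention: 1-5 fall).
SCENARIO_ACTIVITY = {
    "stand": 7,
    "walk": 6,
    "sit": 8,
    "bend_intentional": 9,
    "near_fall_recovered": 10,
    "fall_forward": 1,
    "fall_sideward": 4,
}

_FALL_SCENARIOS = {"fall_forward", "fall_sideward"}


@dataclass(frozen=True)
class SimulationConfig:
    fps: float = 18.0
    n_trials_per_scenario: int = 48
    scenarios: tuple[str, ...] = ALL_SCENARIOS
    trunk_length: float = 0.30
    neck_length: float = 0.15
    fall_peak_angular_rate: float = 1.5  # rad/s, nose-line rate at the peak of a fall
    adl_max_angular_rate: float = 0.5  # rad/s, cap for intentional movements
    noise_sd: float = 0.004  # coordinate jitter, image units
    timestamp_jitter_sd: float = 0.0015  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.adl_max_angular_rate < self.fall_peak_angular_rate:
            raise ConfigurationError(
                "adl_max_angular_rate must be below fall_peak_angular_rate"
            )
        unknown = set(self.scenarios) - set(ALL_SCENARIOS)
        if unknown:
            raise ConfigurationError(f"unknown scenarios: {sorted(unknown)}")


def _raised_cosine(u: np.ndarray | float) -> np.ndarray | float:
    """Smooth 0 -> 1 ramp on u in [0, 1], clamped outside."""
    u = np.clip(u, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


@dataclass(frozen=True)
class _Geometry:
    hip_x: float
    hip_y: float
    z0: float
    trunk: float
    neck: float

    def nose_xy(self, theta: float | np.ndarray, d: float,
                hip_dx: float | np.ndarray = 0.0,
                hip_dy: float | np.ndarray = 0.0):
        r = self.trunk + self.neck
        return (
            self.hip_x + hip_dx + d * r * np.sin(theta),
            self.hip_y + hip_dy - r * np.cos(theta),
        )


def _nose_angle(geom: _Geometry, theta, d, hip_dx=0.0, hip_dy=0.0):
    nx, ny = geom.nose_xy(theta, d, hip_dx, hip_dy)
    return np.arctan2(ny, nx)  # equals arctan(ny/nx) for nx > 0


def _calibrated_duration(
    geom: _Geometry,
    profile: Callable[[np.ndarray], tuple],
    target_rate: float,
    lo: float = 0.3,
    hi: float = 3.0,
) -> float:
    """Duration T such that the noiseless nose-line angular rate of
    ``profile`` (defined on unit time) peaks at ``target_rate``.

    Rates scale as 1/T under time reparametrization, so one fine-grid
    evaluation at T=1 suffices.
    """
    u = np.linspace(0.0, 1.0, 2001)
    theta, d, hip_dx, hip_dy = profile(u)
    a = _nose_angle(geom, theta, d, hip_dx, hip_dy)
    peak = np.abs(np.gradient(a, u)).max()
    return float(np.clip(peak / target_rate, lo, hi))


def _frame(
    t: float,
    subject_id: str,
    trial_id: str,
    activity_id: int,
    geom: _Geometry,
    theta: float,
    d: float,
    hip_dx: float,
    hip_dy: float,
    dz: float,
    noise: np.ndarray,
    excluded: bool = False,
) -> KeypointFrame:
    hx = geom.hip_x + hip_dx
    hy = geom.hip_y + hip_dy
    sx = hx + d * geom.trunk * np.sin(theta)
    sy = hy - geom.trunk * np.cos(theta)
    r = geom.trunk + geom.neck
    nx = hx + d * r * np.sin(theta)
    ny = hy - r * np.cos(theta)
    z = geom.z0 + dz
    coords = np.array([nx, ny, z, sx, sy, z, hx, hy, z]) + noise
    return KeypointFrame(
        t=t,
        subject_id=subject_id,
        trial_id=trial_id,
        activity_id=activity_id,
        excluded=excluded,
        N_x=coords[0], N_y=coords[1], N_z=coords[2],
        LSh_x=coords[3], LSh_y=coords[4], LSh_z=coords[5],
        LH_x=coords[6], LH_y=coords[7], LH_z=coords[8],
    )


def _timestamps(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    dt = np.full(n, 1.0 / cfg.fps)
    if cfg.timestamp_jitter_sd > 0:
        jitter = rng.normal(0.0, cfg.timestamp_jitter_sd, size=n)
        dt = np.maximum(dt + np.clip(jitter, -0.01, 0.01), 1e-3)
    t = np.cumsum(dt)
    return t - t[0]


def simulate_trial(
    scenario: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "S01",
    trial_id: str = "T001",
) -> KeypointSequence:
    """Generate one trial of the given scenario.

    Frames after a simulated impact are flagged ``excluded``. Every frame of
    a trial carries the scenario's activity code (fall recordings are tagged
    as falls throughout, including the short standing lead-in).
    """
    if scenario not in ALL_SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    # all leans orient away from the image origin (d=+1): the arctan(y/x)
    # feature frame is singular at x=0, so a lean toward the origin would
    # conflate closeness-to-origin with angular speed and no realistic fall
    # duration could match the configured peak rate
    d = 1.0
    geom = _Geometry(
        hip_x=float(rng.uniform(0.30, 0.60)),
        hip_y=float(rng.uniform(0.55, 0.65)),
        z0=float(rng.uniform(1.8, 2.2)),
        trunk=cfg.trunk_length,
        neck=cfg.neck_length,
    )
    if scenario in _FALL_SCENARIOS:
        frames = _simulate_fall(scenario, cfg, geom, rng, subject_id, trial_id, d)
    else:
        frames = _simulate_adl(scenario, cfg, geom, rng, subject_id, trial_id, d)
    return KeypointSequence(frames=frames, nominal_fps=cfg.fps)


def _noise(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros(9)
    return rng.normal(0.0, cfg.noise_sd, size=9)


def _simulate_fall(scenario, cfg, geom, rng, subject_id, trial_id, d):
    if scenario == "fall_sideward":
        # lateral camera: a sideward fall projects mostly into depth
        x_gain, z_gain = 0.45, 0.9
    else:
        x_gain, z_gain = 1.0, 0.15
    # the trunk lean itself is not reduced for sideward falls (the body goes
    # down regardless); only its in-image x displacement is foreshortened
    theta_max = 1.83  # ~105 deg: slightly past horizontal, so R crosses 1
    hip_drop, hip_shift = 0.15, 0.10
    T_fall = _calibrated_duration(
        geom,
        lambda u: (theta_max * _raised_cosine(u), d,
                   d * hip_shift * _raised_cosine(u) * x_gain,
                   hip_drop * _raised_cosine(u)),
        cfg.fall_peak_angular_rate,
        lo=0.3, hi=1.5,
    )
    n_fall = max(int(np.ceil(T_fall * cfg.fps)), 4)
    n_pre = max(2, 18 - n_fall) + int(rng.integers(0, 3))
    n_post = int(round(0.4 * cfg.fps))
    n = n_pre + n_fall + n_post
    t = _timestamps(n, cfg, rng)
    t_fall_start = t[n_pre]
    act_fall = SCENARIO_ACTIVITY[scenario]
    frames = []
    for k in range(n):
        if k < n_pre:
            # short standing lead-in; the whole trial carries the fall code,
            # matching activity-level tagging of fall recordings
            theta, hdx, hdy, act, excl = 0.0, 0.0, 0.0, act_fall, False
        elif k < n_pre + n_fall:
            u = (t[k] - t_fall_start) / T_fall
            q = _raised_cosine(u)
            theta = theta_max * q
            hdx = d * hip_shift * q * x_gain
            hdy = hip_drop * q
            act, excl = act_fall, False
        else:
            theta, hdx, hdy = theta_max, d * hip_shift * x_gain, hip_drop
            act, excl = act_fall, True  # post-impact: subject is on the floor
        dz = d * z_gain * 0.3 * _raised_cosine(
            (t[k] - t_fall_start) / T_fall if k >= n_pre else 0.0
        )
        frames.append(
            _frame(t[k], subject_id, trial_id, act, geom, theta, d,
                   hdx, hdy, dz, _noise(rng, cfg), excluded=excl)
        )
    return frames


def _simulate_adl(scenario, cfg, geom, rng, subject_id, trial_id, d):
    act = SCENARIO_ACTIVITY[scenario]
    duration = float(rng.uniform(3.0, 4.0))
    n = int(round(duration * cfg.fps))
    t = _timestamps(n, cfg, rng)
    total = t[-1] if n > 1 else 1.0

    if scenario == "stand":
        def pose(tk):
            return 0.0, 0.0, 0.0, 0.0
    elif scenario == "walk":
        v = d * float(rng.uniform(0.05, 0.10))
        amp = 0.05
        freq = 0.9

        def pose(tk):
            theta = amp * np.sin(2 * np.pi * freq * tk)
            return theta, v * tk, 0.01 * np.sin(2 * np.pi * 2 * freq * tk), 0.0
    elif scenario == "sit":
        theta_peak, drop = 0.25, 0.15
        T_m = _calibrated_duration(
            geom,
            lambda u: (theta_peak * _raised_cosine(u), d, 0.0,
                       drop * _raised_cosine(u)),
            0.8 * cfg.adl_max_angular_rate, lo=0.6, hi=2.5,
        )
        t0 = 0.3 * total

        def pose(tk):
            q = _raised_cosine((tk - t0) / T_m)
            return theta_peak * q, 0.0, drop * q, 0.0
    elif scenario == "bend_intentional":
        theta_peak = 1.1  # a deep bend, nose still above hip

        def updown(u):
            return _raised_cosine(np.minimum(2 * np.asarray(u), 2 - 2 * np.asarray(u)))

        T_m = _calibrated_duration(
            geom,
            lambda u: (theta_peak * updown(u), d, 0.0, 0.02 * updown(u)),
            cfg.adl_max_angular_rate, lo=0.8, hi=4.0,
        )
        t0 = 0.2 * total

        def pose(tk):
            u = (tk - t0) / T_m
            q = float(updown(np.clip(u, 0.0, 1.0)))
            return theta_peak * q, 0.0, 0.02 * q, 0.0
    elif scenario == "near_fall_recovered":
        theta_peak = 0.7  # stumble: trunk pitches, then recovers

        def updown(u):
            return _raised_cosine(np.minimum(2 * np.asarray(u), 2 - 2 * np.asarray(u)))

        T_m = _calibrated_duration(
            geom,
            lambda u: (theta_peak * updown(u), d, 0.04 * updown(u), 0.03 * updown(u)),
            1.2 * cfg.adl_max_angular_rate, lo=0.5, hi=3.0,
        )
        t0 = 0.3 * total

        def pose(tk):
            u = (tk - t0) / T_m
            q = float(updown(np.clip(u, 0.0, 1.0)))
            return theta_peak * q, d * 0.04 * q, 0.03 * q, 0.0
    else:  # pragma: no cover - guarded by simulate_trial
        raise ConfigurationError(scenario)

    frames = []
    for k in range(n):
        theta, hdx, hdy, dz = (float(v) for v in pose(t[k]))
        frames.append(
            _frame(t[k], subject_id, trial_id, act, geom, theta, d,
                   hdx, hdy, dz, _noise(rng, cfg))
        )
    return frames


def simulate_dataset(
    cfg: SimulationConfig = SimulationConfig(),
) -> tuple[list[KeypointSequence], dict[int, str]]:
    """Generate trials for every configured scenario.

    Returns the sequences plus the activity_id -> {fall, not_fall} mapping
    they were generated under.
    """
    if not cfg.scenarios:
        raise ConfigurationError("scenario mix is empty")
    if cfg.n_trials_per_scenario < 1:
        raise ConfigurationError("n_trials_per_scenario must be >= 1")
    ss = np.random.SeedSequence(cfg.seed)
    n_total = len(cfg.scenarios) * cfg.n_trials_per_scenario
    children = ss.spawn(n_total + 1)
    # interleave scenarios across the session, as in a real recording
    # campaign, so a temporal split sees every scenario on both sides
    order_rng = np.random.default_rng(children[0])
    plan = [
        (scenario, i)
        for i in range(cfg.n_trials_per_scenario)
        for scenario in cfg.scenarios
    ]
    plan = [plan[j] for j in order_rng.permutation(len(plan))]
    sequences = []
    for k, (scenario, i) in enumerate(plan):
        rng = np.random.default_rng(children[k + 1])
        subject = f"S{(k % 17) + 1:02d}"
        trial = f"{scenario}-{i:03d}"
        sequences.append(
            simulate_trial(scenario, cfg, rng, subject_id=subject, trial_id=trial)
        )
    return sequences, dict(DEFAULT_ACTIVITY_MAP)
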