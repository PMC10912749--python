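"""Synthetic cohort generator for mobile motor-assessment streams.

A single latent severity ``s`` in [0, 1] drives every task-level effect:
slower and more variable tapping with within-session fatigue drift, noisier
tap placement and alternation errors, a 4-6 Hz tremor oscillation whose
amplitude scales with ``s`` (healthy controls produce sensor noise only),
shrinking radius and decaying angular velocity in tracing/drawing,
a growing between-hand lag in the bimanual coordination task, and reduced
gait speed and foot-tap cadence.  Per-task noise is independent given
``s``, so features correlate through severity without being degenerate
copies of one another.

Clinical labels are derived from the same latent: the motor score is
``round(clip(68*s + eps, 0, 68))`` with Gaussian label noise, matching the
observed 8-68 score range of the motor scale in a PD clinic cohort, and
the Hoehn & Yahr stage is a fixed monotone binning of ``s`` (0 reserved
for controls).

All randomness flows from one root seed via ``numpy.random.SeedSequence``
spawning, so a config fully determines the cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    ALL_TASKS,
    trail_centroid,
    HAND_TASKS,
    AccelStream,
    Circle,
    SubjectRecord,
    TaskSession,
    TaskSpec,
    TouchStream,
)

SCREEN_W, SCREEN_H = 375.0, 667.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Effect sizes and cohort layout for the synthetic generator.

    Defaults mirror a single-centre clinic cohort: 50 PD / 29 HC, PD motor
    scores averaging ~32 with range 8-68, HC scores averaging ~9.  All
    rates and amplitudes are per unit severity unless noted.
    """

    n_pd: int = 50
    n_hc: int = 29
    seed: int = 0

    # latent severity distributions (Beta shape parameters)
    severity_pd_beta: tuple[float, float] = (2.0, 2.3)
    severity_hc_beta: tuple[float, float] = (1.3, 9.0)

    # finger tapping (tasks 1, 2, 5)
    base_interval: float = 0.35        # s, healthy inter-tap interval
    interval_inflation: float = 0.8    # mu(s) = mu0 * (1 + alpha*s)
    interval_cv: float = 0.2           # coefficient of variation of intervals
    fatigue_drift: float = 0.35        # fractional interval growth over a session at s=1
    tap_noise_sigma: float = 8.0       # screen pts, healthy tap scatter
    tap_noise_inflation: float = 2.5   # sigma(s) = sigma0 * (1 + inflation*s)
    alternation_error_slope: float = 0.25  # P(same-side double tap) = slope*s
    target_interval_mult: float = 3.0  # task 5 nose round-trip multiplier

    # tremor (tasks 3, 4)
    tremor_amp: float = 1.2            # m/s^2 at s=1 (PD only)
    tremor_band: tuple[float, float] = (4.0, 6.0)  # Hz
    accel_noise: float = 0.08          # m/s^2 baseline sensor noise
    angle_noise: float = 0.01          # rad baseline attitude noise
    tremor_angle_amp: float = 0.05     # rad at s=1

    # tracing / drawing (tasks 6-8)
    radius_decay: float = 0.5          # fractional radius shrink over a session at s=1
    angular_decay: float = 0.5         # fractional angular-velocity decay at s=1
    trace_speed: float = 1.26          # rad/s around the traced circle/spiral
    draw_speed: float = 3.0            # rad/s free circle drawing
    trace_noise: float = 2.0           # screen pts
    trace_noise_inflation: float = 2.0

    # coordination (task 9)
    lag_slope: float = 0.4             # s of right-hand lag at s=1

    # foot tapping / gait (tasks 10, 11)
    foot_cadence: float = 2.0          # Hz healthy heel tapping
    gait_speed: float = 1.0            # m/s healthy
    gait_reduction: float = 0.5        # v(s) = v0 * (1 - beta*s)
    gait_cadence: float = 1.8          # steps/s healthy
    step_amp: float = 3.0              # m/s^2 step/tap impulse amplitude
    gait_distance: float = 6.0         # m (3 m out + 3 m back)

    # labels
    label_noise_sd: float = 4.0        # SD of eps in the motor-score map
    updrs_max: int = 68
    hy_bins: tuple[float, ...] = (0.25, 0.7, 0.85, 0.95)

    # sampling
    touch_rate: float = 30.0           # Hz move-event sampling
    accel_rate: float = 50.0           # Hz

    # tasks whose streams respond to severity (others behave as s=0);
    # used to construct ablation scenarios
    severity_tasks: frozenset[int] = frozenset(ALL_TASKS)

    def validate(self) -> None:
        if self.n_pd + self.n_hc == 0:
            raise ValueError("cohort must contain at least one subject")
        for name in ("base_interval", "interval_cv", "tap_noise_sigma", "tremor_amp",
                     "accel_noise", "radius_decay", "angular_decay", "lag_slope",
                     "gait_speed", "label_noise_sd", "fatigue_drift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.tremor_band
        if not 0 < lo < hi:
            raise ValueError("tremor_band must satisfy 0 < lo < hi")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SeverityProfile:
    """Per-task generative parameters derived monotonically from severity."""

    s: float
    tap_interval: float        # mu(s), s
    tap_sigma: float           # pts
    p_alternation_error: float
    fatigue: float             # fractional interval growth across the session
    tremor_amp: float          # m/s^2
    radius_shrink: float       # fractional shrink across the session
    angular_decay: float       # fractional angular-velocity decay
    trace_sigma: float         # pts
    lag: float                 # s
    foot_interval: float       # s between heel taps
    gait_velocity: float       # m/s
    gait_cadence: float        # steps/s

    @classmethod
    def from_config(cls, s: float, cfg: GeneratorConfig) -> "SeverityProfile":
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {s}")
        return cls(
            s=s,
            tap_interval=cfg.base_interval * (1 + cfg.interval_inflation * s),
            tap_sigma=cfg.tap_noise_sigma * (1 + cfg.tap_noise_inflation * s),
            p_alternation_error=min(1.0, cfg.alternation_error_slope * s),
            fatigue=cfg.fatigue_drift * s,
            tremor_amp=cfg.tremor_amp * s,
            radius_shrink=min(0.9, cfg.radius_decay * s),
            angular_decay=min(0.9, cfg.angular_decay * s),
            trace_sigma=cfg.trace_noise * (1 + cfg.trace_noise_inflation * s),
            lag=cfg.lag_slope * s,
            foot_interval=(1.0 / cfg.foot_cadence) * (1 + cfg.interval_inflation * s),
            gait_velocity=max(0.1, cfg.gait_speed * (1 - cfg.gait_reduction * s)),
            gait_cadence=max(0.5, cfg.gait_cadence * (1 - 0.2 * s)),
        )


# ---------------------------------------------------------------------------
# task geometry

def _circle_polyline(cx: float, cy: float, r: float, n: int = 73) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def _spiral_polyline(cx: float, cy: float, r_max: float, turns: int = 3,
                     n: int = 181) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi * turns, n)
    r = r_max * th / th[-1]
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def _coordination_trail(side: str, n: int = 61) -> np.ndarray:
    """Vertical wavy trail on one half of the screen; left/right mirror
    images across the vertical midline."""
    u = np.linspace(0.0, 1.0, n)
    y = 150.0 + 360.0 * u
    x = 95.0 + 30.0 * np.sin(4 * np.pi * u)
    if side == "right":
        x = SCREEN_W - x
    return np.column_stack([x, y])


def default_task_specs() -> dict[int, TaskSpec]:
    cx, cy = SCREEN_W / 2, SCREEN_H / 2
    specs = {
        1: TaskSpec(1, circles=[Circle(cx, 380.0, 45.0)], duration=10.0),
        2: TaskSpec(2, circles=[Circle(112.5, 380.0, 45.0), Circle(262.5, 380.0, 45.0)],
                    duration=10.0),
        3: TaskSpec(3, duration=10.0),
        4: TaskSpec(4, duration=10.0),
        5: TaskSpec(5, circles=[Circle(cx, 200.0, 45.0)], duration=10.0),
        6: TaskSpec(6, trails=[_circle_polyline(cx, cy, 120.0)], duration=10.0),
        7: TaskSpec(7, trails=[_spiral_polyline(cx, cy, 140.0)], duration=10.0),
        8: TaskSpec(8, trails=[_circle_polyline(cx, cy, 150.0)], duration=10.0),
        9: TaskSpec(9, trails=[_coordination_trail("left"), _coordination_trail("right")],
                    duration=10.0),
        10: TaskSpec(10, duration=10.0),
        11: TaskSpec(11, duration=12.0),
    }
    for spec in specs.values():
        spec.validate()
    return specs


# ---------------------------------------------------------------------------
# stream simulators

def _gamma_interval(mean: float, cv: float, rng: np.random.Generator) -> float:
    if cv <= 0 or mean <= 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def _sim_tapping(prof: SeverityProfile, cfg: GeneratorConfig, spec: TaskSpec,
                 rng: np.random.Generator, task_id: int) -> TouchStream:
    T = spec.duration
    mult = cfg.target_interval_mult if task_id == 5 else 1.0
    mu0 = prof.tap_interval * mult
    t_list, x_list, y_list, ev_list = [], [], [], []
    t = 0.3
    side = int(rng.integers(len(spec.circles))) if task_id == 2 else 0
    while t < T:
        circ = spec.circles[side]
        x = circ.cx + (rng.normal(0, prof.tap_sigma) if prof.tap_sigma > 0 else 0.0)
        y = circ.cy + (rng.normal(0, prof.tap_sigma) if prof.tap_sigma > 0 else 0.0)
        interval = _gamma_interval(mu0 * (1 + prof.fatigue * t / T), cfg.interval_cv, rng)
        interval = max(interval, 0.05)
        t_list += [t, t + 0.3 * interval]
        x_list += [x, x]
        y_list += [y, y]
        ev_list += ["down", "up"]
        if task_id == 2:
            # alternation error: stay on the same side with probability p
            if not (prof.p_alternation_error > 0 and rng.random() < prof.p_alternation_error):
                side = 1 - side
        t += interval
    n = len(t_list)
    return TouchStream(
        np.array(t_list), np.array(x_list), np.array(y_list),
        np.full(n, "only", dtype="U5"), np.array(ev_list, dtype="U4"),
    )


def _sim_trace(prof: SeverityProfile, cfg: GeneratorConfig, spec: TaskSpec,
               rng: np.random.Generator, task_id: int) -> TouchStream:
    """Circle tracing (6), spiral tracing (7) and free circle drawing (8).

    The drawn radius shrinks linearly across the session and the angular
    velocity decays linearly, both at severity-scaled rates, on top of
    positional jitter.
    """
    T = spec.duration
    tt = np.arange(0.0, T, 1.0 / cfg.touch_rate)
    frac = tt / T
    decay = 1 - prof.angular_decay * frac
    shrink = 1 - prof.radius_shrink * frac
    trail = spec.trails[0]
    cx, cy = trail_centroid(trail)
    if task_id == 7:
        # spiral traced at constant arc speed (slowing with severity), so
        # the whole spiral is covered in T at s=0
        theta_max = 6 * np.pi
        k = 140.0 / theta_max
        th_dense = np.linspace(0.0, theta_max, 2000)
        seg = np.hypot(k, k * th_dense[:-1]) * np.diff(th_dense)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        dt = 1.0 / cfg.touch_rate
        progress = np.concatenate([[0.0], np.cumsum(decay[:-1]) * dt]) / T
        theta = np.interp(progress * cum[-1], cum, th_dense)
        r_ref = k * theta
    else:
        omega0 = cfg.draw_speed if task_id == 8 else cfg.trace_speed
        omega = omega0 * decay
        theta = np.concatenate([[0.0], np.cumsum(omega[:-1] * np.diff(tt))])
        r_ref = np.hypot(trail[0, 0] - cx, trail[0, 1] - cy)  # constant radius
    r = r_ref * shrink
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    if prof.trace_sigma > 0:
        x = x + rng.normal(0, prof.trace_sigma, len(tt))
        y = y + rng.normal(0, prof.trace_sigma, len(tt))
    ev = np.full(len(tt), "move", dtype="U4")
    ev[0] = "down"
    return TouchStream(tt, x, y, np.full(len(tt), "only", dtype="U5"), ev)


def _trail_point(trail: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Linear interpolation along a polyline at normalized arc parameter u."""
    seg = np.linalg.norm(np.diff(trail, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    pos = np.clip(u, 0.0, 1.0) * cum[-1]
    x = np.interp(pos, cum, trail[:, 0])
    y = np.interp(pos, cum, trail[:, 1])
    return np.column_stack([x, y])


def _sim_coordination(prof: SeverityProfile, cfg: GeneratorConfig, spec: TaskSpec,
                      rng: np.random.Generator) -> TouchStream:
    """Both index fingers trace mirror trails; the right hand lags by
    ``prof.lag`` seconds with independent jitter."""
    T = spec.duration
    tt = np.arange(0.0, T, 1.0 / cfg.touch_rate)
    u = tt / T
    u_lag = np.clip((tt - prof.lag), 0.0, T) / T
    left = _trail_point(spec.trails[0], u)
    right = _trail_point(spec.trails[1], u_lag)
    if prof.trace_sigma > 0:
        left = left + rng.normal(0, prof.trace_sigma, left.shape)
        right = right + rng.normal(0, prof.trace_sigma, right.shape)
    n = len(tt)
    t = np.repeat(tt, 2)
    x = np.empty(2 * n)
    y = np.empty(2 * n)
    x[0::2], y[0::2] = left[:, 0], left[:, 1]
    x[1::2], y[1::2] = right[:, 0], right[:, 1]
    pointer = np.tile(np.array(["left", "right"], dtype="U5"), n)
    ev = np.full(2 * n, "move", dtype="U4")
    ev[:2] = "down"
    return TouchStream(t, x, y, pointer, ev)


def _bumps(tt: np.ndarray, times: np.ndarray, amp: float, width: float) -> np.ndarray:
    out = np.zeros_like(tt)
    for ti in times:
        out += amp * np.exp(-0.5 * ((tt - ti) / width) ** 2)
    return out


def _sim_tremor(prof: SeverityProfile, cfg: GeneratorConfig, spec: TaskSpec,
                rng: np.random.Generator, group: str) -> AccelStream:
    """Baseline sensor noise plus, for PD subjects, a severity-scaled
    sinusoid at a subject-specific frequency in the tremor band."""
    T = spec.duration
    tt = np.arange(0.0, T, 1.0 / cfg.accel_rate)
    n = len(tt)
    noise = lambda sd: rng.normal(0, sd, n) if sd > 0 else np.zeros(n)  # noqa: E731
    f = rng.uniform(*cfg.tremor_band)
    amp = prof.tremor_amp if group == "PD" else 0.0
    weights = {"x": 1.0, "y": 0.7, "z": 0.4}
    acc = {}
    for axis, w in weights.items():
        phase = rng.uniform(0, 2 * np.pi)
        acc[axis] = noise(cfg.accel_noise) + w * amp * np.sin(2 * np.pi * f * tt + phase)
    ang_amp = cfg.tremor_angle_amp * prof.s if group == "PD" else 0.0
    ang = {}
    for name in ("roll", "pitch", "yaw"):
        phase = rng.uniform(0, 2 * np.pi)
        ang[name] = noise(cfg.angle_noise) + ang_amp * np.sin(2 * np.pi * f * tt + phase)
    return AccelStream(tt, acc["x"], acc["y"], acc["z"],
                       ang["roll"], ang["pitch"], ang["yaw"], cfg.accel_rate)


def _sim_foot_tapping(prof: SeverityProfile, cfg: GeneratorConfig, spec: TaskSpec,
                      rng: np.random.Generator) -> AccelStream:
    T = spec.duration
    tt = np.arange(0.0, T, 1.0 / cfg.accel_rate)
    n = len(tt)
    times = np.arange(0.5, T - 0.2, prof.foot_interval)
    if cfg.interval_cv > 0 and len(times):
        times = times + rng.normal(0, 0.02, len(times))
    az = _bumps(tt, times, cfg.step_amp, 0.03)
    noise = lambda sd: rng.normal(0, sd, n) if sd > 0 else np.zeros(n)  # noqa: E731
    return AccelStream(tt, noise(cfg.accel_noise), noise(cfg.accel_noise),
                       az + noise(cfg.accel_noise),
                       noise(cfg.angle_noise), noise(cfg.angle_noise),
                       noise(cfg.angle_noise), cfg.accel_rate)


def _sim_gait(prof: SeverityProfile, cfg: GeneratorConfig, spec: TaskSpec,
              rng: np.random.Generator) -> AccelStream:
    """Quiet lead-in, a step-impulse train spanning the 6 m walk, quiet end.

    The first and last step peaks bracket the walk, so the walking time
    recovered from the peak span equals distance / velocity.
    """
    walk_time = cfg.gait_distance / prof.gait_velocity
    n_steps = max(2, int(round(walk_time * prof.gait_cadence)) + 1)
    t0 = 2.0
    times = t0 + np.linspace(0.0, walk_time, n_steps)
    if cfg.interval_cv > 0 and n_steps > 2:
        times[1:-1] = times[1:-1] + rng.normal(0, 0.02, n_steps - 2)
    T = walk_time + 4.0
    tt = np.arange(0.0, T, 1.0 / cfg.accel_rate)
    n = len(tt)
    az = _bumps(tt, times, cfg.step_amp, 0.04)
    noise = lambda sd: rng.normal(0, sd, n) if sd > 0 else np.zeros(n)  # noqa: E731
    return AccelStream(tt, noise(cfg.accel_noise), noise(cfg.accel_noise),
                       az + noise(cfg.accel_noise),
                       noise(cfg.angle_noise), noise(cfg.angle_noise),
                       noise(cfg.angle_noise), cfg.accel_rate)


# ---------------------------------------------------------------------------
# subjects and cohorts

def simulate_subject(
    subject_id: str,
    group: str,
    severity: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    specs: dict[int, TaskSpec] | None = None,
    updrs3_score: int | None = None,
    hy_stage: int | None = None,
) -> SubjectRecord:
    """Simulate all 11 task sessions (per-hand tasks once per hand).

    Tasks excluded from ``config.severity_tasks`` are generated at
    effective severity 0 regardless of ``severity``.
    """
    specs = specs or default_task_specs()
    if updrs3_score is None or hy_stage is None:
        group_, updrs3_score, hy_stage = assign_labels(severity, group, config, rng)
    age = float(np.clip(rng.normal(68.0, 8.0), 43, 88))
    gender = "F" if rng.random() < 0.45 else "M"
    moca = int(np.clip(round(rng.normal(26.0, 3.0)), 16, 30))
    record = SubjectRecord(subject_id, group, int(updrs3_score), int(hy_stage),
                           moca, age, gender)
    for task_id in ALL_TASKS:
        eff_s = severity if task_id in config.severity_tasks else 0.0
        prof = SeverityProfile.from_config(eff_s, config)
        hands = ("L", "R") if task_id in HAND_TASKS else (None,)
        for hand in hands:
            spec = specs[task_id]
            if task_id in (1, 2, 5):
                ses = TaskSession(task_id, hand, spec,
                                  touch=_sim_tapping(prof, config, spec, rng, task_id))
            elif task_id in (6, 7, 8):
                ses = TaskSession(task_id, hand, spec,
                                  touch=_sim_trace(prof, config, spec, rng, task_id))
            elif task_id == 9:
                ses = TaskSession(task_id, hand, spec,
                                  touch=_sim_coordination(prof, config, spec, rng))
            elif task_id in (3, 4):
                ses = TaskSession(task_id, hand, spec,
                                  accel=_sim_tremor(prof, config, spec, rng, group))
            elif task_id == 10:
                ses = TaskSession(task_id, hand, spec,
                                  accel=_sim_foot_tapping(prof, config, spec, rng))
            else:
                ses = TaskSession(task_id, hand, spec,
                                  accel=_sim_gait(prof, config, spec, rng))
            record.add_session(ses)
    record.validate()
    return record


def assign_labels(
    s: float, group: str, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Map latent severity to (group, motor score, H&Y stage)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {s}")
    eps = rng.normal(0, config.label_noise_sd) if config.label_noise_sd > 0 else 0.0
    score = int(round(float(np.clip(config.updrs_max * s + eps, 0, config.updrs_max))))
    if group == "HC":
        return "HC", score, 0
    stage = 1 + int(np.searchsorted(np.asarray(config.hy_bins), s, side="right"))
    return "PD", score, min(stage, 5)


def draw_severity(group: str, config: GeneratorConfig, rng: np.random.Generator) -> float:
    a, b = config.severity_pd_beta if group == "PD" else config.severity_hc_beta
    return float(rng.beta(a, b))


def simulate_cohort(
    config: GeneratorConfig, specs: dict[int, TaskSpec] | None = None
) -> list[SubjectRecord]:
    """Simulate ``n_pd + n_hc`` independent subjects from one root seed."""
    config.validate()
    specs = specs or default_task_specs()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_pd + config.n_hc)
    records = []
    groups = ["PD"] * config.n_pd + ["HC"] * config.n_hc
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        s = draw_severity(group, config, rng)
        records.append(simulate_subject(f"S{i:03d}", group, s, config, rng, specs))
    return records
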