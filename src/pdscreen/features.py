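"""Per-task feature extractors for mobile motor-assessment streams.

Tapping tasks yield counts (total / valid / missed / paired taps), the
summed distance of tap locations to the nearest target centroid ("bias"),
inter-tap interval statistics and the declining slope of tapping frequency
over the session — a low and declining tapping frequency is the digital
signature of bradykinesia.  Tracing and drawing tasks yield trail bias,
tracing velocity (average and declining slope), the reduction slope of the
finger-to-centroid distance (micrographia) and, for free circle drawing,
angular-velocity statistics.  Tremor tasks yield per-axis acceleration and
rotation dispersion plus a spectral estimate of tremor frequency; foot
tapping and gait yield peak-train counts and walking velocity.

Slope features all use ordinary least squares of a response against time;
undefined features (too few samples, degenerate geometry) return NaN and
are imputed at the cohort level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, periodogram
from scipy.spatial import cKDTree

from .datamodel import (
    ALL_TASKS,
    trail_centroid,
    HAND_TASKS,
    AccelStream,
    SubjectRecord,
    TaskSession,
    TaskSpec,
    TouchStream,
    session_key,
)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable extraction parameters (windows, bands, thresholds)."""

    frequency_window: float = 1.0        # s, tapping-frequency window
    position_rate: float = 3.0           # Hz, resampling for centroid-distance series
    angular_interval: float = 0.3        # s, angular-velocity interval
    tremor_band: tuple[float, float] = (1.0, 12.0)   # Hz analysed band
    peak_separation_foot: float = 0.25   # s
    peak_separation_gait: float = 0.4    # s
    peak_prominence_mads: float = 2.0    # prominence = mads * MAD(magnitude)
    passed_point_tol: float = 15.0       # pts, trail-point visit tolerance
    gait_distance: float = 6.0           # m


@dataclass(frozen=True)
class TapEvent:
    t: float
    x: float
    y: float
    target_hit: int | None   # index of the containing circle, None if missed
    valid: bool


@dataclass(frozen=True)
class SlopeFit:
    a: float   # slope, response units per second
    b: float   # intercept
    n_points: int


@dataclass(frozen=True)
class TremorSummary:
    accel_sd: dict[str, float]
    accel_rms: dict[str, float]
    rotation_sd: dict[str, float]
    tremor_frequency: float  # NaN when no in-band power


def ols_fit(t: np.ndarray, r: np.ndarray) -> SlopeFit:
    """Least-squares line r = a*t + b."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if len(t) < 2 or np.ptp(t) == 0:
        return SlopeFit(np.nan, np.nan, len(t))
    a, b = np.polyfit(t, r, 1)
    return SlopeFit(float(a), float(b), len(t))


# ---------------------------------------------------------------------------
# tapping

def detect_taps(stream: TouchStream, spec: TaskSpec) -> list[TapEvent]:
    """One TapEvent per down event; a tap is valid when it lies inside
    (boundary included) some target circle."""
    taps = []
    for i in np.flatnonzero(stream.event == "down"):
        x, y = float(stream.x[i]), float(stream.y[i])
        hit = None
        best = np.inf
        for j, c in enumerate(spec.circles):
            d = np.hypot(x - c.cx, y - c.cy)
            if d <= c.r and d < best:
                hit, best = j, d
        taps.append(TapEvent(float(stream.t[i]), x, y, hit, hit is not None))
    return taps


def count_paired_taps(taps: list[TapEvent], spec: TaskSpec) -> int:
    """Completed alternating left-right pairs of valid taps.

    Taps outside both circles or breaking the alternation do not count;
    invalid taps are simply skipped (they neither pair nor reset the
    alternation), and a same-side valid tap replaces the pending tap.
    """
    if len(spec.circles) != 2:
        raise ValueError("paired taps require a two-circle task spec")
    pairs = 0
    pending: int | None = None
    for tap in sorted(taps, key=lambda e: e.t):
        if not tap.valid:
            continue
        if pending is None or tap.target_hit == pending:
            pending = tap.target_hit
        else:
            pairs += 1
            pending = None
    return pairs


def tap_bias(taps: list[TapEvent], spec: TaskSpec) -> float:
    """Sum over all taps of the distance to the nearest target centroid."""
    if not taps:
        return 0.0
    if not spec.circles:
        raise ValueError("tap bias requires at least one target circle")
    total = 0.0
    for tap in taps:
        total += min(np.hypot(tap.x - c.cx, tap.y - c.cy) for c in spec.circles)
    return float(total)


def interval_stats(taps: list[TapEvent]) -> tuple[float, float]:
    """Mean and population variance of successive inter-tap intervals."""
    if len(taps) < 2:
        return (np.nan, np.nan)
    t = np.sort([tap.t for tap in taps])
    d = np.diff(t)
    return (float(np.mean(d)), float(np.var(d)))


def frequency_slope(taps: list[TapEvent], window: float = 1.0,
                    duration: float | None = None) -> SlopeFit:
    """OLS slope of per-window tap counts (taps/s per second).

    The session is partitioned into consecutive non-overlapping windows
    from t=0; the frequency series is fit against window mid-times.
    """
    if not taps:
        return SlopeFit(np.nan, np.nan, 0)
    t = np.array([tap.t for tap in taps])
    end = duration if duration is not None else float(t.max())
    n_win = int(end // window)
    if n_win < 2:
        return SlopeFit(np.nan, np.nan, n_win)
    edges = np.arange(n_win + 1) * window
    counts, _ = np.histogram(t, bins=edges)
    freq = counts / window
    mids = edges[:-1] + window / 2
    return ols_fit(mids, freq)


# ---------------------------------------------------------------------------
# tracing / drawing

def _resample_positions(stream: TouchStream, rate: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mv = stream.moves()
    if len(mv) < 2:
        return np.array([]), np.array([]), np.array([])
    tt = np.arange(mv.t[0], mv.t[-1] + 1e-12, 1.0 / rate)
    return tt, np.interp(tt, mv.t, mv.x), np.interp(tt, mv.t, mv.y)


def centroid_distance_slope(stream: TouchStream, centroid: tuple[float, float],
                            rate: float = 3.0) -> SlopeFit:
    """Slope of the finger-to-centroid distance series r_1..r_n (pts/s),
    with positions resampled at ``rate``.  A negative slope captures the
    shrinking drawn radius characteristic of micrographia."""
    tt, x, y = _resample_positions(stream, rate)
    if len(tt) < 2:
        return SlopeFit(np.nan, np.nan, len(tt))
    r = np.hypot(x - centroid[0], y - centroid[1])
    return ols_fit(tt, r)


def trace_velocity_features(stream: TouchStream) -> tuple[float, SlopeFit]:
    """(average velocity pts/s, velocity declining slope pts/s^2).

    Average velocity is path length / elapsed time; the slope is OLS of
    instantaneous segment speeds against segment mid-times.
    """
    mv = stream.moves()
    if len(mv) < 3:
        return (np.nan, SlopeFit(np.nan, np.nan, len(mv)))
    dt = np.diff(mv.t)
    keep = dt > 0
    seg = np.hypot(np.diff(mv.x), np.diff(mv.y))
    elapsed = mv.t[-1] - mv.t[0]
    avg = float(seg.sum() / elapsed) if elapsed > 0 else np.nan
    speed = seg[keep] / dt[keep]
    mids = (mv.t[:-1] + mv.t[1:])[keep] / 2
    return (avg, ols_fit(mids, speed))


def trail_bias(stream: TouchStream, trail: np.ndarray) -> float:
    """Mean over drawn samples of the distance to the nearest reference
    trail point (sampling-rate invariant, unlike the summed tap bias)."""
    mv = stream.moves()
    if len(mv) == 0:
        return np.nan
    if len(trail) == 0:
        raise ValueError("reference trail is empty")
    tree = cKDTree(np.asarray(trail, dtype=float))
    d, _ = tree.query(np.column_stack([mv.x, mv.y]))
    return float(np.mean(d))


def circle_drawing_angular(stream: TouchStream, interval: float = 0.3
                           ) -> tuple[float, SlopeFit]:
    """(mean angular velocity rad/s, angular-velocity slope rad/s^2).

    The polar angle about the drawn centroid is unwrapped and resampled at
    ``interval``; velocities are differences per interval.  The series is
    sign-normalized to the dominant drawing direction so clockwise and
    counter-clockwise drawings are comparable.
    """
    mv = stream.moves()
    if len(mv) < 3 or (mv.t[-1] - mv.t[0]) < 3 * interval:
        return (np.nan, SlopeFit(np.nan, np.nan, 0))
    cx, cy = float(np.mean(mv.x)), float(np.mean(mv.y))
    r = np.hypot(mv.x - cx, mv.y - cy)
    if np.max(r) < 1e-9:
        return (np.nan, SlopeFit(np.nan, np.nan, 0))
    theta = np.unwrap(np.arctan2(mv.y - cy, mv.x - cx))
    tt = np.arange(mv.t[0], mv.t[-1] + 1e-12, interval)
    th = np.interp(tt, mv.t, theta)
    omega = np.diff(th) / interval
    if th[-1] - th[0] < 0:
        omega = -omega
    mids = tt[:-1] + interval / 2
    return (float(np.mean(omega)), ols_fit(mids, omega))


def coordination_features(stream: TouchStream, spec: TaskSpec,
                          config: ExtractionConfig | None = None,
                          screen_width: float = 375.0) -> dict[str, float]:
    """Bimanual coordination metrics from an interleaved two-pointer stream.

    ``lr_coordination`` is the mean distance between the left-hand position
    and the mirror image (across the vertical screen midline) of the
    time-matched right-hand position, so a pure lag or asymmetry shows up
    while the mirrored screen geometry cancels.  ``passed_points`` counts
    reference trail points visited within tolerance by either hand.
    """
    config = config or ExtractionConfig()
    left = stream.for_pointer("left").moves()
    right = stream.for_pointer("right").moves()
    out: dict[str, float] = {}
    if len(left) == 0 or len(right) == 0:
        return {k: np.nan for k in
                ("bias", "vel_avg", "vel_slope", "lr_coordination", "passed_points")}
    biases, avgs, slopes = [], [], []
    for sub, trail in ((left, spec.trails[0]), (right, spec.trails[1])):
        biases.append(trail_bias(sub, trail))
        avg, fit = trace_velocity_features(sub)
        avgs.append(avg)
        slopes.append(fit.a)
    out["bias"] = float(np.nanmean(biases))
    out["vel_avg"] = float(np.nanmean(avgs))
    out["vel_slope"] = float(np.nanmean(slopes))
    rx = np.interp(left.t, right.t, right.x)
    ry = np.interp(left.t, right.t, right.y)
    mirror_x = screen_width - rx
    out["lr_coordination"] = float(np.mean(np.hypot(left.x - mirror_x, left.y - ry)))
    drawn = np.column_stack([np.concatenate([left.x, right.x]),
                             np.concatenate([left.y, right.y])])
    tree = cKDTree(drawn)
    passed = 0
    for trail in spec.trails:
        d, _ = tree.query(np.asarray(trail, dtype=float))
        passed += int(np.sum(d <= config.passed_point_tol))
    out["passed_points"] = float(passed)
    return out


# ---------------------------------------------------------------------------
# accelerometer

def tremor_features(stream: AccelStream, band: tuple[float, float] = (1.0, 12.0)
                    ) -> TremorSummary:
    """Dispersion and spectral summary of a tremor recording.

    The tremor frequency is the power-weighted mean frequency
    sum(f * P(f)) / sum(P(f)) over ``band``, where P is the summed
    periodogram of the mean-removed per-axis accelerations.  Requires
    sampling above Nyquist for the band's upper edge.
    """
    stream = stream.resampled()
    if stream.sample_rate <= 2 * band[1]:
        raise ValueError(
            f"sample rate {stream.sample_rate} Hz below Nyquist for band {band}")
    if len(stream) < 2 * stream.sample_rate:
        raise ValueError("tremor analysis requires >= 2 s of data")
    accel_sd = {k: float(np.std(v)) for k, v in stream.axes().items()}
    accel_rms = {k: float(np.sqrt(np.mean(v**2))) for k, v in stream.axes().items()}
    rotation_sd = {k: float(np.std(v)) for k, v in stream.angles().items()}
    power = None
    for v in stream.axes().values():
        f, p = periodogram(v - np.mean(v), fs=stream.sample_rate, window="boxcar")
        power = p if power is None else power + p
    in_band = (f >= band[0]) & (f <= band[1])
    total = float(np.sum(power[in_band]))
    if total <= 0:
        freq = np.nan
    else:
        freq = float(np.sum(f[in_band] * power[in_band]) / total)
    return TremorSummary(accel_sd, accel_rms, rotation_sd, freq)


def _default_prominence(mag: np.ndarray, mads: float) -> float:
    """Noise floor for impulse detection: ``mads`` median absolute
    deviations above the background, but never below 30% of the excursion
    of the tallest impulse (sparse tall impulses barely move the MAD, so a
    pure MAD threshold would admit sensor-noise peaks)."""
    mad = float(np.median(np.abs(mag - np.median(mag))))
    spread = float(np.max(mag) - np.median(mag))
    return max(mads * mad, 0.3 * spread, 1e-12)


def count_acceleration_peaks(stream: AccelStream, min_prominence: float | None = None,
                             min_separation: float = 0.25,
                             prominence_mads: float = 2.0) -> int:
    """Local maxima of the acceleration magnitude exceeding a prominence
    threshold and separated by at least ``min_separation`` seconds."""
    stream = stream.resampled()
    mag = stream.magnitude
    if len(mag) < 3:
        return 0
    if min_prominence is None:
        min_prominence = _default_prominence(mag, prominence_mads)
    distance = max(1, int(round(min_separation * stream.sample_rate)))
    peaks, _ = find_peaks(mag, prominence=min_prominence, distance=distance)
    return int(len(peaks))


def gait_features(stream: AccelStream, distance: float = 6.0,
                  config: ExtractionConfig | None = None) -> tuple[float, int]:
    """(walking velocity m/s, total steps) from the step-impulse train.

    Walking time is the span between the first and last detected step
    peak; velocity is the walk distance over that time.
    """
    config = config or ExtractionConfig()
    stream = stream.resampled()
    mag = stream.magnitude
    prominence = _default_prominence(mag, config.peak_prominence_mads)
    dist = max(1, int(round(config.peak_separation_gait * stream.sample_rate)))
    peaks, _ = find_peaks(mag, prominence=prominence, distance=dist)
    if len(peaks) < 2:
        return (np.nan, int(len(peaks)))
    span = float(stream.t[peaks[-1]] - stream.t[peaks[0]])
    if span <= 0:
        return (np.nan, int(len(peaks)))
    return (distance / span, int(len(peaks)))


# ---------------------------------------------------------------------------
# registry and whole-record extraction

_TAPPING_FEATURES = ("n_taps", "valid_taps", "missed", "bias",
                     "interval_mean", "interval_var", "freq_slope")
_TREMOR_FEATURES = ("acc_sd_x", "acc_sd_y", "acc_sd_z",
                    "acc_rms_x", "acc_rms_y", "acc_rms_z",
                    "rot_sd_roll", "rot_sd_pitch", "rot_sd_yaw", "tremor_freq")
_TRACE_FEATURES = ("bias", "vel_avg", "vel_slope", "radius_slope")

_TASK_FEATURES: dict[int, tuple[str, ...]] = {
    1: _TAPPING_FEATURES,
    2: _TAPPING_FEATURES + ("paired_taps",),
    3: _TREMOR_FEATURES,
    4: _TREMOR_FEATURES,
    5: ("duration", "n_taps", "valid_taps", "interval_mean", "interval_var",
        "freq_slope"),
    6: _TRACE_FEATURES,
    7: _TRACE_FEATURES,
    8: _TRACE_FEATURES + ("angvel_mean", "angvel_slope"),
    9: ("bias", "vel_avg", "vel_slope", "lr_coordination", "passed_points"),
    10: ("n_taps",),
    11: ("walk_velocity", "n_steps"),
}


def feature_registry() -> list[str]:
    """Ordered list of all feature column names (task{k}[_{L|R}]_{name})."""
    names = []
    for task_id in ALL_TASKS:
        hands = ("L", "R") if task_id in HAND_TASKS else (None,)
        for hand in hands:
            prefix = f"task{task_id}_{hand}_" if hand else f"task{task_id}_"
            names += [prefix + f for f in _TASK_FEATURES[task_id]]
    return names


def _extract_tapping(ses: TaskSession, config: ExtractionConfig) -> dict[str, float]:
    taps = detect_taps(ses.touch, ses.spec)
    valid = sum(tap.valid for tap in taps)
    mean_iv, var_iv = interval_stats(taps)
    slope = frequency_slope(taps, config.frequency_window,
                            duration=ses.spec.duration if ses.spec else None)
    out = {
        "n_taps": float(len(taps)),
        "valid_taps": float(valid),
        "missed": float(len(taps) - valid),
        "bias": tap_bias(taps, ses.spec),
        "interval_mean": mean_iv,
        "interval_var": var_iv,
        "freq_slope": slope.a,
    }
    if ses.task_id == 2:
        out["paired_taps"] = float(count_paired_taps(taps, ses.spec))
    if ses.task_id == 5:
        t = [tap.t for tap in taps]
        out = {
            "duration": float(max(t) - min(t)) if len(t) >= 2 else np.nan,
            "n_taps": out["n_taps"],
            "valid_taps": out["valid_taps"],
            "interval_mean": mean_iv,
            "interval_var": var_iv,
            "freq_slope": slope.a,
        }
    return out


def _extract_trace(ses: TaskSession, config: ExtractionConfig) -> dict[str, float]:
    trail = ses.spec.trails[0]
    centroid = trail_centroid(trail)
    avg, vfit = trace_velocity_features(ses.touch)
    rfit = centroid_distance_slope(ses.touch, centroid, config.position_rate)
    out = {
        "bias": trail_bias(ses.touch, trail),
        "vel_avg": avg,
        "vel_slope": vfit.a,
        "radius_slope": rfit.a,
    }
    if ses.task_id == 8:
        mean_w, wfit = circle_drawing_angular(ses.touch, config.angular_interval)
        out["angvel_mean"] = mean_w
        out["angvel_slope"] = wfit.a
    return out


def _extract_tremor(ses: TaskSession, config: ExtractionConfig) -> dict[str, float]:
    ts = tremor_features(ses.accel, config.tremor_band)
    out = {f"acc_sd_{k}": v for k, v in ts.accel_sd.items()}
    out |= {f"acc_rms_{k}": v for k, v in ts.accel_rms.items()}
    out |= {f"rot_sd_{k}": v for k, v in ts.rotation_sd.items()}
    out["tremor_freq"] = ts.tremor_frequency
    return out


def extract_session(ses: TaskSession, config: ExtractionConfig) -> dict[str, float]:
    if ses.task_id in (1, 2, 5):
        return _extract_tapping(ses, config)
    if ses.task_id in (6, 7, 8):
        return _extract_trace(ses, config)
    if ses.task_id == 9:
        return coordination_features(ses.touch, ses.spec, config)
    if ses.task_id in (3, 4):
        return _extract_tremor(ses, config)
    if ses.task_id == 10:
        return {"n_taps": float(count_acceleration_peaks(
            ses.accel, min_separation=config.peak_separation_foot,
            prominence_mads=config.peak_prominence_mads))}
    if ses.task_id == 11:
        velocity, steps = gait_features(ses.accel, config.gait_distance, config)
        return {"walk_velocity": velocity, "n_steps": float(steps)}
    raise ValueError(f"unknown task {ses.task_id}")


def extract_all(record: SubjectRecord, config: ExtractionConfig | None = None
                ) -> dict[str, float]:
    """Feature vector for one subject over the full registry.

    Absent sessions and undefined features yield NaN; imputation happens
    when vectors are assembled into a cohort table.
    """
    config = config or ExtractionConfig()
    record.validate()
    vector: dict[str, float] = {name: np.nan for name in feature_registry()}
    for task_id in ALL_TASKS:
        hands = ("L", "R") if task_id in HAND_TASKS else (None,)
        for hand in hands:
            ses = record.sessions.get(session_key(task_id, hand))
            if ses is None:
                continue
            prefix = f"task{task_id}_{hand}_" if hand else f"task{task_id}_"
            for name, value in extract_session(ses, config).items():
                vector[prefix + name] = float(value)
    return vector
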