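"""Extractor correctness against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdscreen import ExtractionConfig, GeneratorConfig, extract_all, simulate_subject
from pdscreen.datamodel import Circle, TaskSpec
from pdscreen.features import (
    TapEvent,
    centroid_distance_slope,
    circle_drawing_angular,
    count_acceleration_peaks,
    count_paired_taps,
    detect_taps,
    feature_registry,
    frequency_slope,
    gait_features,
    interval_stats,
    ols_fit,
    tap_bias,
    trace_velocity_features,
    trail_bias,
    tremor_features,
)

from conftest import accel_from_axes, touch_from_path, touch_from_taps


# ---------------------------------------------------------------------------
# oracles

def ols_oracle(t, r):
    """Normal-equations slope/intercept, independent of the fit path."""
    t = np.asarray(t, float)
    r = np.asarray(r, float)
    A = np.column_stack([t, np.ones_like(t)])
    coef = np.linalg.solve(A.T @ A, A.T @ r)
    return coef[0], coef[1]


def paired_oracle(symbols):
    """Pairs = sum over maximal alternating runs of valid taps of
    floor(run length / 2); invalid taps are dropped first."""
    valid = [s for s in symbols if s in "LR"]
    pairs = 0
    i = 0
    while i < len(valid):
        j = i + 1
        while j < len(valid) and valid[j] != valid[j - 1]:
            j += 1
        pairs += (j - i) // 2
        i = j
    return pairs


def peak_oracle(mag, min_prominence):
    """O(n^2) textbook peak prominence: for each strict local maximum,
    prominence = height minus the higher of the two minima separating it
    from the nearest higher terrain (or signal edge)."""
    n = len(mag)
    count = 0
    for i in range(1, n - 1):
        if not (mag[i] > mag[i - 1] and mag[i] > mag[i + 1]):
            continue
        left_min = mag[i]
        j = i - 1
        while j >= 0 and mag[j] <= mag[i]:
            left_min = min(left_min, mag[j])
            j -= 1
        right_min = mag[i]
        j = i + 1
        while j < n and mag[j] <= mag[i]:
            right_min = min(right_min, mag[j])
            j += 1
        if mag[i] - max(left_min, right_min) >= min_prominence:
            count += 1
    return count


def taps_from_symbols(symbols, spec):
    """Build a tap sequence: L/R inside the respective circle, M outside."""
    pos = {"L": (-50.0, 0.0), "R": (50.0, 0.0), "M": (0.0, 200.0)}
    return detect_taps(
        touch_from_taps(np.arange(len(symbols), dtype=float),
                        [pos[s][0] for s in symbols],
                        [pos[s][1] for s in symbols]),
        spec,
    )


# ---------------------------------------------------------------------------
# tapping

def test_detect_taps_validity_and_boundary():
    spec = TaskSpec(1, circles=[Circle(0.0, 0.0, 10.0)])
    taps = detect_taps(
        touch_from_taps([0, 1, 2, 3, 4], [0, 5, 10.0, 11, 30], [0, 0, 0, 0, 0]), spec)
    assert [t.valid for t in taps] == [True, True, True, False, False]
    assert sum(t.valid for t in taps) == 3  # boundary tap counts as inside


def test_empty_stream_yields_no_taps():
    spec = TaskSpec(1, circles=[Circle(0, 0, 10)])
    assert detect_taps(touch_from_taps([], [], []), spec) == []


@pytest.mark.parametrize("symbols,expected", [
    ("LRLRLR", 3),
    ("LLR", 1),
    ("LMR", 1),      # invalid tap is skipped, not a reset
    ("LL", 0),
    ("RL", 1),
])
def test_paired_taps_examples(two_circle_spec, symbols, expected):
    assert count_paired_taps(taps_from_symbols(symbols, two_circle_spec),
                             two_circle_spec) == expected


def test_paired_taps_matches_bruteforce_on_all_short_sequences(two_circle_spec):
    for length in range(7):
        for symbols in itertools.product("LRM", repeat=length):
            got = count_paired_taps(taps_from_symbols(symbols, two_circle_spec),
                                    two_circle_spec)
            assert got == paired_oracle(symbols), symbols


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet="LRM", max_size=25))
def test_paired_taps_matches_oracle_on_longer_sequences(symbols):
    spec = TaskSpec(2, circles=[Circle(-50.0, 0.0, 10.0), Circle(50.0, 0.0, 10.0)])
    got = count_paired_taps(taps_from_symbols(symbols, spec), spec)
    assert got == paired_oracle(symbols)


def test_paired_taps_requires_two_circles():
    spec = TaskSpec(1, circles=[Circle(0, 0, 10)])
    with pytest.raises(ValueError):
        count_paired_taps([], spec)


def test_tap_bias_examples_and_oracle():
    spec = TaskSpec(1, circles=[Circle(0.0, 0.0, 10.0)])
    assert tap_bias(taps_from_symbols("", spec), spec) == 0.0
    taps = detect_taps(touch_from_taps([0, 1], [3, 0], [4, 5]), spec)
    assert tap_bias(taps, spec) == pytest.approx(10.0)
    # random taps vs an independent distance-sum oracle, two circles
    spec2 = TaskSpec(2, circles=[Circle(-50, 0, 10), Circle(50, 0, 10)])
    rng = np.random.default_rng(0)
    xs, ys = rng.normal(0, 60, 40), rng.normal(0, 60, 40)
    taps = detect_taps(touch_from_taps(np.arange(40.0), xs, ys), spec2)
    oracle = sum(min(np.hypot(x + 50, y), np.hypot(x - 50, y))
                 for x, y in zip(xs, ys))
    assert tap_bias(taps, spec2) == pytest.approx(oracle, rel=1e-12)


def test_interval_stats_conventions():
    taps = [TapEvent(t, 0, 0, 0, True) for t in (0, 0.5, 1.0, 1.5)]
    assert interval_stats(taps) == (0.5, 0.0)
    taps = [TapEvent(t, 0, 0, 0, True) for t in (0, 1, 3)]
    mean, var = interval_stats(taps)
    assert (mean, var) == (1.5, 0.25)  # population variance of {1, 2}
    assert np.isnan(interval_stats(taps[:1])[0])


def test_interval_stats_matches_two_pass_oracle():
    rng = np.random.default_rng(1)
    t = np.sort(rng.uniform(0, 30, 50))
    taps = [TapEvent(ti, 0, 0, 0, True) for ti in t]
    mean, var = interval_stats(taps)
    d = np.diff(t)
    m = sum(d) / len(d)
    assert mean == pytest.approx(m, rel=1e-12)
    assert var == pytest.approx(sum((x - m) ** 2 for x in d) / len(d), rel=1e-10)


def test_frequency_slope_closed_forms():
    # constant 2 Hz tapping for 10 s -> slope 0
    taps = [TapEvent(t, 0, 0, 0, True) for t in np.arange(0, 10, 0.5)]
    assert frequency_slope(taps, 1.0, duration=10.0).a == pytest.approx(0.0, abs=1e-12)
    # window counts 4,3,2,1 at mid-times 0.5..3.5 -> slope -1
    times = ([0.1, 0.3, 0.5, 0.7] + [1.1, 1.4, 1.7] + [2.2, 2.6] + [3.5])
    fit = frequency_slope([TapEvent(t, 0, 0, 0, True) for t in times], 1.0,
                          duration=4.0)
    assert fit.a == pytest.approx(-1.0, rel=1e-10)


def test_frequency_slope_needs_two_windows():
    taps = [TapEvent(t, 0, 0, 0, True) for t in (0.1, 0.4, 0.8)]
    assert np.isnan(frequency_slope(taps, 1.0).a)


# ---------------------------------------------------------------------------
# slopes and tracing

def test_ols_matches_normal_equations_on_random_instances():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = rng.integers(2, 40)
        t = rng.normal(0, 5, n)
        t[0] += 1e-3  # guard against all-identical times
        r = rng.normal(0, 10, n)
        if np.ptp(t) == 0:
            continue
        fit = ols_fit(t, r)
        a, b = ols_oracle(t, r)
        assert fit.a == pytest.approx(a, rel=1e-10, abs=1e-10)
        assert fit.b == pytest.approx(b, rel=1e-10, abs=1e-10)


def test_centroid_distance_slope_exact_linear():
    t = np.arange(0, 5, 1 / 30)
    r = 100 - 2 * t
    stream = touch_from_path(t, r, np.zeros_like(t))  # along +x from origin
    fit = centroid_distance_slope(stream, (0.0, 0.0), rate=3.0)
    assert fit.a == pytest.approx(-2.0, rel=1e-10)


def test_centroid_distance_slope_constant_radius_is_zero():
    t = np.arange(0, 5, 1 / 30)
    stream = touch_from_path(t, 80 * np.cos(t), 80 * np.sin(t))
    assert centroid_distance_slope(stream, (0.0, 0.0)).a == pytest.approx(0.0, abs=1e-9)


def test_trace_velocity_uniform_and_decaying():
    t = np.arange(0, 10, 0.1)
    stream = touch_from_path(t, 10 * t, np.zeros_like(t))
    avg, fit = trace_velocity_features(stream)
    assert avg == pytest.approx(10.0, rel=1e-12)
    assert fit.a == pytest.approx(0.0, abs=1e-9)
    # speeds 10,8,6,4 over unit-spaced segments -> OLS slope -2
    x = np.concatenate([[0], np.cumsum([10, 8, 6, 4])]).astype(float)
    avg, fit = trace_velocity_features(touch_from_path(np.arange(5.0), x, np.zeros(5)))
    assert fit.a == pytest.approx(-2.0, rel=1e-10)
    assert avg == pytest.approx(28 / 4)  # path length / elapsed


def test_trail_bias_identity_shift_and_oracle():
    u = np.linspace(0, 1, 400)
    trail = np.column_stack([100 * u, 50 * np.sin(2 * np.pi * u)])
    t = np.linspace(0, 10, 400)
    drawn = touch_from_path(t, trail[:, 0], trail[:, 1])
    assert trail_bias(drawn, trail) == 0.0
    # a (3,4) shift perpendicular to a dense straight trail -> distance 5
    line = np.column_stack([400 * u, -300 * u])
    shifted = touch_from_path(t, line[:, 0] + 3, line[:, 1] + 4)
    assert trail_bias(shifted, line) == pytest.approx(5.0, rel=0.01)
    rng = np.random.default_rng(3)
    pts = rng.normal(0, 30, (25, 2))
    drawn = touch_from_path(np.arange(25.0), pts[:, 0], pts[:, 1])
    oracle = np.mean([min(np.hypot(*(p - q)) for q in trail) for p in pts])
    assert trail_bias(drawn, trail) == pytest.approx(oracle, rel=1e-12)


def test_angular_velocity_uniform_circle():
    t = np.arange(0, 3, 0.01)
    theta = 2 * np.pi * t
    stream = touch_from_path(t, 80 * np.cos(theta), 80 * np.sin(theta))
    mean_w, fit = circle_drawing_angular(stream, 0.3)
    assert mean_w == pytest.approx(2 * np.pi, rel=1e-6)
    assert fit.a == pytest.approx(0.0, abs=1e-6)


def test_angular_velocity_linear_decay_slope():
    # omega(t) = 2*pi - (pi/3) t falls from 2*pi to pi over 3 s -> slope -pi/3
    t = np.arange(0, 3.0001, 0.005)
    theta = 2 * np.pi * t - (np.pi / 6) * t**2
    stream = touch_from_path(t, 80 * np.cos(theta), 80 * np.sin(theta))
    mean_w, fit = circle_drawing_angular(stream, 0.3)
    assert fit.a == pytest.approx(-np.pi / 3, rel=0.05)
    assert mean_w == pytest.approx(1.5 * np.pi, rel=0.05)


def test_angle_unwrap_accumulates_full_revolution():
    t = np.arange(0, 1, 0.01)
    theta = 2 * np.pi * t
    stream = touch_from_path(t, np.cos(theta), np.sin(theta))
    mean_w, _ = circle_drawing_angular(stream, 0.3)
    assert mean_w == pytest.approx(2 * np.pi, rel=1e-3)  # not 0


def test_clockwise_drawing_gives_positive_angular_velocity():
    t = np.arange(0, 3, 0.01)
    theta = -2 * np.pi * t
    stream = touch_from_path(t, 80 * np.cos(theta), 80 * np.sin(theta))
    mean_w, _ = circle_drawing_angular(stream, 0.3)
    assert mean_w == pytest.approx(2 * np.pi, rel=1e-6)


# ---------------------------------------------------------------------------
# accelerometer

def test_tremor_frequency_of_pure_sinusoid():
    t = np.arange(0, 10, 1 / 50)
    ts = tremor_features(accel_from_axes(50.0, 0.8 * np.sin(2 * np.pi * 5 * t)))
    assert ts.tremor_frequency == pytest.approx(5.0, abs=0.1)  # one bin = 0.1 Hz
    assert ts.accel_sd["x"] == pytest.approx(0.8 / np.sqrt(2), rel=1e-3)


def test_tremor_frequency_absent_for_dc_stream():
    ts = tremor_features(accel_from_axes(50.0, np.full(500, 2.5)))
    assert np.isnan(ts.tremor_frequency)


def test_tremor_rejects_sub_nyquist_sampling():
    with pytest.raises(ValueError, match="Nyquist"):
        tremor_features(accel_from_axes(20.0, np.zeros(100)), band=(1.0, 12.0))


def test_tremor_weighted_frequency_matches_dft_oracle():
    rng = np.random.default_rng(4)
    sig = rng.normal(0, 1, 500)
    ts = tremor_features(accel_from_axes(50.0, sig))
    # direct rFFT periodogram oracle
    n = len(sig)
    spec = np.abs(np.fft.rfft(sig - sig.mean())) ** 2
    f = np.fft.rfftfreq(n, d=1 / 50)
    band = (f >= 1) & (f <= 12)
    oracle = np.sum(f[band] * spec[band]) / np.sum(spec[band])
    assert ts.tremor_frequency == pytest.approx(oracle, rel=1e-9)


def test_peak_counter_constructed_cases():
    t = np.arange(0, 12, 1 / 50)
    sig = np.zeros_like(t)
    for c in np.arange(0.5, 12, 1.0):
        sig += 3 * np.exp(-0.5 * ((t - c) / 0.05) ** 2)
    assert count_acceleration_peaks(accel_from_axes(50.0, sig)) == 12
    assert count_acceleration_peaks(accel_from_axes(50.0, np.zeros_like(t))) == 0


def test_peak_counter_matches_exhaustive_oracle_on_random_signals():
    rng = np.random.default_rng(5)
    for _ in range(100):
        sig = np.cumsum(rng.normal(0, 1, 120))  # smooth-ish random walk
        sig = np.abs(sig)
        stream = accel_from_axes(50.0, sig)
        prom = 0.5 * float(np.std(sig)) + 0.1
        got = count_acceleration_peaks(stream, min_prominence=prom,
                                       min_separation=0.0)
        assert got == peak_oracle(stream.magnitude, prom)


def test_gait_features_span_and_cadence():
    t = np.arange(0, 10, 1 / 50)
    sig = np.zeros_like(t)
    for c in np.linspace(2.0, 8.0, 11):  # 11 steps spanning exactly 6 s
        sig += 3 * np.exp(-0.5 * ((t - c) / 0.04) ** 2)
    v, steps = gait_features(accel_from_axes(50.0, sig), distance=6.0)
    assert v == pytest.approx(1.0, rel=0.01)
    assert steps == 11
    # doubling cadence at fixed span doubles steps, leaves velocity alone
    sig2 = np.zeros_like(t)
    for c in np.linspace(2.0, 8.0, 21):
        sig2 += 3 * np.exp(-0.5 * ((t - c) / 0.04) ** 2)
    cfg = ExtractionConfig(peak_separation_gait=0.2)
    v2, steps2 = gait_features(accel_from_axes(50.0, sig2), 6.0, cfg)
    assert steps2 == 21
    assert v2 == pytest.approx(v, rel=0.01)


# ---------------------------------------------------------------------------
# whole-record extraction

def test_extract_all_complete_and_deterministic(small_cohort):
    rec = small_cohort[0]
    v1 = extract_all(rec)
    v2 = extract_all(rec)
    assert list(v1) == feature_registry()
    assert v1 == v2


def test_noiseless_zero_severity_vector_has_zero_bias_and_slopes():
    cfg = GeneratorConfig(tap_noise_sigma=0, interval_cv=0, trace_noise=0,
                          accel_noise=0, angle_noise=0, label_noise_sd=0)
    rec = simulate_subject("x", "HC", 0.0, cfg, np.random.default_rng(0))
    vec = extract_all(rec)
    for name, value in vec.items():
        if np.isnan(value):
            continue
        if "bias" in name:
            # trail bias only up to reference polyline discretization
            assert abs(value) < 6.0, name
        if name.endswith(("freq_slope", "vel_slope", "angvel_slope")):
            assert abs(value) < 0.05, name
        if name.endswith("radius_slope") and "task7" not in name:
            assert abs(value) < 0.05, name
    assert vec["task2_L_bias"] == 0.0
    # spiral tracing has an inherently growing radius; severity shrinks it
    assert vec["task7_L_radius_slope"] > 0


def test_missing_hand_session_is_imputed_and_flagged(small_cohort):
    from pdscreen import extract_cohort
    import copy
    records = [copy.deepcopy(r) for r in small_cohort[:6]]
    del records[0].sessions["2L"]
    table = extract_cohort(records)
    assert table.labels.loc[records[0].subject_id, "n_imputed"] > 0
    assert not np.isnan(table.features.loc[records[0].subject_id, "task2_L_bias"])
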