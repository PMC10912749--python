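import numpy as np
import pytest

from pdscreen.datamodel import Circle, TaskSpec, TouchStream, AccelStream


def touch_from_taps(times, xs, ys):
    """TouchStream with one down event per tap."""
    n = len(times)
    return TouchStream(
        t=np.asarray(times, dtype=float),
        x=np.asarray(xs, dtype=float),
        y=np.asarray(ys, dtype=float),
        pointer=np.full(n, "only", dtype="U5"),
        event=np.full(n, "down", dtype="U4"),
    )


def touch_from_path(t, x, y):
    """TouchStream of move samples (first sample is the down event)."""
    n = len(t)
    ev = np.full(n, "move", dtype="U4")
    if n:
        ev[0] = "down"
    return TouchStream(np.asarray(t, float), np.asarray(x, float),
                       np.asarray(y, float), np.full(n, "only", dtype="U5"), ev)


def accel_from_axes(rate, ax, ay=None, az=None):
    n = len(ax)
    zero = np.zeros(n)
    t = np.arange(n) / rate
    return AccelStream(t, np.asarray(ax, float),
                       zero if ay is None else np.asarray(ay, float),
                       zero if az is None else np.asarray(az, float),
                       zero.copy(), zero.copy(), zero.copy(), rate)


@pytest.fixture(scope="session")
def two_circle_spec():
    return TaskSpec(2, circles=[Circle(-50.0, 0.0, 10.0), Circle(50.0, 0.0, 10.0)])


@pytest.fixture(scope="session")
def small_cohort():
    """32-subject default-effect cohort shared across tests."""
    from pdscreen import GeneratorConfig, simulate_cohort
    return simulate_cohort(GeneratorConfig(n_pd=20, n_hc=12, seed=11))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    from pdscreen import extract_cohort
    return extract_cohort(small_cohort)
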