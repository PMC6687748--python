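import numpy as np
import pytest

from pibsampler import (OPTrajectory, ReactionCoordinate, Standardization)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_rc(weights, names=None, shift=None, scale=None, loss=float("nan")):
    """Unit-normalized RC with identity standardization by default."""
    w = np.asarray(weights, dtype=float)
    w = w / np.linalg.norm(w)
    d = w.size
    std = Standardization(
        np.zeros(d) if shift is None else np.asarray(shift, float),
        np.ones(d) if scale is None else np.asarray(scale, float))
    return ReactionCoordinate(weights=w,
                              op_names=names or [f"s{i}" for i in range(d)],
                              standardization=std, loss=loss)


def make_traj(values, dt=0.1, names=None, bias=None, beta=1.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m, d = values.shape
    return OPTrajectory(times=dt * np.arange(m), values=values,
                        names=names or [f"s{i}" for i in range(d)],
                        bias=bias, beta=beta)


@pytest.fixture(scope="session")
def ou_slow_fast():
    """2D overdamped OU data with a planted slow direction at 30 degrees.

    Discrete OU: x_{t+1} = x_t - dt * K x_t + sqrt(2 dt) xi with friction
    matrix K = R diag(k_slow, k_fast) R^T; the slow direction is the
    eigenvector with the smallest rate.
    """
    rng = np.random.default_rng(7)
    th = np.radians(30.0)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    K = R @ np.diag([0.5, 30.0]) @ R.T
    dt = 0.02
    n = 20000
    x = np.zeros((n, 2))
    cur = np.array([1.0, 0.0])
    step = np.eye(2) - dt * K
    noise = np.sqrt(2 * dt)
    xi = rng.standard_normal((n, 2))
    for i in range(n):
        cur = step @ cur + noise * xi[i]
        x[i] = cur
    slow = R[:, 0]
    return make_traj(x, dt=dt), slow
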