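"""Overdamped Langevin dynamics on analytic potentials.

Euler--Maruyama integration of

    x_{t+dt} = x_t - D beta grad[U(x) + V_bias(chi(x))] dt + sqrt(2 D dt) xi,

with xi standard normal.  The bias force is obtained by the chain rule from
the tabulated derivative of a 1D bias grid along a linear reaction
coordinate, using linear interpolation of the exported derivative column —
the same contract an external MD engine reading a PLUMED EXTERNAL grid
would apply.  Outside the grid the bias is constant at its boundary value
(zero force); such frames are counted.

The catalog of built-in potentials provides metastable double wells with
known minima, barrier heights and slow directions so that every stage of
the sampling protocol can be validated against analytic ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .traj_io import OPTrajectory

__all__ = [
    "AnalyticPotential",
    "LangevinParams",
    "simulate",
    "simulate_ensemble",
    "builtin_potentials",
    "double_well_1d",
    "asymmetric_double_well_1d",
    "rotated_double_well_2d",
    "two_barrier_2d",
    "torsion_toy",
]


@dataclass
class AnalyticPotential:
    """An analytic potential energy surface with known metadata.

    ``energy`` and ``gradient`` act on coordinate arrays of shape (dim,) or
    (n, dim).  ``op_map``, when present, maps coordinates to the emitted
    order parameters and returns (ops, jacobian); by default order
    parameters *are* the coordinates.
    """

    name: str
    dimension: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    op_names: list[str]
    metadata: dict = field(default_factory=dict)
    op_map: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n_ops(self) -> int:
        return len(self.op_names)

    def ops(self, x: np.ndarray) -> np.ndarray:
        if self.op_map is None:
            return np.atleast_2d(x)
        return self.op_map(np.atleast_2d(x))[0]

    def check_gradient(self, x: np.ndarray, h: float = 1e-6) -> float:
        """Max relative mismatch between gradient and finite differences."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        g = np.atleast_2d(self.gradient(x))
        worst = 0.0
        for j in range(self.dimension):
            xp, xm = x.copy(), x.copy()
            xp[:, j] += h
            xm[:, j] -= h
            fd = (self.energy(xp) - self.energy(xm)) / (2 * h)
            scale = np.maximum(np.abs(g[:, j]), 1.0)
            worst = max(worst, float(np.max(np.abs(fd - g[:, j]) / scale)))
        return worst


@dataclass(frozen=True)
class LangevinParams:
    """Integration settings for the overdamped Langevin engine."""

    beta: float = 1.0
    diffusion: float = 1.0
    dt: float = 1e-3
    n_steps: int = 10000
    save_stride: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.diffusion <= 0 or self.beta <= 0:
            raise ValueError("dt, diffusion and beta must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")


def _bias_terms(pot: AnalyticPotential, bias, x: np.ndarray):
    """Per-replica bias energy and coordinate-space bias force gradient."""
    grid, rc = bias
    if pot.op_map is None:
        ops = x
        if rc.d != pot.dimension:
            raise ValueError("bias RC dimension does not match potential dimension")
        jac = None
    else:
        ops, jac = pot.op_map(x)
        if rc.d != ops.shape[1]:
            raise ValueError("bias RC dimension does not match order-parameter count")
    chi = rc.project_values(ops)
    v = grid.interpolate(chi)
    dv = np.interp(chi, grid.centers, _bias_der(grid), left=0.0, right=0.0)
    outside = (chi < grid.centers[0]) | (chi > grid.centers[-1])
    dv = np.where(outside, 0.0, dv)
    # dchi/d(op) = c / scale (z-scored projection)
    dchi_dop = rc.weights / rc.standardization.scale
    if jac is None:
        grad = dv[:, None] * dchi_dop[None, :]
    else:
        # jac has shape (n, n_ops, dim)
        grad = dv[:, None] * np.einsum("j,njd->nd", dchi_dop, jac)
    return v, grad, int(outside.sum())


def _bias_der(grid) -> np.ndarray:
    der = getattr(grid, "derivative", None)
    if der is None:
        # central differences on the tabulated values
        der = np.gradient(grid.values, grid.binwidth)
    return np.asarray(der)


def simulate_ensemble(pot: AnalyticPotential, params: LangevinParams,
                      n_replicas: int, bias=None,
                      x0: np.ndarray | None = None) -> list[OPTrajectory]:
    """Run ``n_replicas`` independent overdamped Langevin trajectories.

    ``bias`` is an optional (BiasGrid, ReactionCoordinate) pair — or a list
    of such pairs, applied additively as V1(chi1) + V2(chi2) — acting on
    the emitted order parameters.  Replicas share the integrator loop
    (vectorized) but are statistically independent.  The same seed gives a
    bit-identical ensemble.
    """
    if bias is not None and not isinstance(bias, list):
        bias = [bias]
    if bias is not None:
        bias = [b for b in bias if b is not None and b[0] is not None]
        if not bias:
            bias = None
    rng = np.random.default_rng(params.seed)
    dim = pot.dimension
    if x0 is None:
        x0 = np.asarray(pot.metadata.get("x0", np.zeros(dim)), dtype=float)
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    if x0.shape == (1, dim) and n_replicas > 1:
        x0 = np.repeat(x0, n_replicas, axis=0)
    if x0.shape != (n_replicas, dim):
        raise ValueError("x0 must broadcast to (n_replicas, dimension)")

    x = x0.copy()
    n_saved = params.n_steps // params.save_stride
    ops0 = pot.ops(x)
    saved = np.empty((n_saved, n_replicas, ops0.shape[1]))
    saved_v = np.empty((n_saved, n_replicas)) if bias is not None else None
    step_scale = params.diffusion * params.beta * params.dt
    noise_scale = math.sqrt(2.0 * params.diffusion * params.dt)
    outside_count = 0

    k = 0
    for step in range(1, params.n_steps + 1):
        grad = np.atleast_2d(pot.gradient(x))
        if bias is not None:
            for pair in bias:
                _, gbias, n_out = _bias_terms(pot, pair, x)
                grad = grad + gbias
                outside_count += n_out
        x = x - step_scale * grad + noise_scale * rng.standard_normal((n_replicas, dim))
        if step % params.save_stride == 0:
            saved[k] = pot.ops(x)
            if bias is not None:
                vtot = np.zeros(n_replicas)
                for pair in bias:
                    v, _, _ = _bias_terms(pot, pair, x)
                    vtot += v
                saved_v[k] = vtot
            k += 1

    times = params.dt * params.save_stride * np.arange(1, n_saved + 1)
    trajs = []
    for r in range(n_replicas):
        traj = OPTrajectory(
            times=times, values=saved[:, r, :], names=list(pot.op_names),
            bias=None if saved_v is None else saved_v[:, r],
            beta=params.beta)
        traj.final_coords = x[r].copy()   # for warm continuation
        trajs.append(traj)
    if outside_count:
        for t in trajs:
            t.n_outside_grid = outside_count  # bookkeeping attribute
    return trajs


def simulate(pot: AnalyticPotential, params: LangevinParams, bias=None,
             x0: np.ndarray | None = None) -> OPTrajectory:
    """Single-replica convenience wrapper around :func:`simulate_ensemble`."""
    return simulate_ensemble(pot, params, 1, bias=bias, x0=x0)[0]


# ---------------------------------------------------------------------------
# built-in potentials


def double_well_1d(barrier: float = 4.0) -> AnalyticPotential:
    """U(x) = h (x^2 - 1)^2 with minima at +-1 and barrier h at x = 0."""
    h = float(barrier)

    def energy(x):
        x = np.atleast_2d(x)
        return h * (x[:, 0] ** 2 - 1.0) ** 2

    def gradient(x):
        x = np.atleast_2d(x)
        return (4.0 * h * (x[:, 0] ** 2 - 1.0) * x[:, 0])[:, None]

    return AnalyticPotential(
        name="double_well_1d", dimension=1, energy=energy, gradient=gradient,
        op_names=["x"],
        metadata={"minima": [-1.0, 1.0], "barrier": h, "x0": np.array([-1.0])})


def asymmetric_double_well_1d(barrier: float = 4.0, delta_f: float = 2.0
                              ) -> AnalyticPotential:
    """Tilted double well U(x) = h (x^2-1)^2 + (dF/2) x.

    ``delta_f`` is the energy difference U(+1) - U(-1) = dF between the two
    well bottoms of the untilted wells (the deeper well is at x = -1).
    """
    h, a = float(barrier), float(delta_f) / 2.0

    def energy(x):
        x = np.atleast_2d(x)
        return h * (x[:, 0] ** 2 - 1.0) ** 2 + a * x[:, 0]

    def gradient(x):
        x = np.atleast_2d(x)
        return (4.0 * h * (x[:, 0] ** 2 - 1.0) * x[:, 0] + a)[:, None]

    return AnalyticPotential(
        name="asym_double_well_1d", dimension=1, energy=energy,
        gradient=gradient, op_names=["x"],
        metadata={"minima": [-1.0, 1.0], "barrier": h, "delta_f": float(delta_f),
                  "x0": np.array([-1.0])})


def rotated_double_well_2d(angle_deg: float = 30.0, barrier: float = 3.0,
                           kappa_fast: float = 40.0) -> AnalyticPotential:
    """Double well along a planted slow axis at ``angle_deg``; stiff harmonic
    confinement along the orthogonal fast axis."""
    th = math.radians(angle_deg)
    u = np.array([math.cos(th), math.sin(th)])
    v = np.array([-math.sin(th), math.cos(th)])
    h, kf = float(barrier), float(kappa_fast)

    def energy(x):
        x = np.atleast_2d(x)
        s = x @ u
        f = x @ v
        return h * (s**2 - 1.0) ** 2 + 0.5 * kf * f**2

    def gradient(x):
        x = np.atleast_2d(x)
        s = x @ u
        f = x @ v
        return (4.0 * h * (s**2 - 1.0) * s)[:, None] * u + (kf * f)[:, None] * v

    return AnalyticPotential(
        name="rotated_double_well_2d", dimension=2, energy=energy,
        gradient=gradient, op_names=["s1", "s2"],
        metadata={"slow_direction": u, "barrier": h,
                  "minima": [-u, u], "x0": -u})


def two_barrier_2d(barrier_x: float = 3.0, barrier_y: float = 4.0
                   ) -> AnalyticPotential:
    """Separable two-barrier landscape: independent double wells along x and
    y give four metastable wells at (+-1, +-1); escaping the start well
    requires surmounting first the x barrier and then the y barrier (or
    vice versa), the geometry used for two-component RC learning."""
    hx, hy = float(barrier_x), float(barrier_y)

    def energy(x):
        x = np.atleast_2d(x)
        return hx * (x[:, 0] ** 2 - 1.0) ** 2 + hy * (x[:, 1] ** 2 - 1.0) ** 2

    def gradient(x):
        x = np.atleast_2d(x)
        g = np.empty_like(x)
        g[:, 0] = 4.0 * hx * (x[:, 0] ** 2 - 1.0) * x[:, 0]
        g[:, 1] = 4.0 * hy * (x[:, 1] ** 2 - 1.0) * x[:, 1]
        return g

    return AnalyticPotential(
        name="two_barrier_2d", dimension=2, energy=energy, gradient=gradient,
        op_names=["x", "y"],
        metadata={"barriers": (hx, hy),
                  "axis1": np.array([1.0, 0.0]), "axis2": np.array([0.0, 1.0]),
                  "minima": [np.array([sx, sy]) for sx in (-1, 1) for sy in (-1, 1)],
                  "x0": np.array([-1.0, -1.0])})


def torsion_toy(barrier_phi: float = 4.0, barrier_psi: float = 1.0
                ) -> AnalyticPotential:
    """Two periodic torsions (phi, psi) emitting trigonometric order
    parameters (cos phi, sin phi, cos psi, sin psi).

    U = (h_phi/2)(1 - cos 2 phi) + (h_psi/2)(1 - cos 2 psi): each torsion is
    a periodic double well with barrier h; phi is the slow, high-barrier
    torsion, mimicking a small-peptide backbone.
    """
    hp_, hs = float(barrier_phi), float(barrier_psi)

    def energy(x):
        x = np.atleast_2d(x)
        return 0.5 * hp_ * (1 - np.cos(2 * x[:, 0])) + 0.5 * hs * (1 - np.cos(2 * x[:, 1]))

    def gradient(x):
        x = np.atleast_2d(x)
        g = np.empty_like(x)
        g[:, 0] = hp_ * np.sin(2 * x[:, 0])
        g[:, 1] = hs * np.sin(2 * x[:, 1])
        return g

    def op_map(x):
        x = np.atleast_2d(x)
        phi, psi = x[:, 0], x[:, 1]
        ops = np.column_stack([np.cos(phi), np.sin(phi), np.cos(psi), np.sin(psi)])
        jac = np.zeros((x.shape[0], 4, 2))
        jac[:, 0, 0] = -np.sin(phi)
        jac[:, 1, 0] = np.cos(phi)
        jac[:, 2, 1] = -np.sin(psi)
        jac[:, 3, 1] = np.cos(psi)
        return ops, jac

    return AnalyticPotential(
        name="torsion_toy", dimension=2, energy=energy, gradient=gradient,
        op_names=["cos_phi", "sin_phi", "cos_psi", "sin_psi"],
        metadata={"barriers": (hp_, hs), "x0": np.array([math.pi / 2, math.pi / 2])},
        op_map=op_map)


def builtin_potentials() -> dict[str, Callable[..., AnalyticPotential]]:
    """Catalog of built-in analytic potentials, keyed by name."""
    return {
        "double_well_1d": double_well_1d,
        "asym_double_well_1d": asymmetric_double_well_1d,
        "rotated_double_well_2d": rotated_double_well_2d,
        "two_barrier_2d": two_barrier_2d,
        "torsion_toy": torsion_toy,
    }
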