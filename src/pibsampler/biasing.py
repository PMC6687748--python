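"""Construction of the next-round bias potential along the reaction coordinate.

The raw bias is V(chi) = (1/beta) log P_u(chi) (the negative free energy up
to a constant).  Two rules shape it into the applied bias:

* the minimum over the grid is 0 and the maximum is capped at
  (maximum bias of the previous round + delta_V), where delta_V is a
  confidence constant for poorly sampled regions — caps grow arithmetically
  while they bind and stall once the transition-state anchor bounds the
  bias;
* identifiable transition states (free-energy barriers above a threshold)
  receive exactly zero bias, the prerequisite for recovering unbiased rates
  by time rescaling.

The shift is anchored at the transition states: the raw bias is translated
so that the least-biased barrier region sits exactly at zero, then clipped
to [0, cap] and zeroed on every barrier bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reweighting import FreeEnergyProfile
from .traj_io import GridFunction, write_plumed_grid

__all__ = ["BiasGrid", "identify_transition_states", "build_bias"]


def _central_diff(v: np.ndarray, dx: float) -> np.ndarray:
    """Central differences, second-order one-sided at the endpoints (exact
    for quadratics, so a log-Gaussian bias round-trips through trapezoid
    integration to machine precision)."""
    if v.size >= 3:
        return np.gradient(v, dx, edge_order=2)
    return np.gradient(v, dx)


@dataclass
class BiasGrid:
    """Tabulated bias V_bias(chi) >= 0 (units 1/beta) with cap metadata."""

    grid: GridFunction
    cap: float
    delta_v: float
    ts_regions: list[tuple[float, float]] = field(default_factory=list)
    round_index: int = 0
    derivative: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.grid.values
        if v.min() < -1e-12:
            raise ValueError("bias values must be non-negative")
        if v.max() > self.cap + 1e-9:
            raise ValueError("bias values must not exceed the cap")
        if self.derivative is None:
            self.derivative = _central_diff(v, self.grid.binwidth)

    # -- evaluation contract: linear interpolation between bin centers,
    #    constant (zero-force) beyond the first/last center.
    @property
    def centers(self) -> np.ndarray:
        return self.grid.centers

    @property
    def binwidth(self) -> float:
        return self.grid.binwidth

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def value(self, chi: np.ndarray) -> np.ndarray:
        return self.grid.interpolate(chi)

    def interpolate(self, chi: np.ndarray) -> np.ndarray:
        return self.grid.interpolate(chi)

    def write(self, path) -> None:
        write_plumed_grid(self.grid, self.derivative, path)


def identify_transition_states(profile: FreeEnergyProfile,
                               min_barrier: float,
                               ts_margin: float = 1.0
                               ) -> list[tuple[float, float]]:
    """Locate free-energy barriers separating metastable minima.

    A grid point is a transition state when it is a local maximum of F and
    the drop to the neighbouring minima is at least ``min_barrier`` (units
    1/beta) on both sides.  Each barrier is returned as the chi-interval
    where F stays within ``ts_margin`` of the barrier top.
    """
    f = profile.f
    x = profile.centers
    n = f.size
    regions: list[tuple[float, float]] = []
    for i in range(1, n - 1):
        if not (f[i] >= f[i - 1] and f[i] >= f[i + 1] and
                (f[i] > f[i - 1] or f[i] > f[i + 1])):
            continue
        # depth to the lowest point before climbing above f[i] on each side
        left_min = f[:i].min()
        right_min = f[i + 1:].min()
        # restrict to the basin adjacent to this maximum
        j = i - 1
        lm = f[i]
        while j >= 0 and f[j] <= f[i] + 1e-12:
            lm = min(lm, f[j])
            j -= 1
        j = i + 1
        rm = f[i]
        while j < n and f[j] <= f[i] + 1e-12:
            rm = min(rm, f[j])
            j += 1
        if f[i] - lm < min_barrier or f[i] - rm < min_barrier:
            continue
        lo = i
        while lo > 0 and f[lo - 1] >= f[i] - ts_margin:
            lo -= 1
        hi = i
        while hi < n - 1 and f[hi + 1] >= f[i] - ts_margin:
            hi += 1
        regions.append((float(x[lo]), float(x[hi])))
    # merge overlaps
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(regions):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def build_bias(profile: FreeEnergyProfile,
               prev: BiasGrid | None = None,
               delta_v: float = 2.0,
               ts_regions: list[tuple[float, float]] | None = None,
               round_index: int | None = None) -> BiasGrid:
    """Build the next-round bias grid from an unbiased-density estimate.

    raw = (1/beta) log p_u, shifted so the bias vanishes continuously into
    every transition-state region (or so the raw minimum is 0 when there
    are none), clipped to [0, cap] with cap = max(prev bias) + delta_v (or
    delta_v on the first round), and forced to zero on every
    transition-state bin.  The derivative for export is computed by central
    differences.
    """
    if delta_v <= 0:
        raise ValueError("delta_v must be positive")
    if ts_regions is None:
        ts_regions = []
    g = profile.grid
    m_floor = (0.1 / max(profile.n_effective, 1.0)) / g.binwidth
    raw = np.log(np.maximum(profile.p_u, m_floor)) / profile.beta

    x = g.centers
    ts_mask = np.zeros(g.nbins, dtype=bool)
    for lo, hi in ts_regions:
        ts_mask |= (x >= lo - 1e-12) & (x <= hi + 1e-12)

    if ts_mask.any():
        # anchor at the transition-state bin with the largest raw bias (the
        # region edge): every TS bin then sits at or below zero, so after
        # clipping the bias vanishes continuously into each barrier region —
        # a jump there would break both the applied force and the
        # exp(beta V) bookkeeping right where rates are measured
        shift = raw[ts_mask].max()
    else:
        shift = raw.min()
    v = raw - shift
    cap = (float(prev.values.max()) if prev is not None else 0.0) + delta_v
    v = np.clip(v, 0.0, cap)
    v[ts_mask] = 0.0
    der = _central_diff(v, g.binwidth)
    der[ts_mask] = 0.0
    grid = GridFunction(name=g.name, grid_min=g.grid_min, grid_max=g.grid_max,
                        nbins=g.nbins, values=v, periodic=g.periodic)
    idx = round_index if round_index is not None else (
        prev.round_index + 1 if prev is not None else 0)
    return BiasGrid(grid=grid, cap=cap, delta_v=delta_v,
                    ts_regions=list(ts_regions), round_index=idx,
                    derivative=der)
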