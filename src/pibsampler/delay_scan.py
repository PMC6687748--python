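"""Selection of the predictive time delay by the weight-plateau criterion.

The PIB is trained for gradually increasing lags; the reaction-coordinate
estimate plateaus once the lag exceeds the fast, non-predictive
decorrelation times, and the smallest such lag is kept for all later
rounds.  The plateau criterion is angular and sign-blind: lag l plateaus
when 1 - |cos angle(c_l, c_l')| < 1 - cos(angle_tol) against the next
``n_confirm`` lags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pib_model import PIBHyperparams, PredictiveBottleneck, ReactionCoordinate
from .traj_io import OPTrajectory

__all__ = ["DelayScanResult", "scan", "find_plateau", "default_lag_grid"]

DEFAULT_ANGLE_TOL_DEG = 5.0
DEFAULT_N_CONFIRM = 2


def default_lag_grid(n_frames: int) -> list[int]:
    """Geometric lag grid (1, 2, 5, 10, 20, 50 frames) capped at M/10."""
    grid = [1, 2, 5, 10, 20, 50]
    cap = max(1, n_frames // 10)
    return [k for k in grid if k <= cap] or [1]


@dataclass
class DelayScanResult:
    """Trained RC weights and losses per lag, and the selected plateau lag."""

    lags: list[int]
    stride: float
    weight_vectors: list[np.ndarray]
    losses: list[float]
    plateau_lag: int | None
    rcs: list[ReactionCoordinate] = field(default_factory=list)

    @property
    def delays(self) -> np.ndarray:
        """Physical time delays Delta t = k * stride."""
        return self.stride * np.asarray(self.lags, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lag": self.lags, "delay": self.delays,
                           "loss": self.losses})
        w = np.asarray(self.weight_vectors)
        names = (self.rcs[0].op_names if self.rcs
                 else [f"c{i}" for i in range(w.shape[1])])
        for j, name in enumerate(names):
            df[f"w_{name}"] = w[:, j]
        return df


def find_plateau(weight_vectors, angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
                 n_confirm: int = DEFAULT_N_CONFIRM) -> int | None:
    """Index of the first vector within the angular tolerance of the next
    ``n_confirm`` vectors (sign-blind); None when never satisfied."""
    ws = [np.asarray(w, dtype=float) for w in weight_vectors]
    ws = [w / np.linalg.norm(w) for w in ws]
    thresh = 1.0 - math.cos(math.radians(angle_tol_deg))
    for i in range(len(ws) - n_confirm):
        ok = all(1.0 - abs(float(ws[i] @ ws[i + j])) < thresh
                 for j in range(1, n_confirm + 1))
        if ok:
            return i
    return None


def scan(traj: OPTrajectory, lags: list[int] | None = None,
         hp: PIBHyperparams | None = None,
         weights: np.ndarray | None = None,
         angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
         n_confirm: int = DEFAULT_N_CONFIRM) -> DelayScanResult:
    """Train the PIB at each lag and locate the first weight plateau."""
    if lags is None:
        lags = default_lag_grid(traj.n_frames)
    lags = sorted(int(k) for k in lags)
    if not lags:
        raise ValueError("lag list must not be empty")
    if lags[0] < 1 or lags[-1] >= traj.n_frames:
        raise ValueError("lags must satisfy 1 <= lag < n_frames")
    hp = hp or PIBHyperparams()
    rcs, losses = [], []
    for k in lags:
        res = PredictiveBottleneck(traj, k, hp, weights=weights).fit()
        rcs.append(res.rc)
        losses.append(res.loss)
    wvecs = [rc.weights for rc in rcs]
    idx = find_plateau(wvecs, angle_tol_deg, n_confirm)
    return DelayScanResult(
        lags=lags, stride=traj.stride, weight_vectors=wvecs, losses=losses,
        plateau_lag=None if idx is None else lags[idx], rcs=rcs)
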