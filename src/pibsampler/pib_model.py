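"""Predictive-information-bottleneck reaction-coordinate learner.

The model maps d order parameters through a deterministic *linear* encoder to
a scalar bottleneck chi = sum_i c_i s_i (unit-norm weights, applied to
z-scored inputs), adds Gaussian noise of fixed variance to chi, and decodes
the state a lag of k frames into the future with a two-hidden-layer ELU
network under a spherical Gaussian observation model

    Q(X_{n+k} | chi_n) = N(X_{n+k}; f(chi_n), sigma^2 I).

Training maximizes the variational predictive objective

    L' = { sum_n w^n }^{-1} sum_n w^n log Q(X^{n+k} | chi^n),

with importance weights w^n = exp(beta V^n) when frames were generated under
a bias potential V, and w = 1 otherwise.  Under the Gaussian decoder this is
exactly -(weighted MSE)/(2 sigma^2) - (d/2) log(2 pi sigma^2), so the fit
reduces to weighted mean-square-error minimization; the linear encoder keeps
the learned coordinate physically interpretable.

The public surface follows the statsmodels convention:
:class:`PredictiveBottleneck` is built from a trajectory and
:meth:`PredictiveBottleneck.fit` returns a :class:`PIBResults` carrying the
reaction coordinate, the decoder, per-restart losses and a summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .traj_io import OPTrajectory

__all__ = [
    "PIBHyperparams",
    "Standardization",
    "ReactionCoordinate",
    "DecoderModel",
    "PredictiveBottleneck",
    "PIBResults",
    "project",
    "objective",
    "train",
    "equivalence_check_mse",
]


@dataclass(frozen=True)
class PIBHyperparams:
    """Network and optimizer settings.

    Defaults follow the reference protocol: Gaussian bottleneck-noise
    variance 0.005, two ELU hidden layers of 128 neurons, RMSprop with
    learning rate 0.003, uniform initialization in [-0.005, 0.005].
    """

    noise_variance: float = 0.005
    hidden_layers: int = 2
    hidden_width: int = 128
    activation: str = "elu"
    learning_rate: float = 0.003
    init_range: float = 0.005
    epochs: int = 200
    batch_size: int = 512
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be positive")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.activation != "elu":
            raise ValueError("only the 'elu' activation is supported")


@dataclass(frozen=True)
class Standardization:
    """Per-order-parameter affine transform applied before projection."""

    shift: np.ndarray
    scale: np.ndarray

    @staticmethod
    def identity(d: int) -> "Standardization":
        return Standardization(np.zeros(d), np.ones(d))

    @staticmethod
    def from_data(values: np.ndarray, weights: np.ndarray | None = None,
                  names: list[str] | None = None) -> "Standardization":
        """Weighted z-score transform; raises on a zero-variance column."""
        values = np.asarray(values, dtype=float)
        if weights is None:
            w = np.ones(values.shape[0])
        else:
            w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        mean = w @ values
        var = w @ (values - mean) ** 2
        # relative threshold: roundoff on an exactly-constant column leaves
        # a variance of order (eps * mean)^2, not zero
        bad = np.flatnonzero(var <= 1e-20 * (mean**2 + 1.0))
        if bad.size:
            labels = [names[i] if names else str(i) for i in bad]
            raise ValueError(f"constant order-parameter column(s): {', '.join(labels)}")
        return Standardization(mean, np.sqrt(var))

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.shift) / self.scale


@dataclass
class ReactionCoordinate:
    """Unit-norm linear combination chi = sum_i c_i * standardized(s_i)."""

    weights: np.ndarray
    op_names: list[str]
    standardization: Standardization
    loss: float = math.nan

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = np.linalg.norm(self.weights)
        if abs(n - 1.0) > 1e-8:
            raise ValueError("reaction-coordinate weights must have unit L2 norm")

    @property
    def d(self) -> int:
        return self.weights.size

    def project_values(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.d:
            raise ValueError(
                f"trajectory has {values.shape[1]} order parameters, RC expects {self.d}"
            )
        return self.standardization.apply(values) @ self.weights

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.op_names, name="weight")


def _unit_sign_fix(c: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalize to unit norm; flip sign so the largest-|.| component is positive."""
    c = c / np.linalg.norm(c)
    s = 1.0 if c[np.argmax(np.abs(c))] >= 0 else -1.0
    return s * c, s


def _elu(x: np.ndarray) -> np.ndarray:
    out = np.where(x > 0, x, np.expm1(np.clip(x, None, 0.0)))
    return out


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y = elu(x); derivative is 1 for x>0 and elu(x)+1 otherwise
    return np.where(x > 0, 1.0, y + 1.0)


class DecoderModel:
    """Stochastic decoder f(chi): a dense ELU MLP from bottleneck value(s)
    to a d-vector prediction of the standardized future order parameters."""

    def __init__(self, n_inputs: int, n_outputs: int, hp: PIBHyperparams,
                 rng: np.random.Generator):
        self.n_inputs = n_inputs
        self.n_outputs = n_outputs
        self.hp = hp
        widths = [n_inputs] + [hp.hidden_width] * hp.hidden_layers + [n_outputs]
        self.weights = [
            rng.uniform(-hp.init_range, hp.init_range, size=(a, b))
            for a, b in zip(widths[:-1], widths[1:])
        ]
        self.biases = [rng.uniform(-hp.init_range, hp.init_range, size=b)
                       for b in widths[1:]]

    @property
    def architecture(self) -> str:
        hidden = "-".join(str(self.hp.hidden_width) for _ in range(self.hp.hidden_layers))
        return f"{self.n_inputs}->{hidden}->{self.n_outputs} (elu)"

    def forward(self, chi: np.ndarray, cache: bool = False):
        a = np.atleast_2d(chi)
        if a.ndim == 2 and a.shape[1] != self.n_inputs:
            a = a.reshape(-1, self.n_inputs)
        acts = [a]
        pre = []
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ W + b
            pre.append(z)
            acts.append(_elu(z) if i < n_layers - 1 else z)
        if cache:
            return acts[-1], (pre, acts)
        return acts[-1]

    def predict(self, chi: np.ndarray) -> np.ndarray:
        """Mean prediction f(chi) for bottleneck values chi."""
        return self.forward(chi)

    def backward(self, grad_out: np.ndarray, cache) -> tuple[list, list, np.ndarray]:
        """Backpropagate d(loss)/d(output); returns weight grads, bias grads
        and the gradient with respect to the bottleneck input."""
        pre, acts = cache
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        g = grad_out
        for i in range(len(self.weights) - 1, -1, -1):
            if i < len(self.weights) - 1:
                g = g * _elu_grad(pre[i], acts[i + 1])
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return gW, gb, g

    def flip_input_sign(self, index: int) -> None:
        """Negate one bottleneck input so f(-chi) reproduces the old f(chi)."""
        self.weights[0][index, :] *= -1.0


class _RMSprop:
    """RMSprop with the standard decay 0.9 and epsilon 1e-8."""

    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            c = self.cache.get(i)
            if c is None:
                c = np.zeros_like(p)
            c = self.rho * c + (1.0 - self.rho) * g * g
            self.cache[i] = c
            p -= self.lr * g / (np.sqrt(c) + self.eps)


def _log_q_constant(d: int, sigma2: float) -> float:
    """The chi-independent part of E[log Q]: -(d/2) log(2 pi sigma^2)."""
    return -0.5 * d * math.log(2.0 * math.pi * sigma2)


def _prepare_weights(traj: OPTrajectory, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        w = traj.importance_weights()
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (traj.n_frames,):
            raise ValueError("weights must have one entry per frame")
    if not np.all(np.isfinite(w)):
        raise ValueError("importance weights must be finite")
    if not np.any(w > 0):
        raise ValueError("importance weights are all zero")
    return w


def project(traj: OPTrajectory, rc: ReactionCoordinate) -> np.ndarray:
    """Project a trajectory onto the reaction coordinate, chi^n = c . s^n."""
    if traj.n_ops != rc.d:
        raise ValueError(f"trajectory has {traj.n_ops} order parameters, RC expects {rc.d}")
    return rc.project_values(traj.values)


def objective(traj: OPTrajectory, rc: ReactionCoordinate, decoder: DecoderModel,
              lag_k: int, weights: np.ndarray | None = None,
              fixed_rc: ReactionCoordinate | None = None) -> float:
    """Evaluate the variational predictive objective L'.

    Returns the normalized weighted mean of log Q(X^{n+k} | chi^n) over
    n = 1 .. M-k, evaluated at the decoder mean (no bottleneck noise).
    """
    obj, _ = equivalence_check_mse(traj, rc, decoder, lag_k, weights, fixed_rc)
    return obj


def equivalence_check_mse(traj: OPTrajectory, rc: ReactionCoordinate,
                          decoder: DecoderModel, lag_k: int,
                          weights: np.ndarray | None = None,
                          fixed_rc: ReactionCoordinate | None = None
                          ) -> tuple[float, float]:
    """Return (objective, weighted_mse) and assert their algebraic identity.

    Under the Gaussian decoder, objective = -wMSE/(2 sigma^2) + const with
    const = -(d/2) log(2 pi sigma^2).
    """
    if lag_k < 0 or traj.n_frames - lag_k < 1:
        raise ValueError("need lag_k >= 0 and at least one (past, future) pair")
    w = _prepare_weights(traj, weights)[: traj.n_frames - lag_k]
    w = w / w.sum()
    xs = rc.standardization.apply(traj.values)
    chi = xs @ rc.weights
    past = chi[: traj.n_frames - lag_k]
    if fixed_rc is not None:
        chi_fixed = fixed_rc.project_values(traj.values)[: traj.n_frames - lag_k]
        inputs = np.column_stack([chi_fixed, past])
    else:
        inputs = past[:, None]
    future = xs[lag_k:]
    pred = decoder.forward(inputs)
    resid = pred - future
    wmse = float(w @ np.sum(resid**2, axis=1))
    sigma2 = decoder.hp.noise_variance
    obj = -wmse / (2.0 * sigma2) + _log_q_constant(traj.n_ops, sigma2)
    return obj, wmse


def _train_single(xs: np.ndarray, w: np.ndarray, lag_k: int, hp: PIBHyperparams,
                  rng: np.random.Generator,
                  chi_fixed: np.ndarray | None) -> tuple[np.ndarray, DecoderModel, float]:
    """One optimization run from a random init; returns (c, decoder, loss).

    loss is the final full-data weighted MSE evaluated at the decoder mean
    (noise-free), the quantity minimized up to the Gaussian constant.
    """
    n, d = xs.shape
    n_pairs = n - lag_k
    past = xs[:n_pairs]
    future = xs[lag_k:]
    wn = w[:n_pairs] / w[:n_pairs].sum()
    n_inputs = 1 if chi_fixed is None else 2

    c, _ = _unit_sign_fix(rng.uniform(-hp.init_range, hp.init_range, size=d) + 1e-12)
    decoder = DecoderModel(n_inputs, d, hp, rng)
    opt = _RMSprop(hp.learning_rate)
    sigma = math.sqrt(hp.noise_variance)

    idx_all = np.arange(n_pairs)
    batch = min(hp.batch_size, n_pairs)
    for _ in range(hp.epochs):
        rng.shuffle(idx_all)
        for start in range(0, n_pairs, batch):
            idx = idx_all[start:start + batch]
            xb, yb, wb = past[idx], future[idx], wn[idx]
            wb = wb / wb.sum()
            chi = xb @ c + rng.normal(0.0, sigma, size=idx.size)
            if chi_fixed is None:
                inputs = chi[:, None]
            else:
                inputs = np.column_stack([chi_fixed[idx], chi])
            pred, cache = decoder.forward(inputs, cache=True)
            resid = pred - yb
            grad_out = 2.0 * wb[:, None] * resid
            gW, gb, g_in = decoder.backward(grad_out, cache)
            g_chi = g_in[:, -1]  # gradient wrt the trainable bottleneck column
            g_c = xb.T @ g_chi
            opt.step(decoder.weights + decoder.biases + [c],
                     gW + gb + [g_c])
            nc = np.linalg.norm(c)
            if not np.isfinite(nc) or nc == 0:
                return c, decoder, math.nan
            c /= nc

    # final noise-free loss on the full data
    chi = past @ c
    inputs = chi[:, None] if chi_fixed is None else np.column_stack(
        [chi_fixed[:n_pairs], chi])
    resid = decoder.forward(inputs) - future
    loss = float(wn @ np.sum(resid**2, axis=1))
    return c, decoder, loss


def train(traj: OPTrajectory, lag_k: int, hp: PIBHyperparams | None = None,
          weights: np.ndarray | None = None,
          fixed_rc: ReactionCoordinate | None = None
          ) -> tuple[ReactionCoordinate, DecoderModel]:
    """Train the PIB and return the lowest-loss restart's encoder and decoder.

    See :class:`PredictiveBottleneck` for the object-oriented interface.
    """
    res = PredictiveBottleneck(traj, lag_k, hp, weights=weights,
                               fixed_rc=fixed_rc).fit()
    return res.rc, res.decoder


class PredictiveBottleneck:
    """Predictive-information-bottleneck model for one trajectory.

    Parameters
    ----------
    traj : OPTrajectory
        Training data; when it carries a bias column, Boltzmann importance
        weights exp(beta V) are used automatically.
    lag_k : int
        Predictive delay in frames between past input and future target.
    hyperparams : PIBHyperparams, optional
    weights : array, optional
        Explicit per-frame importance weights, overriding the bias column.
    fixed_rc : ReactionCoordinate, optional
        Washing-out mode: this already-learned coordinate is projected and
        fed to the decoder as a fixed second input while a new orthogonal
        direction is trained.
    """

    def __init__(self, traj: OPTrajectory, lag_k: int,
                 hyperparams: PIBHyperparams | None = None,
                 weights: np.ndarray | None = None,
                 fixed_rc: ReactionCoordinate | None = None):
        if lag_k < 1 or lag_k >= traj.n_frames:
            raise ValueError("lag_k must satisfy 1 <= lag_k < n_frames")
        self.traj = traj
        self.lag_k = int(lag_k)
        self.hp = hyperparams or PIBHyperparams()
        self.weights = _prepare_weights(traj, weights)
        self.fixed_rc = fixed_rc

    def fit(self) -> "PIBResults":
        hp = self.hp
        std = Standardization.from_data(self.traj.values, self.weights,
                                        self.traj.names)
        xs = std.apply(self.traj.values)
        chi_fixed = (self.fixed_rc.project_values(self.traj.values)
                     if self.fixed_rc is not None else None)

        seeds = np.random.SeedSequence(hp.seed).spawn(hp.n_restarts)
        runs = []
        for r in range(hp.n_restarts):
            rng = np.random.default_rng(seeds[r])
            c, dec, loss = _train_single(xs, self.weights, self.lag_k, hp,
                                         rng, chi_fixed)
            if math.isfinite(loss):
                runs.append((loss, r, c, dec))
        if not runs:
            raise RuntimeError("all training restarts diverged (non-finite loss)")
        # lowest loss; ties broken by lowest restart index
        loss, r_best, c, dec = min(runs, key=lambda t: (t[0], t[1]))
        c, sign = _unit_sign_fix(c)
        if sign < 0:
            dec.flip_input_sign(dec.n_inputs - 1)
        rc = ReactionCoordinate(weights=c, op_names=list(self.traj.names),
                                standardization=std, loss=loss)
        restart_losses = np.full(hp.n_restarts, np.nan)
        for l, r, *_ in runs:
            restart_losses[r] = l
        return PIBResults(self, rc, dec, loss, restart_losses, r_best)


class PIBResults:
    """Fitted PIB: reaction coordinate, decoder and diagnostics."""

    def __init__(self, model: PredictiveBottleneck, rc: ReactionCoordinate,
                 decoder: DecoderModel, loss: float,
                 restart_losses: np.ndarray, best_restart: int):
        self.model = model
        self.rc = rc
        self.decoder = decoder
        self.loss = loss
        self.restart_losses = restart_losses
        self.best_restart = best_restart

    @property
    def objective_value(self) -> float:
        """The variational objective L' at the fitted parameters."""
        sigma2 = self.model.hp.noise_variance
        return -self.loss / (2 * sigma2) + _log_q_constant(self.rc.d, sigma2)

    def project(self, traj: OPTrajectory | None = None) -> np.ndarray:
        return project(traj if traj is not None else self.model.traj, self.rc)

    def summary(self) -> str:
        hp = self.model.hp
        lines = [
            "Predictive Information Bottleneck Results",
            "=" * 45,
            f"frames: {self.model.traj.n_frames}   order parameters: {self.rc.d}",
            f"lag (frames): {self.model.lag_k}   "
            f"lag (time): {self.model.lag_k * self.model.traj.stride:g}",
            f"restarts: {hp.n_restarts}   best restart: {self.best_restart}",
            f"weighted MSE loss: {self.loss:.6g}",
            f"objective L': {self.objective_value:.6g}",
            "",
            "reaction-coordinate weights (on z-scored order parameters):",
        ]
        lines += [f"  {n:>12s}  {w: .4f}" for n, w in
                  zip(self.rc.op_names, self.rc.weights)]
        return "\n".join(lines)

    def plot_weights(self, ax=None):
        """Bar plot of the RC weights (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.rc.op_names, self.rc.weights)
        ax.set_ylabel("RC weight $c_i$")
        return ax
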