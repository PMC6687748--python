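"""The iterative sample--learn--bias loop and the two-coordinate stage.

Each round: run several biased replicas, pick the most ergodic one (highest
pooled-z-scored variance) for training, re-learn the reaction coordinate at
the fixed plateau lag with importance-weighted training, re-estimate the
unbiased density of the new coordinate from the pooled replicas, and build
the next bias with its cap raised by delta_V.  The loop runs until both the
coordinate and its free-energy profile stop changing.

When the first bias saturates (its maximum stops tracking the growing cap
and no new regions are visited), a second coordinate chi2 is learned by the
washing-out construction: chi1 and V1(chi1) stay fixed, chi1 is fed to the
decoder as a fixed input, the importance weights account for V2 only, and
the applied bias is the separable sum V1(chi1) + V2(chi2).  chi2 is
re-orthogonalized against chi1 after every fit.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .biasing import BiasGrid, build_bias, identify_transition_states
from .pib_model import (PIBHyperparams, PredictiveBottleneck, ReactionCoordinate,
                        Standardization, project)
from .reweighting import FreeEnergyProfile, estimate_density
from .traj_io import (GridFunction, OPTrajectory, read_colvar, read_plumed_grid,
                      write_colvar, write_plumed_grid)

__all__ = [
    "RoundState",
    "ToySampler",
    "FileSampler",
    "select_training_trajectory",
    "run_round",
    "start_second_rc",
    "check_convergence",
    "PIBProtocol",
    "save_round",
    "load_round",
    "plumed_snippet",
]

N_REPLICAS_DEFAULT = 4
CONV_ANGLE_DEG = 5.0
CONV_F_SUP = 0.5          # units 1/beta


@dataclass
class RoundState:
    """Everything one protocol round produces."""

    round_index: int = 0
    stage: int = 1
    rc1: ReactionCoordinate | None = None
    bias1: BiasGrid | None = None
    rc2: ReactionCoordinate | None = None
    bias2: BiasGrid | None = None
    trajectories: list[OPTrajectory] = field(default_factory=list)
    profile1: FreeEnergyProfile | None = None
    profile2: FreeEnergyProfile | None = None
    converged: bool = False
    saturated: bool = False
    seed: int = 0
    bias_integral: float = math.nan
    coverage: int = 0

    def applied_biases(self) -> list:
        out = []
        if self.bias1 is not None:
            out.append((self.bias1, self.rc1))
        if self.stage >= 2 and self.bias2 is not None:
            out.append((self.bias2, self.rc2))
        return out


class ToySampler:
    """In-process sampler driving the built-in Langevin engine.

    Replicas continue from their previous round's final coordinates (warm
    restart), so each round samples its own biased ensemble rather than a
    transient from a fixed start — the working assumption of the
    importance-sampling reweighting.
    """

    def __init__(self, potential, params, x0=None, warm_restart: bool = True):
        self.potential = potential
        self.params = params
        self.x0 = x0
        self.warm_restart = warm_restart
        self._last_coords: np.ndarray | None = None

    def sample(self, biases: list, n_replicas: int, seed: int) -> list[OPTrajectory]:
        from .toy_md import simulate_ensemble
        params = replace(self.params, seed=seed)
        bias_arg = [(g, rc) for g, rc in biases] if biases else None
        x0 = self.x0
        if self.warm_restart and self._last_coords is not None \
                and self._last_coords.shape[0] == n_replicas:
            x0 = self._last_coords
        trajs = simulate_ensemble(self.potential, params, n_replicas,
                                  bias=bias_arg, x0=x0)
        self._last_coords = np.array([t.final_coords for t in trajs])
        return trajs


class FileSampler:
    """File-handoff sampler for external MD engines.

    ``sample`` writes the bias grid(s) and a PLUMED input snippet into the
    round directory and then ingests COLVAR files the external engine must
    have produced there (``replica_<i>.colvar`` with a bias column).  The
    sampler never launches MD itself.
    """

    def __init__(self, workdir: str, bias_column: str = "bias", beta: float = 1.0):
        self.workdir = workdir
        self.bias_column = bias_column
        self.beta = beta
        self._round = 0

    def sample(self, biases: list, n_replicas: int, seed: int) -> list[OPTrajectory]:
        rdir = os.path.join(self.workdir, f"round_{self._round}")
        os.makedirs(rdir, exist_ok=True)
        for i, (grid, rc) in enumerate(biases, start=1):
            grid.write(os.path.join(rdir, f"bias{i}.grid"))
            with open(os.path.join(rdir, f"plumed{i}.dat"), "w") as fh:
                fh.write(plumed_snippet(rc, grid, f"chi{i}"))
        trajs = []
        for i in range(n_replicas):
            path = os.path.join(rdir, f"replica_{i}.colvar")
            if not os.path.exists(path):
                raise FileNotFoundError(
                    f"expected external MD output {path}; run the engine with "
                    "the emitted bias grid and PLUMED snippet, then resume")
            trajs.append(read_colvar(path, bias_column_name=self.bias_column,
                                     beta=self.beta))
        self._round += 1
        return trajs


def plumed_snippet(rc: ReactionCoordinate, grid: BiasGrid, label: str = "chi") -> str:
    """A PLUMED input fragment declaring the linear RC and its external bias.

    The COMBINE coefficients fold the z-score transform into raw-coordinate
    space: chi = sum_i (c_i / scale_i) s_i - sum_i c_i shift_i / scale_i.
    """
    coeffs = rc.weights / rc.standardization.scale
    const = float(np.sum(rc.weights * rc.standardization.shift
                         / rc.standardization.scale))
    args = ",".join(rc.op_names)
    co = ",".join(format(c, ".12g") for c in coeffs)
    lines = [
        f"{label}_lin: COMBINE ARG={args} COEFFICIENTS={co} PERIODIC=NO",
        f"{label}: CUSTOM ARG={label}_lin FUNC=x-({const:.12g}) PERIODIC=NO",
        f"ext_{label}: EXTERNAL ARG={label} FILE=bias_{label}.grid",
    ]
    return "\n".join(lines) + "\n"


def select_training_trajectory(replicas: list[OPTrajectory]) -> int:
    """Index of the replica with maximum ergodic exploration.

    Variance is summed over order parameters after z-scoring each by the
    statistics of the pooled replicas; ties break to the lowest index.
    """
    if not replicas:
        raise ValueError("need at least one replica")
    pooled = np.vstack([t.values for t in replicas])
    std = Standardization.from_data(pooled, names=replicas[0].names)
    scores = np.array([std.apply(t.values).var(axis=0).sum() for t in replicas])
    return int(np.argmax(scores))


def _orthogonalize(rc2: ReactionCoordinate, rc1: ReactionCoordinate
                   ) -> ReactionCoordinate:
    c = rc2.weights - (rc2.weights @ rc1.weights) * rc1.weights
    n = np.linalg.norm(c)
    if n < 1e-12:
        raise ValueError("second coordinate is parallel to the first")
    c = c / n
    if c[np.argmax(np.abs(c))] < 0:
        c = -c
    return ReactionCoordinate(weights=c, op_names=rc2.op_names,
                              standardization=rc2.standardization, loss=rc2.loss)


def check_convergence(prev: RoundState, new: RoundState,
                      angle_tol_deg: float = CONV_ANGLE_DEG,
                      f_tol: float = CONV_F_SUP) -> bool:
    """Converged when consecutive RCs agree within ``angle_tol_deg`` and the
    free-energy profiles within ``f_tol`` sup-norm (common support)."""
    rc_a = prev.rc1 if new.stage == 1 else prev.rc2
    rc_b = new.rc1 if new.stage == 1 else new.rc2
    pr_a = prev.profile1 if new.stage == 1 else prev.profile2
    pr_b = new.profile1 if new.stage == 1 else new.profile2
    if rc_a is None or rc_b is None or pr_a is None or pr_b is None:
        return False
    cosang = abs(float(rc_a.weights @ rc_b.weights))
    if 1.0 - cosang >= 1.0 - math.cos(math.radians(angle_tol_deg)):
        return False
    lo = max(pr_a.grid.grid_min, pr_b.grid.grid_min)
    hi = min(pr_a.grid.grid_max, pr_b.grid.grid_max)
    if hi <= lo:
        return False
    x = np.linspace(lo, hi, 200)
    fa = np.interp(x, pr_a.centers, pr_a.f)
    fb = np.interp(x, pr_b.centers, pr_b.f)
    return bool(np.max(np.abs(fa - fb)) < f_tol)


def _saturation(prev: RoundState, new: RoundState) -> bool:
    """Bias saturates when the wells are filled: the bias maximum no longer
    tracks the growing cap (the added delta_V headroom stays unused) and
    sampling visits no new bins."""
    if prev.bias1 is None or new.bias1 is None:
        return False
    dmax = float(new.bias1.values.max() - prev.bias1.values.max())
    headroom_unused = dmax < 0.25 * new.bias1.delta_v
    no_new_bins = new.coverage <= math.ceil(1.02 * prev.coverage)
    return headroom_unused and no_new_bins


def run_round(state: RoundState, sampler, hp: PIBHyperparams, delta_v: float,
              lag_k: int, n_replicas: int = N_REPLICAS_DEFAULT,
              nbins: int = 100, min_barrier: float = 2.0,
              ts_margin: float = 1.0, smoothing_sigma: float = 1.0
              ) -> RoundState:
    """Execute one sample--learn--bias iteration and return the next state."""
    biases = state.applied_biases()
    round_seed = (state.seed + 7919 * (state.round_index + 1)) % (2**31)
    trajs = sampler.sample(biases, n_replicas, round_seed)
    if biases:
        for t in trajs:
            if t.bias is None:
                raise ValueError(
                    "sampler returned a trajectory without a bias column in a "
                    "biased round")
    train_idx = select_training_trajectory(trajs)
    train_traj = trajs[train_idx]
    pooled = np.vstack([t.values for t in trajs])
    beta = trajs[0].beta

    stage = state.stage
    if stage == 1:
        weights = None  # full exp(beta V_total) from the trajectory
        res = PredictiveBottleneck(train_traj, lag_k, hp, weights=weights).fit()
        rc1 = res.rc
        chi_pool = rc1.project_values(pooled)
        if biases:
            v_pool = np.concatenate([t.bias for t in trajs])
        else:
            v_pool = None
        prof = estimate_density(chi_pool, v_pool, beta=beta,
                                grid_spec=(chi_pool.min() - 1e-9,
                                           chi_pool.max() + 1e-9, nbins),
                                smoothing_sigma=smoothing_sigma)
        ts = identify_transition_states(prof, min_barrier, ts_margin)
        bias1 = build_bias(prof, prev=state.bias1, delta_v=delta_v,
                           ts_regions=ts, round_index=state.round_index + 1)
        counts, _ = np.histogram(chi_pool, bins=prof.grid.edges)
        new = replace(state,
                      round_index=state.round_index + 1,
                      rc1=rc1, bias1=bias1, trajectories=trajs,
                      profile1=prof,
                      bias_integral=float(np.trapezoid(bias1.values,
                                                       bias1.centers)),
                      coverage=int(np.count_nonzero(counts)))
        new.converged = check_convergence(state, new)
        new.saturated = state.saturated or _saturation(state, new)
        return new

    # stage 2: washing-out — chi1 and V1 fixed, weights from V2 only
    if state.rc1 is None or state.bias1 is None:
        raise ValueError("stage 2 requires a trained first coordinate and bias")
    if state.rc2 is not None and state.bias2 is not None:
        chi2_train = state.rc2.project_values(train_traj.values)
        v2_train = state.bias2.value(chi2_train)
        w_train = np.exp(beta * (v2_train - v2_train.max()))
    else:
        w_train = np.ones(train_traj.n_frames)
    res = PredictiveBottleneck(train_traj, lag_k, hp, weights=w_train,
                               fixed_rc=state.rc1).fit()
    rc2 = _orthogonalize(res.rc, state.rc1)
    chi2_pool = rc2.project_values(pooled)
    if state.bias2 is not None:
        v2_pool = np.concatenate([
            state.bias2.value(rc2.project_values(t.values)) for t in trajs])
    else:
        v2_pool = None
    prof2 = estimate_density(chi2_pool, v2_pool, beta=beta,
                             grid_spec=(chi2_pool.min() - 1e-9,
                                        chi2_pool.max() + 1e-9, nbins),
                             smoothing_sigma=smoothing_sigma)
    ts2 = identify_transition_states(prof2, min_barrier, ts_margin)
    bias2 = build_bias(prof2, prev=state.bias2, delta_v=delta_v,
                       ts_regions=ts2, round_index=state.round_index + 1)
    new = replace(state,
                  round_index=state.round_index + 1,
                  rc2=rc2, bias2=bias2, trajectories=trajs, profile2=prof2)
    new.converged = check_convergence(state, new)
    return new


def start_second_rc(state: RoundState) -> RoundState:
    """Enter the washing-out stage; valid only after stage-1 saturation."""
    if not state.saturated:
        raise ValueError("second coordinate requires a saturated first-stage bias")
    return replace(state, stage=2, converged=False)


class PIBProtocol:
    """Driver for the full loop against a pluggable sampler.

    Parameters mirror :func:`run_round`; ``run`` iterates until convergence
    or ``max_rounds``, switching to the second coordinate automatically when
    the first-stage bias saturates (if ``two_stage``).
    """

    def __init__(self, sampler, hp: PIBHyperparams, delta_v: float, lag_k: int,
                 n_replicas: int = N_REPLICAS_DEFAULT, seed: int = 0,
                 two_stage: bool = False, **round_kwargs):
        self.sampler = sampler
        self.hp = hp
        self.delta_v = delta_v
        self.lag_k = lag_k
        self.n_replicas = n_replicas
        self.two_stage = two_stage
        self.round_kwargs = round_kwargs
        self.states: list[RoundState] = [RoundState(seed=seed)]

    @property
    def state(self) -> RoundState:
        return self.states[-1]

    def step(self) -> RoundState:
        new = run_round(self.state, self.sampler, self.hp, self.delta_v,
                        self.lag_k, self.n_replicas, **self.round_kwargs)
        if self.two_stage and new.stage == 1 and new.saturated:
            new = start_second_rc(new)
        self.states.append(new)
        return new

    def run(self, max_rounds: int = 10) -> RoundState:
        for _ in range(max_rounds):
            new = self.step()
            if new.converged and not (self.two_stage and new.stage == 1):
                break
        return self.state


# ---------------------------------------------------------------------------
# round-directory serialization


def _rc_to_dict(rc: ReactionCoordinate) -> dict:
    return {"weights": rc.weights.tolist(), "op_names": rc.op_names,
            "shift": rc.standardization.shift.tolist(),
            "scale": rc.standardization.scale.tolist(),
            "loss": None if math.isnan(rc.loss) else rc.loss}


def _rc_from_dict(d: dict) -> ReactionCoordinate:
    return ReactionCoordinate(
        weights=np.array(d["weights"]), op_names=list(d["op_names"]),
        standardization=Standardization(np.array(d["shift"]),
                                        np.array(d["scale"])),
        loss=math.nan if d["loss"] is None else d["loss"])


def save_round(state: RoundState, directory: str) -> None:
    """Serialize a round to ``directory`` (text files only)."""
    os.makedirs(directory, exist_ok=True)
    meta = {"round_index": state.round_index, "stage": state.stage,
            "converged": state.converged, "saturated": state.saturated,
            "seed": state.seed, "bias_integral": state.bias_integral,
            "coverage": state.coverage,
            "n_replicas": len(state.trajectories)}
    for tag, rc, bias, prof in (("1", state.rc1, state.bias1, state.profile1),
                                ("2", state.rc2, state.bias2, state.profile2)):
        if rc is not None:
            meta[f"rc{tag}"] = _rc_to_dict(rc)
        if bias is not None:
            bias.write(os.path.join(directory, f"bias{tag}.grid"))
            meta[f"bias{tag}"] = {"cap": bias.cap, "delta_v": bias.delta_v,
                                  "ts_regions": bias.ts_regions,
                                  "round_index": bias.round_index}
        if prof is not None:
            write_plumed_grid(prof.grid, np.zeros(prof.grid.nbins),
                              os.path.join(directory, f"profile{tag}.grid"))
            meta[f"profile{tag}"] = {"beta": prof.beta,
                                     "n_effective": prof.n_effective,
                                     "f": prof.f.tolist()}
    for i, traj in enumerate(state.trajectories):
        write_colvar(traj, os.path.join(directory, f"replica_{i}.colvar"))
        meta.setdefault("beta", traj.beta)
        meta.setdefault("has_bias", traj.bias is not None)
        meta.setdefault("bias_name", traj.bias_name)
    with open(os.path.join(directory, "state.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_round(directory: str) -> RoundState:
    """Reload a round saved by :func:`save_round`."""
    with open(os.path.join(directory, "state.json")) as fh:
        meta = json.load(fh)
    state = RoundState(round_index=meta["round_index"], stage=meta["stage"],
                       converged=meta["converged"], saturated=meta["saturated"],
                       seed=meta["seed"],
                       bias_integral=meta.get("bias_integral", math.nan),
                       coverage=meta.get("coverage", 0))
    for tag in ("1", "2"):
        if f"rc{tag}" in meta:
            setattr(state, f"rc{tag}", _rc_from_dict(meta[f"rc{tag}"]))
        if f"bias{tag}" in meta:
            grid, der = read_plumed_grid(os.path.join(directory,
                                                      f"bias{tag}.grid"))
            b = meta[f"bias{tag}"]
            setattr(state, f"bias{tag}",
                    BiasGrid(grid=grid, cap=b["cap"], delta_v=b["delta_v"],
                             ts_regions=[tuple(r) for r in b["ts_regions"]],
                             round_index=b["round_index"], derivative=der))
        if f"profile{tag}" in meta:
            grid, _ = read_plumed_grid(os.path.join(directory,
                                                    f"profile{tag}.grid"))
            p = meta[f"profile{tag}"]
            setattr(state, f"profile{tag}",
                    FreeEnergyProfile(grid=grid, f=np.array(p["f"]),
                                      beta=p["beta"],
                                      n_effective=p["n_effective"]))
    trajs = []
    for i in range(meta.get("n_replicas", 0)):
        path = os.path.join(directory, f"replica_{i}.colvar")
        trajs.append(read_colvar(
            path,
            bias_column_name=meta["bias_name"] if meta.get("has_bias") else None,
            beta=meta.get("beta", 1.0)))
    state.trajectories = trajs
    return state
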