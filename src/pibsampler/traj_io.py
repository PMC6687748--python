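"""Order-parameter time series and grid functions in PLUMED-compatible text dialects.

The COLVAR dialect: the first non-blank line is ``#! FIELDS time <name> ...``,
every later line starting with ``#`` is a comment, data rows are whitespace
separated floats (scientific notation accepted), and the first column is
always time.  Grid files follow the PLUMED EXTERNAL convention with
``#! SET`` header lines and bin-centered rows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "OPTrajectory",
    "GridFunction",
    "ColvarFormatError",
    "StrideError",
    "read_colvar",
    "write_colvar",
    "write_plumed_grid",
    "read_plumed_grid",
]

_STRIDE_RTOL = 1e-9


class ColvarFormatError(ValueError):
    """Raised on malformed COLVAR / grid text input."""


class StrideError(ValueError):
    """Raised when time stamps are not uniformly strided."""


@dataclass
class OPTrajectory:
    """A time series of d order parameters with optional per-frame bias energy.

    Parameters
    ----------
    times : (M,) array
        Uniformly strided time stamps (MD time units).
    values : (M, d) array
        Order-parameter values s_1 ... s_d per frame.
    names : list of str
        d order-parameter labels.
    bias : (M,) array, optional
        Per-frame bias energy V^n in units of 1/beta (or the declared unit).
    beta : float
        Inverse temperature 1/(k_B T); stored so reweighting is unit-safe.
    """

    times: np.ndarray
    values: np.ndarray
    names: list[str]
    bias: np.ndarray | None = None
    beta: float = 1.0
    bias_name: str = "bias"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values disagree on frame count")
        if self.n_frames < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.n_ops < 1 or len(self.names) != self.n_ops:
            raise ValueError("names must label every order-parameter column")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise StrideError("time stamps must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=_STRIDE_RTOL, atol=_STRIDE_RTOL * max(abs(dt[0]), 1.0)):
            raise StrideError("time stamps are not uniformly strided")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (self.n_frames,):
                raise ValueError("bias must have exactly one entry per frame")
            if not np.all(np.isfinite(self.bias)):
                raise ValueError("bias energies must be finite")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_ops(self) -> int:
        return self.values.shape[1]

    @property
    def stride(self) -> float:
        """Time between consecutive frames."""
        return float(self.times[1] - self.times[0])

    def importance_weights(self) -> np.ndarray:
        """Per-frame reweighting factors w^n = exp(beta * V^n).

        Returns uniform weights when the trajectory carries no bias.  An
        overall constant in V cancels on normalization; the maximum is
        subtracted before exponentiation for numerical safety.
        """
        if self.bias is None:
            return np.ones(self.n_frames)
        v = self.beta * self.bias
        return np.exp(v - v.max())

    def with_bias(self, bias: np.ndarray, name: str = "bias") -> "OPTrajectory":
        return replace(self, bias=np.asarray(bias, dtype=float), bias_name=name)


@dataclass
class GridFunction:
    """A scalar function tabulated on a uniform, bin-centered 1D grid."""

    name: str
    grid_min: float
    grid_max: float
    nbins: int
    values: np.ndarray
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be below grid_max")
        if self.nbins < 2:
            raise ValueError("a grid needs at least 2 bins")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nbins,):
            raise ValueError("values must hold one entry per bin")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def binwidth(self) -> float:
        return (self.grid_max - self.grid_min) / self.nbins

    @property
    def centers(self) -> np.ndarray:
        return self.grid_min + (np.arange(self.nbins) + 0.5) * self.binwidth

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.nbins + 1)

    def interpolate(self, x: np.ndarray) -> np.ndarray:
        """Linear interpolation between bin centers, constant beyond them."""
        return np.interp(np.asarray(x, dtype=float), self.centers, self.values)


def read_colvar(path, bias_column_name: str | None = None, beta: float = 1.0) -> OPTrajectory:
    """Read a COLVAR-style file into an :class:`OPTrajectory`.

    Parameters
    ----------
    path : str or file-like
        File with a ``#! FIELDS time <name>...`` header.
    bias_column_name : str, optional
        Column to strip out of the order parameters and store as per-frame
        bias energy.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.splitlines()
    header = None
    for line in lines:
        if line.strip():
            header = line
            break
    if header is None or not header.startswith("#!"):
        raise ColvarFormatError("missing '#! FIELDS' header line")
    tokens = header.split()
    if len(tokens) < 4 or tokens[:2] != ["#!", "FIELDS"] or tokens[2] != "time":
        raise ColvarFormatError("header must read '#! FIELDS time <name>...'")
    names = tokens[3:]

    data_lines = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    try:
        data = np.loadtxt(io.StringIO("\n".join(data_lines)), ndmin=2)
    except ValueError as exc:
        raise ColvarFormatError(f"could not parse numeric rows: {exc}") from exc
    if data.shape[1] != len(names) + 1:
        raise ColvarFormatError(
            f"rows have {data.shape[1]} columns but header declares {len(names) + 1}"
        )
    times = data[:, 0]
    values = data[:, 1:]
    bias = None
    bias_name = "bias"
    if bias_column_name is not None:
        if bias_column_name not in names:
            raise ColvarFormatError(f"no column named {bias_column_name!r} in header")
        j = names.index(bias_column_name)
        bias = values[:, j]
        values = np.delete(values, j, axis=1)
        names = [n for n in names if n != bias_column_name]
        bias_name = bias_column_name
    return OPTrajectory(times=times, values=values, names=list(names), bias=bias,
                        beta=beta, bias_name=bias_name)


def write_colvar(traj: OPTrajectory, path) -> None:
    """Write a trajectory in the COLVAR dialect at full float precision."""
    names = list(traj.names)
    cols = [traj.times] + [traj.values[:, j] for j in range(traj.n_ops)]
    if traj.bias is not None:
        names.append(traj.bias_name)
        cols.append(traj.bias)
    header = "#! FIELDS time " + " ".join(names)
    body = np.column_stack(cols)
    rows = "\n".join(" ".join(format(v, ".17g") for v in row) for row in body)
    text = header + "\n" + rows + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def write_plumed_grid(grid: GridFunction, derivative: np.ndarray, path) -> None:
    """Write a PLUMED EXTERNAL-style grid file (bias + derivative columns)."""
    derivative = np.asarray(derivative, dtype=float)
    if derivative.shape != (grid.nbins,):
        raise ValueError("derivative must have one entry per bin")
    name = grid.name
    lines = [
        f"#! FIELDS {name} external.bias der_{name}",
        f"#! SET min_{name} {grid.grid_min:.17g}",
        f"#! SET max_{name} {grid.grid_max:.17g}",
        f"#! SET nbins_{name} {grid.nbins}",
        f"#! SET periodic_{name} {'true' if grid.periodic else 'false'}",
    ]
    for x, v, d in zip(grid.centers, grid.values, derivative):
        lines.append(f"{x:.17g} {v:.17g} {d:.17g}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_plumed_grid(path) -> tuple[GridFunction, np.ndarray]:
    """Read a grid file written by :func:`write_plumed_grid`.

    Returns the grid function and the derivative column.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    meta: dict[str, str] = {}
    name = None
    rows = []
    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.startswith("#!"):
            toks = s.split()
            if toks[1] == "FIELDS":
                name = toks[2]
            elif toks[1] == "SET":
                meta[toks[2]] = toks[3]
        else:
            rows.append([float(t) for t in s.split()])
    if name is None:
        raise ColvarFormatError("grid file lacks a FIELDS header")
    data = np.asarray(rows)
    grid = GridFunction(
        name=name,
        grid_min=float(meta[f"min_{name}"]),
        grid_max=float(meta[f"max_{name}"]),
        nbins=int(meta[f"nbins_{name}"]),
        values=data[:, 1],
        periodic=meta.get(f"periodic_{name}", "false") == "true",
    )
    return grid, data[:, 2]
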