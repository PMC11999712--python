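"""Discrete fields: space x state population density and the food field.

The layout is cell-centred finite volume in both space and state, so
every density value is a cell average and mass bookkeeping (marginals,
totals, moments) reduces to midpoint-rule quadrature that is exact for
the scheme's own representation.

A population field always carries two state axes, gregarisation ``ng``
and hunger-satiation ``nh``, in that order.  A state dimension may be
*frozen*: a single cell pinned at a point value with unit quadrature
weight, which encodes runs where that coordinate is held fixed (for
example the hunger-free experiments, where every locust sits at
``nh = 0.5``) without a separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "SpatialGrid",
    "StateDim",
    "StateGrid",
    "PopulationField",
    "FoodField",
    "marginal_density",
    "total_mass",
    "state_moments",
    "StateMoments",
    "support_width",
    "save_fields",
    "load_fields",
]


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform periodic grid on ``[0, L)`` with ``nx`` cells."""

    L: float
    nx: int
    periodic: bool = True

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("domain length L must be positive")
        if self.nx < 8:
            raise ValueError("need at least 8 spatial cells")

    @property
    def dx(self) -> float:
        return self.L / self.nx

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx


@dataclass(frozen=True)
class StateDim:
    """One internal-state axis on [0, 1].

    Active dims partition [0, 1] into ``n`` equal cells of width
    ``1/n``.  A frozen dim has a single cell holding a point state with
    quadrature weight 1, so marginalisation is a no-op for it.
    """

    name: str
    n: int = 24
    frozen: bool = False
    value: float | None = None

    def __post_init__(self):
        if self.frozen:
            if self.n != 1 or self.value is None:
                raise ValueError("a frozen dim has n=1 and a point value")
            if not 0.0 <= self.value <= 1.0:
                raise ValueError("point state must lie in [0, 1]")
        elif self.n < 2:
            raise ValueError("an active state dim needs at least 2 cells")

    @classmethod
    def fixed(cls, name: str, value: float) -> "StateDim":
        return cls(name=name, n=1, frozen=True, value=value)

    @property
    def width(self) -> float:
        """Quadrature weight of one cell (1 for a frozen dim)."""
        return 1.0 if self.frozen else 1.0 / self.n

    @property
    def centers(self) -> np.ndarray:
        if self.frozen:
            return np.array([self.value])
        return (np.arange(self.n) + 0.5) / self.n

    @property
    def faces(self) -> np.ndarray:
        """Interior cell faces (empty for a frozen dim)."""
        if self.frozen:
            return np.empty(0)
        return np.arange(1, self.n) / self.n


@dataclass(frozen=True)
class StateGrid:
    """Product grid over the gregarisation and hunger axes."""

    ng: StateDim
    nh: StateDim

    def __post_init__(self):
        if self.ng.name != "ng" or self.nh.name != "nh":
            raise ValueError("state dims must be named 'ng' and 'nh', in that order")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ng.n, self.nh.n)

    @property
    def cell_volume(self) -> float:
        return self.ng.width * self.nh.width

    def dim(self, name: str) -> StateDim:
        if name == "ng":
            return self.ng
        if name == "nh":
            return self.nh
        raise KeyError(name)


def _check_values(values, shape, name):
    values = np.asarray(values, dtype=float)
    if values.shape != shape:
        raise ValueError(f"{name} values have shape {values.shape}, expected {shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} values must be finite")
    return values


@dataclass
class PopulationField:
    """Density rho(x, ng, nh) in locusts per metre per unit state volume."""

    grid: SpatialGrid
    states: StateGrid
    values: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        shape = (self.grid.nx,) + self.states.shape
        self.values = _check_values(self.values, shape, "population")

    def copy(self) -> "PopulationField":
        return PopulationField(self.grid, self.states, self.values.copy(), self.t)


@dataclass
class FoodField:
    """Food density c(x) in food mass per metre."""

    grid: SpatialGrid
    values: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.values = _check_values(self.values, (self.grid.nx,), "food")

    def copy(self) -> "FoodField":
        return FoodField(self.grid, self.values.copy(), self.t)

    @classmethod
    def zeros(cls, grid: SpatialGrid, t: float = 0.0) -> "FoodField":
        return cls(grid, np.zeros(grid.nx), t)


def marginal_density(rho: PopulationField) -> np.ndarray:
    """Total local density rho_bar(x): the density summed over all states."""
    return rho.values.sum(axis=(1, 2)) * rho.states.cell_volume


def total_mass(rho: PopulationField) -> float:
    """Total number of locusts, by midpoint quadrature over space and state."""
    return float(marginal_density(rho).sum() * rho.grid.dx)


@dataclass(frozen=True)
class StateMoments:
    """Per-location and global first moments of the state coordinates.

    Per-location means are NaN wherever the local density vanishes.
    """

    mean_ng: np.ndarray
    mean_nh: np.ndarray
    global_ng: float
    global_nh: float


def state_moments(rho: PopulationField, empty_tol: float = 0.0) -> StateMoments:
    """Density-weighted mean gregarisation and satiation.

    ``empty_tol`` sets the local density (relative to the spatial
    maximum) below which the per-location mean is flagged undefined.
    """
    sg = rho.states
    dvol = sg.cell_volume
    rho_bar = marginal_density(rho)
    mass = rho_bar.sum() * rho.grid.dx
    if mass <= 0:
        raise ValueError("state moments of a zero-mass field are undefined")
    cutoff = max(empty_tol * rho_bar.max(), 0.0)

    means = []
    globals_ = []
    for axis, dim in ((1, sg.ng), (2, sg.nh)):
        other = 2 if axis == 1 else 1
        # first moment of the state coordinate at each x
        m1 = np.tensordot(rho.values.sum(axis=other), dim.centers, axes=([1], [0])) * dvol
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_x = np.where(rho_bar > cutoff, m1 / rho_bar, np.nan)
        means.append(mean_x)
        globals_.append(float(m1.sum() * rho.grid.dx / mass))
    return StateMoments(means[0], means[1], globals_[0], globals_[1])


def support_width(rho_bar: np.ndarray, grid: SpatialGrid, fraction: float = 0.98) -> float:
    """Width of the smallest contiguous interval holding ``fraction`` of the mass.

    The interval grows outward from the cell of maximum density, one
    cell at a time toward whichever neighbour (periodically wrapped)
    carries more density, until the enclosed mass first reaches
    ``fraction`` of the total.  Deterministic by construction and
    monotone in ``fraction``.
    """
    rho_bar = np.asarray(rho_bar, dtype=float)
    if rho_bar.ndim != 1 or rho_bar.shape[0] != grid.nx:
        raise ValueError("rho_bar must be a 1-D spatial field on the grid")
    if np.any(rho_bar < 0):
        raise ValueError("rho_bar must be nonnegative")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    total = rho_bar.sum()
    if total <= 0:
        raise ValueError("support of a zero-mass field is undefined")
    target = fraction * total

    nx = grid.nx
    i0 = int(np.argmax(rho_bar))
    left, right = i0, i0  # inclusive interval in unwrapped indices
    acc = rho_bar[i0]
    while acc < target and (right - left + 1) < nx:
        cand_l = rho_bar[(left - 1) % nx]
        cand_r = rho_bar[(right + 1) % nx]
        if cand_l > cand_r:
            left -= 1
            acc += cand_l
        else:
            right += 1
            acc += cand_r
    return (right - left + 1) * grid.dx


# ---------------------------------------------------------------------------
# HDF5 container

def save_fields(path, rho: PopulationField, food: FoodField | None = None, attrs: dict | None = None):
    """Write the density (and optionally food) to an HDF5 container.

    Layout: datasets ``/rho`` (x, ng, nh), ``/food`` (x),
    ``/coords/{x,ng,nh}``, with time and state-grid metadata as root
    attributes.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("rho", data=rho.values)
        if food is not None:
            f.create_dataset("food", data=food.values)
        g = f.create_group("coords")
        g.create_dataset("x", data=rho.grid.centers)
        g.create_dataset("ng", data=rho.states.ng.centers)
        g.create_dataset("nh", data=rho.states.nh.centers)
        f.attrs["t"] = rho.t
        f.attrs["L"] = rho.grid.L
        f.attrs["nx"] = rho.grid.nx
        for dim in (rho.states.ng, rho.states.nh):
            f.attrs[f"{dim.name}_n"] = dim.n
            f.attrs[f"{dim.name}_frozen"] = dim.frozen
            if dim.frozen:
                f.attrs[f"{dim.name}_value"] = dim.value
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_fields(path) -> tuple[PopulationField, FoodField | None]:
    with h5py.File(path, "r") as f:
        grid = SpatialGrid(L=float(f.attrs["L"]), nx=int(f.attrs["nx"]))
        dims = {}
        for name in ("ng", "nh"):
            if bool(f.attrs[f"{name}_frozen"]):
                dims[name] = StateDim.fixed(name, float(f.attrs[f"{name}_value"]))
            else:
                dims[name] = StateDim(name, int(f.attrs[f"{name}_n"]))
        states = StateGrid(dims["ng"], dims["nh"])
        t = float(f.attrs["t"])
        rho = PopulationField(grid, states, f["rho"][...], t)
        food = FoodField(grid, f["food"][...], t) if "food" in f else None
    return rho, food
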