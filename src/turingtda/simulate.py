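"""Finite-difference method-of-lines integration of the reaction-diffusion
models on a rectangle with zero-flux (Neumann) boundaries.

The domain [0, Lx] x [0, Ly] is discretised on a closed vertex grid with
uniform stepsize; the Laplacian is the standard 5-point stencil with
mirrored ghost nodes (second-order Neumann).  Initial conditions are i.i.d.
Gaussian perturbations of the uniform steady state.  Two integrators are
available: an explicit adaptive embedded Runge-Kutta pair (Bogacki-
Shampine 3(2)) and a semi-implicit (IMEX) scheme with backward-Euler
diffusion and explicit reaction, which trades temporal order for an
unconditional diffusive stability limit.  Both detect numerical steady
states via the sup-norm of the time derivative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .kinetics import (
    ModelParams,
    enumerate_modes,
    kinetics_rhs,
    linearise,
    steady_state,
    turing_conditions,
    unstable_band,
)

__all__ = [
    "RectGrid",
    "Field",
    "SimConfig",
    "build_grid",
    "nyquist_stepsize",
    "random_ic",
    "neumann_laplacian",
    "integrate",
]


@dataclass(frozen=True)
class RectGrid:
    """Closed uniform vertex grid on [0, Lx] x [0, Ly].

    Vertices are ordered row-major with y as the outer index:
    ``index = iy * nx + ix``, vertex coordinates ``(ix * stepsize,
    iy * stepsize)``.
    """

    Lx: float
    Ly: float
    stepsize: float
    nx: int
    ny: int

    @property
    def n_vertices(self) -> int:
        return self.nx * self.ny

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (x, y) coordinate arrays in vertex order."""
        x = np.arange(self.nx) * self.stepsize
        y = np.arange(self.ny) * self.stepsize
        X, Y = np.meshgrid(x, y)  # shape (ny, nx)
        return X.ravel(), Y.ravel()


@dataclass
class Field:
    """Scalar concentration values at grid vertices for one species."""

    grid: RectGrid
    values: np.ndarray
    species: str = "u"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_vertices:
            raise ValueError("field length does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    def as_grid(self) -> np.ndarray:
        """Values reshaped to (ny, nx)."""
        return self.values.reshape(self.grid.ny, self.grid.nx)


@dataclass(frozen=True)
class SimConfig:
    """Integration controls.

    tau_end: final nondimensional time (patterns are sampled at 250).
    ic_sd: standard deviation of the Gaussian initial perturbation.
    steady_tol: sup-norm of the time derivative below which the state is
        declared (numerically) steady.
    method: "explicit" (adaptive RK 3(2)) or "imex" (fixed-step
        semi-implicit).
    dt: fixed step for the IMEX scheme.
    """

    tau_end: float = 250.0
    ic_sd: float = 0.1
    seed: int = 0
    steady_tol: float = 1e-5
    method: str = "explicit"
    dt: float = 0.01
    rtol: float = 1e-6
    atol: float = 1e-9
    check_every: int = 50

    def __post_init__(self) -> None:
        if self.tau_end <= 0:
            raise ValueError("tau_end must be positive")
        if self.method not in ("explicit", "imex"):
            raise ValueError(f"unknown method {self.method!r}")


def build_grid(Lx: float, Ly: float, stepsize: float) -> RectGrid:
    """Vertex grid covering the closed rectangle exactly.

    The stepsize must divide both side lengths (to within 1e-9 relative);
    no silent remeshing is performed.
    """
    if stepsize <= 0 or stepsize > min(Lx, Ly):
        raise ValueError("stepsize must satisfy 0 < stepsize <= min(Lx, Ly)")
    counts = []
    for L in (Lx, Ly):
        ratio = L / stepsize
        if abs(ratio - round(ratio)) > 1e-9 * max(ratio, 1.0):
            raise ValueError(
                f"stepsize {stepsize} does not divide side length {L}"
            )
        counts.append(int(round(ratio)) + 1)
    nx, ny = counts
    if nx < 2 or ny < 2:
        raise ValueError("grid must have at least 2 vertices per axis")
    return RectGrid(Lx=Lx, Ly=Ly, stepsize=stepsize, nx=nx, ny=ny)


def nyquist_stepsize(mode: tuple[int, int], Lx: float, Ly: float) -> float:
    """Upper bound on the grid stepsize: half the minimal wavelength of
    the given mode, with the per-axis cosine half-period (Lx/m, Ly/n) as
    the wavelength convention.  Zero indices impose no constraint."""
    m, n = mode
    if m == 0 and n == 0:
        raise ValueError("mode (0, 0) has no wavelength")
    lengths = []
    if m > 0:
        lengths.append(Lx / m)
    if n > 0:
        lengths.append(Ly / n)
    return 0.5 * min(lengths)


def random_ic(
    params: ModelParams,
    grid: RectGrid,
    sd: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Field, Field]:
    """Steady state plus i.i.d. Gaussian(0, sd^2) noise at every vertex.

    One seed per node; it is split deterministically into independent
    u and v streams.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    u_s, v_s = steady_state(params)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_u, ss_v = ss.spawn(2)
    n = grid.n_vertices
    u = u_s + np.random.default_rng(ss_u).normal(0.0, sd, n) if sd > 0 else np.full(n, u_s)
    v = v_s + np.random.default_rng(ss_v).normal(0.0, sd, n) if sd > 0 else np.full(n, v_s)
    return Field(grid, u, "u"), Field(grid, v, "v")


def _lap1d(n: int) -> sp.spmatrix:
    main = -2.0 * np.ones(n)
    lower = np.ones(n - 1)
    upper = np.ones(n - 1)
    upper[0] = 2.0  # mirrored ghost at the left boundary
    lower[-1] = 2.0  # mirrored ghost at the right boundary
    return sp.diags([lower, main, upper], [-1, 0, 1])


def neumann_laplacian(grid: RectGrid) -> sp.csr_matrix:
    """5-point Laplacian with mirrored ghost nodes, in vertex order."""
    Lx1 = _lap1d(grid.nx)
    Ly1 = _lap1d(grid.ny)
    L = sp.kron(sp.identity(grid.ny), Lx1) + sp.kron(Ly1, sp.identity(grid.nx))
    return (L / grid.stepsize ** 2).tocsr()


def _diffusivities(params: ModelParams) -> tuple[float, float]:
    lin = linearise(params)
    return lin.d_u, lin.d_v


def _check_nyquist(params: ModelParams, grid: RectGrid) -> None:
    try:
        lin = linearise(params)
        if not turing_conditions(lin).in_space:
            return
        band = unstable_band(lin)
        if band is None:
            return
        max_index = max(
            1, int(math.ceil(max(grid.Lx, grid.Ly) * math.sqrt(band[1]) / math.pi))
        )
        bounds = [
            nyquist_stepsize((r.m, r.n), grid.Lx, grid.Ly)
            for r in enumerate_modes(lin, grid.Lx, grid.Ly, max_index)
            if r.unstable
        ]
        if bounds and grid.stepsize > min(bounds):
            warnings.warn(
                f"stepsize {grid.stepsize} exceeds the Nyquist bound "
                f"{min(bounds):.4g} for the minimal unstable wavelength",
                stacklevel=3,
            )
    except ValueError:
        pass


def integrate(
    params: ModelParams,
    u0: Field,
    v0: Field,
    config: SimConfig,
    kinetics_enabled: bool = True,
) -> tuple[Field, Field, str]:
    """Evolve the model from (u0, v0) until a numerical steady state or
    tau_end.

    Returns (u, v, status) with status "steady" when the sup-norm of the
    time derivative fell below config.steady_tol, else
    "tau_end_reached".  The ``kinetics_enabled`` hook disables the
    reaction terms (pure Neumann diffusion), used for conservation
    checks.
    """
    if u0.grid != v0.grid:
        raise ValueError("u and v must share a grid")
    grid = u0.grid
    if kinetics_enabled:
        _check_nyquist(params, grid)
    lap = neumann_laplacian(grid)
    d_u, d_v = _diffusivities(params)
    n = grid.n_vertices

    def rhs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        du = d_u * (lap @ u)
        dv = d_v * (lap @ v)
        if kinetics_enabled:
            f, g = kinetics_rhs(u, v, params)
            du = du + f
            dv = dv + g
        return du, dv

    if config.method == "imex":
        u, v, status, t = _integrate_imex(rhs, lap, d_u, d_v, u0, v0, config, kinetics_enabled, params)
    else:
        u, v, status, t = _integrate_explicit(rhs, u0, v0, config, grid, max(d_u, d_v))
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise RuntimeError(f"solution blew up near tau = {t:.4g}")
    return (
        Field(grid, u, u0.species),
        Field(grid, v, v0.species),
        status,
    )


def _integrate_explicit(rhs, u0: Field, v0: Field, config: SimConfig, grid, dmax):
    """Adaptive Bogacki-Shampine 3(2) with FSAL and a diffusive CFL cap."""
    y_u = u0.values.copy()
    y_v = v0.values.copy()
    t = 0.0
    dt_cap = 0.3 * grid.stepsize ** 2 / dmax
    dt = min(dt_cap, config.tau_end / 10.0, 0.1)
    ku1, kv1 = rhs(y_u, y_v)
    if max(np.abs(ku1).max(), np.abs(kv1).max()) < config.steady_tol:
        return y_u, y_v, "steady", t
    while t < config.tau_end:
        dt = min(dt, config.tau_end - t, dt_cap)
        if dt < 1e-12:
            raise RuntimeError(f"stepsize underflow near tau = {t:.4g}")
        ku2, kv2 = rhs(y_u + 0.5 * dt * ku1, y_v + 0.5 * dt * kv1)
        ku3, kv3 = rhs(y_u + 0.75 * dt * ku2, y_v + 0.75 * dt * kv2)
        yu_new = y_u + dt * (2.0 * ku1 + 3.0 * ku2 + 4.0 * ku3) / 9.0
        yv_new = y_v + dt * (2.0 * kv1 + 3.0 * kv2 + 4.0 * kv3) / 9.0
        if not (np.all(np.isfinite(yu_new)) and np.all(np.isfinite(yv_new))):
            raise RuntimeError(f"solution blew up near tau = {t:.4g}")
        ku4, kv4 = rhs(yu_new, yv_new)
        err_u = dt * (-5.0 * ku1 / 72.0 + ku2 / 12.0 + ku3 / 9.0 - ku4 / 8.0)
        err_v = dt * (-5.0 * kv1 / 72.0 + kv2 / 12.0 + kv3 / 9.0 - kv4 / 8.0)
        scale_u = config.atol + config.rtol * np.maximum(np.abs(y_u), np.abs(yu_new))
        scale_v = config.atol + config.rtol * np.maximum(np.abs(y_v), np.abs(yv_new))
        errnorm = max(
            float(np.abs(err_u / scale_u).max()),
            float(np.abs(err_v / scale_v).max()),
        )
        if errnorm <= 1.0:
            t += dt
            y_u, y_v = yu_new, yv_new
            ku1, kv1 = ku4, kv4  # FSAL
            if max(np.abs(ku1).max(), np.abs(kv1).max()) < config.steady_tol:
                return y_u, y_v, "steady", t
        factor = 0.9 * (errnorm + 1e-16) ** (-1.0 / 3.0)
        dt *= min(5.0, max(0.2, factor))
    return y_u, y_v, "tau_end_reached", t


def _integrate_imex(rhs, lap, d_u, d_v, u0: Field, v0: Field, config: SimConfig, kinetics_enabled, params):
    """Backward-Euler diffusion + forward-Euler reaction at a fixed step."""
    dt = config.dt
    n = u0.values.size
    eye = sp.identity(n, format="csc")
    solve_u = splu((eye - dt * d_u * lap).tocsc()).solve
    solve_v = splu((eye - dt * d_v * lap).tocsc()).solve
    y_u = u0.values.copy()
    y_v = v0.values.copy()
    t = 0.0
    n_steps = int(math.ceil(config.tau_end / dt))
    for step in range(n_steps):
        if kinetics_enabled:
            f, g = kinetics_rhs(y_u, y_v, params)
            y_u = solve_u(y_u + dt * f)
            y_v = solve_v(y_v + dt * g)
        else:
            y_u = solve_u(y_u)
            y_v = solve_v(y_v)
        t += dt
        if (step + 1) % config.check_every == 0 or step == n_steps - 1:
            if not (np.all(np.isfinite(y_u)) and np.all(np.isfinite(y_v))):
                raise RuntimeError(f"solution blew up near tau = {t:.4g}")
            du, dv = rhs(y_u, y_v)
            if max(np.abs(du).max(), np.abs(dv).max()) < config.steady_tol:
                return y_u, y_v, "steady", t
    return y_u, y_v, "tau_end_reached", t
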