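"""Seeded generators of spot, stripe and labyrinth test fields.

Fields are built from the Neumann cosine eigenfunctions of the rectangle
(the linear modes of the reaction-diffusion problem), so their topological
content is known by construction: spots are a product mode
cos(m pi x / Lx) cos(n pi y / Ly), stripes a single-axis mode, and
labyrinths a seeded random superposition of modes with near-equal
wavenumber magnitude, mimicking the mode mixing of a degenerate linear
spectrum.  Each generated field carries a ground-truth feature count
measured directly on the grid, so persistence and clustering can be
validated without PDE runs.  These fixtures reproduce topology classes,
not PDE amplitude profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import label as cc_label

from .simulate import Field, RectGrid, nyquist_stepsize

__all__ = ["PatternKind", "PatternSpec", "make_pattern", "perturb"]


class PatternKind(str, Enum):
    SPOTS = "spots"
    STRIPES = "stripes"
    LABYRINTH = "labyrinth"


@dataclass(frozen=True)
class PatternSpec:
    """Specification of a synthetic pattern field.

    (m, n) are mode indices; for LABYRINTH they set the target wavenumber
    magnitude around which modes are mixed.
    """

    kind: PatternKind
    m: int
    n: int = 0
    amplitude: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    n_modes: int = 6

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _count_strict_minima(Z: np.ndarray, threshold: float) -> int:
    """Strict local minima (8-neighbourhood, boundary-aware) below the
    threshold, by direct grid search."""
    ny, nx = Z.shape
    count = 0
    for iy in range(ny):
        for ix in range(nx):
            z = Z[iy, ix]
            if z >= threshold:
                continue
            neighbourhood = Z[
                max(iy - 1, 0) : iy + 2, max(ix - 1, 0) : ix + 2
            ]
            if np.sum(neighbourhood < z) == 0 and np.sum(neighbourhood == z) == 1:
                count += 1
    return count


def _count_components_below(Z: np.ndarray, threshold: float) -> int:
    labeled, n = cc_label(Z < threshold)
    return int(n)


def make_pattern(
    spec: PatternSpec, grid: RectGrid
) -> tuple[Field, int | None]:
    """Generate a pattern field plus its ground-truth feature count.

    SPOTS: count of strict local minima below mid-range ((max+min)/2);
    STRIPES and LABYRINTH: count of connected components of the
    sub-mid-range set.  Counts are measured on the returned (possibly
    noisy) field by direct grid search, independent of any persistence
    computation.  Raises when the requested modes violate the grid's
    Nyquist bound.
    """
    X, Y = grid.coords()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.kind is PatternKind.SPOTS:
        if spec.m < 1 or spec.n < 1:
            raise ValueError("spots need both mode indices >= 1")
        _check_nyquist(spec.m, spec.n, grid)
        Z = np.cos(spec.m * np.pi * X / grid.Lx) * np.cos(
            spec.n * np.pi * Y / grid.Ly
        )
    elif spec.kind is PatternKind.STRIPES:
        if spec.m < 1:
            raise ValueError("stripes need a nonzero mode index")
        _check_nyquist(spec.m, 0, grid)
        Z = np.cos(spec.m * np.pi * X / grid.Lx)
    elif spec.kind is PatternKind.LABYRINTH:
        modes = _labyrinth_modes(spec, grid)
        weights = rng.normal(0.0, 1.0, len(modes))
        Z = np.zeros_like(X)
        for (m, n), w in zip(modes, weights):
            Z += w * np.cos(m * np.pi * X / grid.Lx) * np.cos(
                n * np.pi * Y / grid.Ly
            )
        Z /= max(np.abs(Z).max(), 1e-12)
    else:  # pragma: no cover
        raise ValueError(f"unknown kind {spec.kind}")
    values = spec.amplitude * Z
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, values.shape)
    fld = Field(grid, values, species="u")
    Zg = fld.as_grid()
    mid = 0.5 * (Zg.max() + Zg.min())
    if spec.kind is PatternKind.SPOTS:
        truth = _count_strict_minima(Zg, mid)
    else:
        truth = _count_components_below(Zg, mid)
    return fld, truth


def _check_nyquist(m: int, n: int, grid: RectGrid) -> None:
    bound = nyquist_stepsize((m, n), grid.Lx, grid.Ly)
    if grid.stepsize > bound:
        raise ValueError(
            f"mode ({m}, {n}) needs stepsize <= {bound:.4g}, got {grid.stepsize}"
        )


def _labyrinth_modes(spec: PatternSpec, grid: RectGrid) -> list[tuple[int, int]]:
    """Modes with k^2 magnitude near the target, widened until at least
    ``n_modes`` are available (ordered deterministically)."""
    target = spec.m ** 2 + spec.n ** 2
    if target == 0:
        raise ValueError("labyrinth needs a nonzero target mode magnitude")
    cap = int(math.ceil(math.sqrt(target))) + 3
    all_modes = [
        (m, n)
        for m in range(cap + 1)
        for n in range(cap + 1)
        if (m, n) != (0, 0)
    ]
    for tol in np.arange(0.05, 1.01, 0.05):
        modes = [
            (m, n)
            for (m, n) in all_modes
            if abs(m * m + n * n - target) <= tol * target
        ]
        if len(modes) >= spec.n_modes:
            break
    else:  # pragma: no cover
        raise ValueError("could not find enough near-resonant modes")
    for m, n in modes:
        _check_nyquist(max(m, 1), n, grid)
    return sorted(modes)


def perturb(field: Field, eps: float, seed: int = 0) -> Field:
    """Seeded perturbation with sup-norm difference at most eps
    (uniform noise in [-eps, eps] at every vertex)."""
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    if eps == 0:
        return Field(field.grid, field.values.copy(), field.species)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise = rng.uniform(-eps, eps, field.values.shape)
    return Field(field.grid, field.values + noise, field.species)
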