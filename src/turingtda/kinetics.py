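"""Kinetics, linear stability and weakly nonlinear analysis of two-species
Turing systems.

Two reaction-diffusion models are built in:

* **CIMA** (Lengyel-Epstein reduction of the chlorite-iodide-malonic acid
  reaction), nondimensionalised to

  .. math::
      u_\\tau = \\nabla^2 u + \\alpha - u - 4uv/(1+u^2), \\qquad
      v_\\tau = \\sigma\\left(\\delta \\nabla^2 v + \\beta u
                - \\beta u v / (1+u^2)\\right),

  with feed rate ``alpha``, kinetic rate ``beta``, diffusivity ratio
  ``delta`` and starch complexation factor ``sigma``.

* **Schnakenberg** (cross kinetics):

  .. math::
      u_\\tau = \\nabla^2 u + \\alpha - u + u^2 v, \\qquad
      v_\\tau = \\delta \\nabla^2 v + \\beta - u^2 v.

This module provides uniform steady states, Jacobians at the steady state,
the four Turing (diffusion-driven instability) conditions C1-C4, the
dispersion relation h(k^2) and growth rate lambda(k^2), enumeration of
Neumann cosine modes on a rectangle, the dominant linear mode, the scan for
the unstable mode with the smallest wavelength (which bounds the mesh
stepsize), and the Ermentrout weakly nonlinear stripe/spot criterion for the
CIMA kinetics with its critical feed-rate values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np

__all__ = [
    "Model",
    "ModelParams",
    "LinearisedSystem",
    "ModeRecord",
    "TuringConditions",
    "Classification",
    "ErmentroutResult",
    "register_model",
    "steady_state",
    "linearise",
    "turing_conditions",
    "dispersion",
    "unstable_band",
    "enumerate_modes",
    "dominant_mode",
    "max_unstable_wavenumber",
    "ermentrout",
    "critical_alphas",
]


class Model(str, Enum):
    CIMA = "cima"
    SCHNAKENBERG = "schnakenberg"


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional parameters of a registered model.

    ``sigma`` is only meaningful for CIMA; it must be left at 1 for
    Schnakenberg.
    """

    model: Model
    alpha: float
    beta: float
    delta: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.beta <= 0 or self.delta <= 0 or self.sigma <= 0:
            raise ValueError("beta, delta and sigma must be positive")
        if self.model is Model.SCHNAKENBERG and self.sigma != 1.0:
            raise ValueError("sigma is fixed at 1 for the Schnakenberg model")


@dataclass(frozen=True)
class LinearisedSystem:
    """Jacobian of the kinetics at the uniform steady state plus effective
    diffusivities.

    For CIMA the sigma prefactor of the v equation is folded into
    ``g_u``, ``g_v`` and ``d_v`` (so ``d_v = sigma * delta``); for
    Schnakenberg ``d_v = delta``.  ``d_u`` is 1 for both models.
    """

    f_u: float
    f_v: float
    g_u: float
    g_v: float
    d_u: float = 1.0
    d_v: float = 1.0

    def __post_init__(self) -> None:
        if self.d_u <= 0 or self.d_v <= 0:
            raise ValueError("diffusivities must be positive")


@dataclass(frozen=True)
class ModeRecord:
    """A Neumann cosine mode (m, n) on the rectangle with its wavenumber
    squared, dispersion value, growth rate and instability flag."""

    m: int
    n: int
    k2: float
    h_val: float
    lambda_val: float
    unstable: bool


@dataclass(frozen=True)
class TuringConditions:
    c1: bool
    c2: bool
    c3: bool
    c4: bool

    @property
    def in_space(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4


class Classification(str, Enum):
    STRIPES = "stripes"
    SPOTS = "spots"
    NEITHER = "neither"


@dataclass(frozen=True)
class ErmentroutResult:
    a: float
    b: float
    classification: Classification


# --------------------------------------------------------------------------
# model registry
# --------------------------------------------------------------------------

def _cima_kinetics(u, v, p: ModelParams):
    f = p.alpha - u - 4.0 * u * v / (1.0 + u * u)
    g = p.sigma * p.beta * (u - u * v / (1.0 + u * u))
    return f, g


def _cima_steady(p: ModelParams):
    return p.alpha / 5.0, 1.0 + p.alpha ** 2 / 25.0


def _cima_linearise(p: ModelParams) -> LinearisedSystem:
    # printed closed form: 1/(a^2+25) [[3a^2-125, -20a], [2a^2 b s, -5 a b s]]
    a, b, s = p.alpha, p.beta, p.sigma
    den = a * a + 25.0
    return LinearisedSystem(
        f_u=(3.0 * a * a - 125.0) / den,
        f_v=-20.0 * a / den,
        g_u=2.0 * a * a * b * s / den,
        g_v=-5.0 * a * b * s / den,
        d_u=1.0,
        d_v=s * p.delta,
    )


def _schnakenberg_kinetics(u, v, p: ModelParams):
    f = p.alpha - u + u * u * v
    g = p.beta - u * u * v
    return f, g


def _schnakenberg_steady(p: ModelParams):
    u = p.alpha + p.beta
    if u <= 0:
        raise ValueError("Schnakenberg steady state requires alpha + beta > 0")
    return u, p.beta / (u * u)


def _schnakenberg_linearise(p: ModelParams) -> LinearisedSystem:
    u, v = _schnakenberg_steady(p)
    return LinearisedSystem(
        f_u=-1.0 + 2.0 * u * v,
        f_v=u * u,
        g_u=-2.0 * u * v,
        g_v=-u * u,
        d_u=1.0,
        d_v=p.delta,
    )


@dataclass(frozen=True)
class _ModelDef:
    kinetics: Callable
    steady: Callable
    linearise: Callable


_REGISTRY: dict[Model, _ModelDef] = {
    Model.CIMA: _ModelDef(_cima_kinetics, _cima_steady, _cima_linearise),
    Model.SCHNAKENBERG: _ModelDef(
        _schnakenberg_kinetics, _schnakenberg_steady, _schnakenberg_linearise
    ),
}


def register_model(model: Model, kinetics, steady, linearise_fn) -> None:
    """Hook for registering additional two-species kinetics."""
    _REGISTRY[model] = _ModelDef(kinetics, steady, linearise_fn)


def kinetics_rhs(u, v, params: ModelParams):
    """Reaction terms (f, g) of the registered model, vectorised over u, v."""
    return _REGISTRY[params.model].kinetics(u, v, params)


# --------------------------------------------------------------------------
# steady state, Jacobian, Turing conditions
# --------------------------------------------------------------------------

def steady_state(params: ModelParams) -> tuple[float, float]:
    """Uniform steady state (u_s, v_s) of the kinetics.

    Raises if a component is negative (invalid parameters) or if the
    kinetics do not vanish at the returned point.
    """
    u_s, v_s = _REGISTRY[params.model].steady(params)
    if u_s < 0 or v_s < 0:
        raise ValueError(f"nonpositive steady state ({u_s}, {v_s})")
    f, g = kinetics_rhs(u_s, v_s, params)
    scale = max(abs(u_s), abs(v_s), 1.0)
    if max(abs(f), abs(g)) > 1e-12 * scale:
        raise ValueError("kinetics do not vanish at the computed steady state")
    return u_s, v_s


def linearise(params: ModelParams) -> LinearisedSystem:
    """Jacobian of the kinetics at the steady state with effective
    diffusivities (d_u, d_v)."""
    return _REGISTRY[params.model].linearise(params)


def turing_conditions(lin: LinearisedSystem) -> TuringConditions:
    """The four diffusion-driven instability conditions.

    C1: trace negative (steady state stable without diffusion).
    C2: determinant positive.
    C3: d_v f_u + d_u g_v > 0 (differential diffusion destabilises).
    C4: (d_v f_u + d_u g_v)^2 > 4 d_u d_v det (real band of unstable k^2).

    All inequalities are strict; points on the Hopf boundary
    (f_u + g_v = 0) are outside the Turing space.
    """
    det = lin.f_u * lin.g_v - lin.f_v * lin.g_u
    q = lin.d_v * lin.f_u + lin.d_u * lin.g_v
    return TuringConditions(
        c1=lin.f_u + lin.g_v < 0,
        c2=det > 0,
        c3=q > 0,
        c4=q * q - 4.0 * lin.d_u * lin.d_v * det > 0,
    )


def dispersion(lin: LinearisedSystem, k2: float) -> tuple[float, float]:
    """Dispersion pair (h(k^2), lambda(k^2)).

    h(k^2) = d_u d_v k^4 - (d_v f_u + d_u g_v) k^2 + det J is the
    determinant of the k^2-shifted Jacobian; lambda is the largest real
    part of its eigenvalues.  h(k^2) < 0 marks a linearly unstable
    wavenumber.
    """
    if k2 < 0:
        raise ValueError("k2 must be nonnegative")
    det = lin.f_u * lin.g_v - lin.f_v * lin.g_u
    h = (
        lin.d_u * lin.d_v * k2 * k2
        - (lin.d_v * lin.f_u + lin.d_u * lin.g_v) * k2
        + det
    )
    tr = lin.f_u + lin.g_v - (lin.d_u + lin.d_v) * k2
    disc = tr * tr - 4.0 * h
    if disc >= 0:
        lam = 0.5 * (tr + math.sqrt(disc))
    else:
        lam = 0.5 * tr
    return h, lam


def unstable_band(lin: LinearisedSystem) -> tuple[float, float] | None:
    """Roots (k^2_-, k^2_+) of h, or None when h has no positive real roots
    (no unstable band)."""
    det = lin.f_u * lin.g_v - lin.f_v * lin.g_u
    q = lin.d_v * lin.f_u + lin.d_u * lin.g_v
    a = lin.d_u * lin.d_v
    disc = q * q - 4.0 * a * det
    if disc <= 0 or q <= 0:
        return None
    s = math.sqrt(disc)
    return ((q - s) / (2.0 * a), (q + s) / (2.0 * a))


# --------------------------------------------------------------------------
# Neumann modes on the rectangle
# --------------------------------------------------------------------------

def _mode_k2(m: int, n: int, Lx: float, Ly: float) -> float:
    return math.pi ** 2 * (m * m / Lx ** 2 + n * n / Ly ** 2)


def enumerate_modes(
    lin: LinearisedSystem, Lx: float, Ly: float, max_index: int
) -> list[ModeRecord]:
    """All Neumann modes (m, n) with 0 <= m, n <= max_index, not both zero.

    (m, n) and (n, m) are distinct records.  A mode is unstable iff
    h(k^2) < 0 < lambda(k^2).  Raises if the enumerated range does not
    cover the unstable band (k^2_+ beyond the largest per-axis k^2), so
    instabilities can never be silently missed.
    """
    if max_index < 1:
        raise ValueError("max_index must be >= 1")
    band = unstable_band(lin)
    if band is not None and turing_conditions(lin).in_space:
        needed = max(Lx, Ly) * math.sqrt(band[1]) / math.pi
        if max_index < needed:
            raise ValueError(
                f"max_index={max_index} does not cover the unstable band; "
                f"need at least {math.ceil(needed)}"
            )
    records = []
    for m in range(max_index + 1):
        for n in range(max_index + 1):
            if m == 0 and n == 0:
                continue
            k2 = _mode_k2(m, n, Lx, Ly)
            h, lam = dispersion(lin, k2)
            records.append(
                ModeRecord(m, n, k2, h, lam, unstable=(h < 0 < lam))
            )
    return records


def dominant_mode(
    lin: LinearisedSystem, Lx: float, Ly: float, max_index: int
) -> tuple[int, int, float]:
    """Unstable mode with the largest growth rate, plus the percentage gap
    100 (lambda_1 - lambda_2) / lambda_1 between the two largest growth
    rates over *distinct* k^2 values (0 if only one unstable k^2).

    On a square domain (m, n) and (n, m) tie; the representative with
    m >= n is returned.
    """
    unstable = [r for r in enumerate_modes(lin, Lx, Ly, max_index) if r.unstable]
    if not unstable:
        raise ValueError("no unstable mode at these parameters")
    best = max(unstable, key=lambda r: (r.lambda_val, r.m >= r.n, r.m))
    lams = {}
    for r in unstable:
        key = round(r.k2, 12)
        lams[key] = max(lams.get(key, -math.inf), r.lambda_val)
    vals = sorted(lams.values(), reverse=True)
    gap = 0.0 if len(vals) < 2 else 100.0 * (vals[0] - vals[1]) / vals[0]
    return best.m, best.n, gap


# --------------------------------------------------------------------------
# vectorised Jacobians for parameter-space scans
# --------------------------------------------------------------------------

def _jacobian_arrays(model: Model, A, B, S, delta):
    """Broadcastable Jacobian entries and d_v over parameter arrays."""
    if model is Model.CIMA:
        den = A * A + 25.0
        fu = (3.0 * A * A - 125.0) / den
        fv = -20.0 * A / den
        gu = 2.0 * A * A * B * S / den
        gv = -5.0 * A * B * S / den
        dv = S * delta
    elif model is Model.SCHNAKENBERG:
        u = A + B
        fu = -1.0 + 2.0 * B / u
        fv = u * u
        gu = -2.0 * B / u
        gv = -u * u
        dv = np.broadcast_to(np.asarray(delta, dtype=float), fu.shape)
    else:  # pragma: no cover - registry models need their own scan support
        raise NotImplementedError(f"no vectorised Jacobian for {model}")
    return fu, fv, gu, gv, dv


def _band_arrays(model: Model, A, B, S, delta):
    """Feasibility mask and unstable band (k2-, k2+) over parameter arrays."""
    fu, fv, gu, gv, dv = _jacobian_arrays(model, A, B, S, delta)
    det = fu * gv - fv * gu
    q = dv * fu + gv
    disc = q * q - 4.0 * dv * det
    feasible = (fu + gv < 0) & (det > 0) & (q > 0) & (disc > 0)
    root = np.sqrt(np.where(disc > 0, disc, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k2m = (q - root) / (2.0 * dv)
        k2p = (q + root) / (2.0 * dv)
    return feasible, k2m, k2p


def max_unstable_wavenumber(
    model: Model,
    *,
    alpha_bounds: tuple[float, float],
    delta: float,
    Lx: float,
    Ly: float,
    sigma_bounds: tuple[float, float] = (1.0, 1.0),
    beta_bounds: tuple[float, float] | None = None,
    alpha_step: float = 0.1,
    sigma_step: float = 0.1,
    beta_step: float = 0.01,
    max_index: int = 12,
) -> tuple[int, int]:
    """Unstable mode with the smallest wavelength over a restricted Turing
    space.

    The wavelength that matters for meshing is the per-axis cosine
    half-period (Lx/m along x, Ly/n along y), so the scan maximises the
    per-axis resolution requirement max(m/Lx, n/Ly) over every unstable
    mode at every feasible (alpha, beta, sigma); ties are broken by
    smaller k^2, then by m >= n.  beta is scanned over its
    Turing-feasible range at each (alpha, sigma); by default the beta
    scan covers (0, 17], which contains the feasible range for the CIMA
    bounds alpha <= 20, delta = 1.5.
    """
    alphas = np.arange(alpha_bounds[0], alpha_bounds[1] + 1e-12, alpha_step)
    sigmas = np.arange(sigma_bounds[0], sigma_bounds[1] + 1e-12, sigma_step)
    if beta_bounds is None:
        beta_bounds = (beta_step, 17.0)
    betas = np.arange(beta_bounds[0], beta_bounds[1] + 1e-12, beta_step)
    if alphas.size == 0 or sigmas.size == 0 or betas.size == 0:
        raise ValueError("empty scan bounds")

    A = alphas[:, None, None]
    S = sigmas[None, :, None]

    # pass 1: global maximum of k^2_+ over the feasible set
    chunk = max(1, int(2e6 // (alphas.size * sigmas.size)) or 1)
    k2max = 0.0
    any_feasible = False
    for i in range(0, betas.size, chunk):
        Bc = betas[None, None, i : i + chunk]
        feas, _, k2p = _band_arrays(model, A, Bc, S, delta)
        if feas.any():
            any_feasible = True
            k2max = max(k2max, float(k2p[feas].max()))
    if not any_feasible:
        raise ValueError("no Turing-feasible point within the given bounds")

    m_cap = int(math.floor(Lx * math.sqrt(k2max) / math.pi))
    n_cap = int(math.floor(Ly * math.sqrt(k2max) / math.pi))
    if max_index < max(m_cap, n_cap):
        raise ValueError(
            f"max_index={max_index} does not cover the unstable band; "
            f"need at least {max(m_cap, n_cap)}"
        )
    candidates = [
        (m, n)
        for m in range(m_cap + 1)
        for n in range(n_cap + 1)
        if (m, n) != (0, 0) and _mode_k2(m, n, Lx, Ly) <= k2max
    ]
    # strictest per-axis requirement first; ties -> smaller k^2, then m >= n
    candidates.sort(
        key=lambda mn: (
            -max(mn[0] / Lx, mn[1] / Ly),
            _mode_k2(mn[0], mn[1], Lx, Ly),
            -mn[0],
        )
    )

    for m, n in candidates:
        K = _mode_k2(m, n, Lx, Ly)
        for i in range(0, betas.size, chunk):
            Bc = betas[None, None, i : i + chunk]
            feas, k2m, k2p = _band_arrays(model, A, Bc, S, delta)
            if bool((feas & (k2m < K) & (K < k2p)).any()):
                return m, n
    raise ValueError("no unstable mode found within the scanned bounds")


# --------------------------------------------------------------------------
# Ermentrout weakly nonlinear stripe/spot selection (CIMA)
# --------------------------------------------------------------------------

def ermentrout(params: ModelParams) -> ErmentroutResult:
    """Weakly nonlinear stripe/spot selection coefficients (a, b) for the
    CIMA kinetics on a small square with periodic boundaries.

    The stripe solution is stable iff b < a < 0; the spot solution is
    stable iff a < -|b| < 0.  The delta- and sigma-dependent prefactor is
    common to a and b, so the classification depends on alpha only.
    """
    if params.model is not Model.CIMA:
        raise ValueError("the stripe/spot criterion is implemented for CIMA")
    a2 = params.alpha ** 2
    denom1 = (a2 - 75.0) ** 2
    denom2 = a2 * (2.0 * params.delta * params.sigma - 3.0) + 225.0
    if denom1 < 1e-12 or abs(denom2) < 1e-12:
        raise ValueError("singular prefactor in the stripe/spot criterion")
    pref = 1875.0 * params.delta * params.sigma / (denom1 * denom2)
    a = pref * (28.0 * a2 ** 2 - 5175.0 * a2 - 39375.0) / (7.0 * a2 + 675.0)
    b = (
        pref
        * 3.0
        * (11.0 * a2 ** 3 - 875.0 * a2 ** 2 - 119375.0 * a2 + 234375.0)
        / ((a2 + 25.0) * (a2 + 525.0))
    )
    if b < a < 0:
        cls = Classification.STRIPES
    elif a < -abs(b) < 0:
        cls = Classification.SPOTS
    else:
        cls = Classification.NEITHER
    return ErmentroutResult(a=a, b=b, classification=cls)


def critical_alphas(
    delta: float,
    sigma: float,
    alpha_max: float = 20.0,
    scan_step: float = 0.01,
    tol: float = 1e-4,
) -> tuple[float, float, float]:
    """The three feed-rate values in (0, alpha_max) at which the
    stripe/spot classification changes, located by a dense scan followed
    by bisection to ``tol``.

    Because the delta/sigma prefactor is common to a and b, the triple is
    independent of (delta, sigma) wherever the prefactor is positive.
    """

    def cls(alpha: float) -> Classification:
        p = ModelParams(Model.CIMA, alpha=alpha, beta=1.0, delta=delta, sigma=sigma)
        return ermentrout(p).classification

    grid = np.arange(scan_step, alpha_max, scan_step)
    boundaries = []
    prev = cls(float(grid[0]))
    for alpha in grid[1:]:
        cur = cls(float(alpha))
        if cur != prev:
            lo, hi = float(alpha) - scan_step, float(alpha)
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if cls(mid) == prev:
                    lo = mid
                else:
                    hi = mid
            boundaries.append(0.5 * (lo + hi))
            prev = cur
    if len(boundaries) != 3:
        raise RuntimeError(
            f"expected 3 classification changes in (0, {alpha_max}), "
            f"found {len(boundaries)} at {boundaries}"
        )
    return tuple(boundaries)  # type: ignore[return-value]
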