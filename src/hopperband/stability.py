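"""Closed-form steady-state estimates and linear stability theory.

With food held constant in space and time and the whole population in a
single internal state, the spatial dynamics are a gradient flow whose
aggregate steady states admit closed-form estimates:

* large-mass limit: the aggregate is approximately rectangular with a
  mass-independent maximum density (the positive root of a quadratic in
  the force ratio ``F = fn/fl``) and support ``M / max density``;
* small-mass limit: Taylor-expanding the kernel and dropping linear
  diffusion gives cube-root scalings, density ~ M^(2/3) and support
  ~ M^(1/3).

Perturbing a spatially homogeneous state rho_c by a mode ``exp(iqx)``
gives the growth rate

``sigma(q) = -q^2 D fl (1 + 2 gamma rho_c^2) - q^2 fn rho_c Qhat(q)``,

with ``Qhat(q) = 2r / (1 + q^2 r^2)`` the transform of the Morse
kernel.  Because ``Qhat`` peaks at q = 0, the long-wave limit is the
binding mode, which yields the closed-form instability threshold, the
critical gregarious mass fraction of a two-state mixture, and the
largest homogeneous density that can still destabilise.  Numerical
oracles (mode maximisation and eigenvalue bisection) accompany each
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import beta as beta_fn

from .model import ModelParams, local_mobility, social_strength

__all__ = [
    "PointState",
    "StabilityReport",
    "ratio_F",
    "max_density_large_mass",
    "support_large_mass",
    "calibrate_gamma",
    "small_mass_estimates",
    "kernel_transform",
    "dispersion_rate",
    "max_growth_rate",
    "single_state_unstable",
    "CriticalFraction",
    "two_state_critical_fraction",
    "two_state_critical_fraction_numeric",
    "max_homogeneous_density",
    "stability_report",
]


@dataclass(frozen=True)
class PointState:
    """A single internal state with a uniform ambient food level."""

    ng: float
    nh: float = 0.5
    c: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.ng <= 1.0 and 0.0 <= self.nh <= 1.0):
            raise ValueError("state coordinates must lie in [0, 1]")
        if self.c < 0:
            raise ValueError("food level must be nonnegative")


def ratio_F(state: PointState, params: ModelParams) -> float:
    """Ratio of nonlocal to local movement effects, ``fn/fl``.

    Negative values mean net attraction; only then can cohesive
    aggregates exist.
    """
    fl = float(local_mobility(state.nh, state.c))
    return float(social_strength(state.ng, params)) / fl


def _require_attractive(F: float) -> None:
    if F >= 0:
        raise ValueError("no cohesive aggregation: the state is net-repulsive (F >= 0)")


def max_density_large_mass(state: PointState, params: ModelParams, VQ: float | None = None) -> float:
    """Mass-independent maximum density of a large aggregate.

    Positive root of ``(2 D gamma / 3) h^2 + (fn VQ / 2) h + D fl = 0``
    rescaled by ``fl``; requires net attraction strong enough for the
    discriminant to be nonnegative.  ``VQ`` defaults to the infinite-line
    kernel integral ``2r``.
    """
    VQ = 2.0 * params.r if VQ is None else VQ
    F = ratio_F(state, params)
    _require_attractive(F)
    a = 3.0 * VQ / (8.0 * params.D * params.gamma)
    disc = (a * F) ** 2 - 3.0 / (2.0 * params.gamma)
    if disc < 0:
        raise ValueError("no cohesive aggregation: attraction too weak (negative discriminant)")
    return -a * F + math.sqrt(disc)


def support_large_mass(M: float, state: PointState, params: ModelParams, VQ: float | None = None) -> float:
    """Support of a large aggregate, ``M / max density``."""
    if M <= 0:
        raise ValueError("mass must be positive")
    return M / max_density_large_mass(state, params, VQ)


def calibrate_gamma(target_density: float, state: PointState, params: ModelParams, VQ: float | None = None) -> float:
    """Local-repulsion strength for which the large-mass density equals the target.

    Algebraic inverse of :func:`max_density_large_mass`:
    ``gamma = -6 VQ F / (8 D rho) - 3 / (2 rho^2)``.
    """
    if target_density <= 0:
        raise ValueError("target density must be positive")
    VQ = 2.0 * params.r if VQ is None else VQ
    F = ratio_F(state, params)
    _require_attractive(F)
    gamma = -6.0 * VQ * F / (8.0 * params.D * target_density) - 1.5 / target_density**2
    if gamma <= 0:
        raise ValueError("infeasible calibration: requested density needs nonpositive gamma")
    return gamma


def small_mass_estimates(M: float, state: PointState, params: ModelParams) -> tuple[float, float]:
    """Small-mass maximum density and support.

    ``max density = (-3 M^2 F / (8 D r gamma))^(1/3)`` and
    ``support = B(2/3, 1/2) (M D r gamma / (-3F))^(1/3)``; both follow
    from balancing the Taylor-expanded social flux against the local
    repulsion with linear diffusion neglected.
    """
    if M <= 0:
        raise ValueError("mass must be positive")
    F = ratio_F(state, params)
    _require_attractive(F)
    D, r, g = params.D, params.r, params.gamma
    density = (-3.0 * M**2 * F / (8.0 * D * r * g)) ** (1.0 / 3.0)
    support = beta_fn(2.0 / 3.0, 0.5) * (M * D * r * g / (-3.0 * F)) ** (1.0 / 3.0)
    return float(density), float(support)


def kernel_transform(q, r: float):
    """Fourier transform of the Morse kernel on the line, ``2r/(1+q^2 r^2)``."""
    q = np.asarray(q, dtype=float)
    return 2.0 * r / (1.0 + (q * r) ** 2)


def dispersion_rate(q, rho_c: float, state: PointState, params: ModelParams):
    """Linear growth rate sigma(q) of mode exp(iqx) about density rho_c."""
    if rho_c <= 0:
        raise ValueError("background density must be positive")
    q = np.asarray(q, dtype=float)
    fl = float(local_mobility(state.nh, state.c))
    fn = float(social_strength(state.ng, params))
    return -(q**2) * (
        params.D * fl * (1.0 + 2.0 * params.gamma * rho_c**2)
        + fn * rho_c * kernel_transform(q, params.r)
    )


def max_growth_rate(rho_c: float, state: PointState, params: ModelParams, q_max: float = 200.0):
    """Numerical supremum of sigma over q > 0, with its maximiser.

    Kernel-agnostic oracle for the closed-form threshold; scans a log
    grid then polishes with bounded minimisation.
    """
    qs = np.logspace(-4, math.log10(q_max), 600)
    sig = dispersion_rate(qs, rho_c, state, params)
    i = int(np.argmax(sig))
    lo = qs[max(i - 1, 0)]
    hi = qs[min(i + 1, len(qs) - 1)]
    res = minimize_scalar(lambda q: -dispersion_rate(q, rho_c, state, params), bounds=(lo, hi), method="bounded")
    if -res.fun >= sig[i]:
        return float(-res.fun), float(res.x)
    return float(sig[i]), float(qs[i])


def _instability_threshold(rho_c: float, params: ModelParams) -> float:
    """Value of -F above which the homogeneous state destabilises (q -> 0)."""
    return params.D * (1.0 + 2.0 * params.gamma * rho_c**2) / (2.0 * params.r * rho_c)


def single_state_unstable(rho_c: float, state: PointState, params: ModelParams) -> tuple[bool, float]:
    """Linear instability verdict for a single-state homogeneous population.

    Returns ``(unstable, threshold)`` where ``threshold`` is the value
    of ``-F`` at marginal stability.  For the Morse kernel the binding
    mode is the long-wave limit, so the verdict is equivalent to
    ``sup_q sigma(q) > 0``.
    """
    if rho_c <= 0:
        raise ValueError("background density must be positive")
    thr = _instability_threshold(rho_c, params)
    return (-ratio_F(state, params)) > thr, thr


@dataclass(frozen=True)
class CriticalFraction:
    """Critical gregarious mass fraction, with feasibility at the given density."""

    value: float
    feasible: bool


def two_state_critical_fraction(
    nS: PointState, nG: PointState, rho_c: float, params: ModelParams
) -> CriticalFraction:
    """Smallest gregarious fraction phi at which a two-state mixture destabilises.

    The background ``rho_c`` is split ``(1-phi)`` into the more
    solitarious state ``nS`` and ``phi`` into the less repulsive state
    ``nG``.  The long-wave determinant condition collapses to the
    single-state criterion applied to the phi-weighted mean force
    ratio, giving

    ``phi* = (F_S + D(1 + 2 gamma rho_c^2)/(2 r rho_c)) / (F_S - F_G)``.

    Values above 1 are returned flagged infeasible (no composition
    aggregates at this density).
    """
    if rho_c <= 0:
        raise ValueError("background density must be positive")
    FS, FG = ratio_F(nS, params), ratio_F(nG, params)
    if FS <= FG:
        raise ValueError("state ordering violated: nG must be strictly less repulsive than nS")
    phi = (FS + _instability_threshold(rho_c, params)) / (FS - FG)
    return CriticalFraction(float(phi), bool(phi <= 1.0))


def _two_state_matrix(q: float, phi: float, nS: PointState, nG: PointState, rho_c: float, params: ModelParams):
    states = (nS, nG)
    rho0 = (rho_c * (1.0 - phi), rho_c * phi)
    qhat = float(kernel_transform(q, params.r))
    m = np.empty((2, 2))
    for i, (st, ri) in enumerate(zip(states, rho0)):
        fli = float(local_mobility(st.nh, st.c))
        fni = float(social_strength(st.ng, params))
        for j in range(2):
            m[i, j] = -(q**2) * (
                params.D * fli * (1.0 if i == j else 0.0)
                + ri * (fni * qhat + 2.0 * params.D * params.gamma * fli * rho_c)
            )
    return m


def two_state_critical_fraction_numeric(
    nS: PointState, nG: PointState, rho_c: float, params: ModelParams, q: float = 1e-4
) -> float:
    """Oracle for phi*: bisection on the leading eigenvalue of the 2x2 dispersion matrix.

    Works at a small but finite wavenumber (the matrix scales with q^2,
    so the sign structure is q-independent in the long-wave limit).
    Returns ``inf`` if even a fully gregarious composition at 10x unit
    fraction stays stable.
    """

    def lead(phi: float) -> float:
        return float(np.max(np.real(np.linalg.eigvals(_two_state_matrix(q, phi, nS, nG, rho_c, params)))))

    lo, hi = 0.0, 1.0
    if lead(lo) > 0:
        return 0.0
    while lead(hi) <= 0:
        hi *= 2.0
        if hi > 16.0:
            return math.inf
    return brentq(lambda p: lead(p), lo, hi, xtol=1e-14, rtol=1e-13)


def max_homogeneous_density(state: PointState, params: ModelParams) -> float:
    """Largest homogeneous density that is still linearly unstable.

    Larger root of the marginal-stability quadratic
    ``2 D gamma rho_c^2 + 2 r F rho_c + D = 0``.  As attraction grows
    this approaches two thirds of the large-mass maximum density.
    """
    F = ratio_F(state, params)
    _require_attractive(F)
    b = params.r * F / (2.0 * params.D * params.gamma)
    disc = b * b - 1.0 / (2.0 * params.gamma)
    if disc < 0:
        raise ValueError("no instability window: attraction too weak (negative discriminant)")
    return -b + math.sqrt(disc)


@dataclass(frozen=True)
class StabilityReport:
    """Summary of the linear stability of a homogeneous state."""

    F: float
    rho_c: float
    unstable: bool
    threshold: float
    q: np.ndarray
    sigma: np.ndarray
    max_sigma: float
    most_unstable_q: float
    phi_star: float | None = None
    phi_star_feasible: bool | None = None
    rho_c_max: float | None = None

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "rho_c": self.rho_c,
            "unstable": self.unstable,
            "threshold_minus_F": self.threshold,
            "max_sigma": self.max_sigma,
            "most_unstable_q": self.most_unstable_q,
            "phi_star": self.phi_star,
            "phi_star_feasible": self.phi_star_feasible,
            "rho_c_max": self.rho_c_max,
        }


def stability_report(
    state: PointState,
    rho_c: float,
    params: ModelParams,
    q: np.ndarray | None = None,
    solitarious: PointState | None = None,
) -> StabilityReport:
    """Assemble dispersion curve, verdict and optional two-state quantities."""
    if q is None:
        q = np.linspace(0.0, 8.0 * math.pi / params.r, 512)
    sigma = dispersion_rate(q, rho_c, state, params)
    unstable, thr = single_state_unstable(rho_c, state, params)
    smax, qmax = max_growth_rate(rho_c, state, params)
    phi = feas = rc_max = None
    if solitarious is not None:
        cf = two_state_critical_fraction(solitarious, state, rho_c, params)
        phi, feas = cf.value, cf.feasible
    F = ratio_F(state, params)
    if F < 0:
        try:
            rc_max = max_homogeneous_density(state, params)
        except ValueError:
            rc_max = None
    return StabilityReport(
        F=F, rho_c=rho_c, unstable=unstable, threshold=thr,
        q=np.asarray(q, dtype=float), sigma=np.asarray(sigma, dtype=float),
        max_sigma=smax, most_unstable_q=qmax,
        phi_star=phi, phi_star_feasible=feas, rho_c_max=rc_max,
    )
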