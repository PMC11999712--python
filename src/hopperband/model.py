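"""Locust behavioural functions and the model parameter set.

The model tracks a locust population density that is structured by two
internal state coordinates, each normalised to the unit interval:

``ng``
    degree of gregarisation.  Solitarious behaviour (mutual avoidance)
    for ``ng < 0.5``, gregarious behaviour (mutual attraction) above.
``nh``
    hunger--satiation.  ``nh = 0`` is completely starving, ``nh = 1``
    completely satiated.

All closed-form behavioural responses live here: the mobility factors
through which food and hunger modulate local movement, the sigmoidal
switch from social repulsion to attraction with gregarisation, the
density-dependent serotonin release that drives gregarisation, and the
feeding/metabolism kinetics of the hunger coordinate.  Everything is
vectorised over numpy arrays and validates its physical domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ModelParams",
    "food_mobility",
    "hunger_mobility",
    "local_mobility",
    "social_strength",
    "serotonin_release",
    "gregarisation_velocity",
    "hunger_velocity",
    "feeding_rate",
    "consumption_rate",
    "derive_metabolic_rate",
]

#: Keys that appear in serialized parameter files, in canonical order.
PARAM_KEYS = ("D", "gamma", "A", "r", "k", "kappa", "delta", "nu", "eta_l", "eta_f")


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the locust specialisation.

    Defaults are the calibrated values used for all production
    simulations.  Rates are per hour, lengths in metres and densities in
    locusts per metre of (one-dimensional) transect.

    Parameters
    ----------
    D : float
        Linear diffusion coefficient (m^2 hr^-1).
    gamma : float
        Strength of the nonlinear local repulsion (locusts^-2).
    A : float
        Maximum strength of the nonlocal social interaction
        (m^3 hr^-1 locust^-1).
    r : float
        Sensing range of the social potential (m).
    k : float
        Serotonin decay rate (hr^-1).
    kappa : float
        Density at which serotonin release reaches half its maximum
        (locusts m^-2).
    delta : float
        Maximal normalised serotonin release rate (hr^-1).
    nu : float
        Satiation loss rate due to metabolism (hr^-1).
    eta_l : float
        Satiation gain rate while feeding (hr^-1).
    eta_f : float
        Per-capita food consumption rate (hr^-1).
    sigmoid_steepness, sigmoid_midpoint : float
        Shape constants of the repulsion/attraction switch.  These are
        structural constants of the model, exposed read-only so
        sensitivity studies can construct variants explicitly.
    """

    D: float = 0.01
    gamma: float = 4.5291
    A: float = 6.83
    r: float = 0.14
    k: float = 0.9986
    kappa: float = 4.8293
    delta: float = 0.9960
    nu: float = 0.2496
    eta_l: float = 0.9362
    eta_f: float = 0.0384
    sigmoid_steepness: float = 15.0
    sigmoid_midpoint: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be a finite number, got {v!r}")
        for name in PARAM_KEYS:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if self.sigmoid_steepness <= 0:
            raise ValueError("sigmoid_steepness must be strictly positive")
        if not 0.0 < self.sigmoid_midpoint < 1.0:
            raise ValueError("sigmoid_midpoint must lie in (0, 1)")

    def to_dict(self) -> dict[str, float]:
        """Serializable mapping of the ten tunable constants."""
        return {name: float(getattr(self, name)) for name in PARAM_KEYS}


def _as_checked(x, lo=None, hi=None, name="value"):
    arr = np.asarray(x, dtype=float)
    if lo is not None and np.any(arr < lo):
        raise ValueError(f"{name} must be >= {lo}")
    if hi is not None and np.any(arr > hi):
        raise ValueError(f"{name} must be <= {hi}")
    return arr


def food_mobility(c):
    """Mobility factor from local food density: ``exp(-c)``.

    Locusts pause to feed where food is present, so mobility decreases
    monotonically from 1 (bare ground) towards 0 as food density grows,
    with each doubling of food having a diminishing effect.
    """
    c = _as_checked(c, lo=0.0, name="food density c")
    return np.exp(-c)


def hunger_mobility(nh):
    """Mobility factor from satiation: ``1.5 - nh``.

    Linear in the satiation state, normalised so a half-satiated locust
    has factor 1; a starving locust (``nh=0``) moves three times as fast
    as a fully satiated one (``nh=1``).
    """
    nh = _as_checked(nh, lo=0.0, hi=1.0, name="satiation nh")
    return 1.5 - nh


def local_mobility(nh, c):
    """Combined local mobility factor ``food_mobility(c) * hunger_mobility(nh)``."""
    return food_mobility(c) * hunger_mobility(nh)


def social_strength(ng, params: ModelParams):
    """Signed strength of the nonlocal social interaction.

    A steep sigmoid in the gregarisation state, odd-symmetric about the
    solitarious/gregarious transition point: positive (repulsive) for
    ``ng`` below the midpoint, negative (attractive) above, and exactly
    zero at the midpoint.  Saturates at ``+/- A``.
    """
    ng = _as_checked(ng, lo=0.0, hi=1.0, name="gregarisation ng")
    s, m = params.sigmoid_steepness, params.sigmoid_midpoint
    return params.A * (1.0 - 2.0 / (1.0 + np.exp(-s * (ng - m))))


def serotonin_release(rho_bar, params: ModelParams):
    """Density-dependent serotonin release rate (hr^-1).

    Saturating Hill-type response ``delta * (rho/kappa)^2 / (1 + (rho/kappa)^2)``:
    zero at zero density, half-maximal at ``rho = kappa``, bounded by ``delta``.
    """
    rho_bar = _as_checked(rho_bar, lo=0.0, name="local density rho_bar")
    u = (rho_bar / params.kappa) ** 2
    return params.delta * u / (1.0 + u)


def gregarisation_velocity(ng, rho_bar, params: ModelParams):
    """Rate of change of the gregarisation state, ``f(rho_bar) - k*ng``.

    Serotonin release pushes the state up, first-order decay pulls it
    down; the pointwise equilibrium is ``ng* = f(rho_bar)/k``.  Because
    ``delta < k`` for the default calibration the velocity at ``ng = 1``
    is always negative, so no mass is driven out of the state interval.
    """
    ng = _as_checked(ng, lo=0.0, hi=1.0, name="gregarisation ng")
    return serotonin_release(rho_bar, params) - params.k * ng


def feeding_rate(nh, params: ModelParams):
    """Satiation gain rate per unit food, ``eta_l * (2 - nh)``.

    A starving locust eats twice as fast as a satiated one.
    """
    nh = _as_checked(nh, lo=0.0, hi=1.0, name="satiation nh")
    return params.eta_l * (2.0 - nh)


def hunger_velocity(nh, c, params: ModelParams):
    """Rate of change of satiation, ``eta_l*(2-nh)*c - nu*nh``."""
    c = _as_checked(c, lo=0.0, name="food density c")
    nh = np.asarray(nh, dtype=float)
    return feeding_rate(nh, params) * c - params.nu * nh


def consumption_rate(nh, params: ModelParams):
    """Per-capita food consumption factor, ``eta_f * (2 - nh)`` (hr^-1)."""
    nh = _as_checked(nh, lo=0.0, hi=1.0, name="satiation nh")
    return params.eta_f * (2.0 - nh)


def derive_metabolic_rate(active_hours: float, residual_satiation: float) -> float:
    """Calibrate the metabolic satiation-loss rate ``nu``.

    Under pure decay ``dnh/dt = -nu*nh``, a locust starting fully
    satiated retains a fraction ``residual_satiation`` of its satiation
    after ``active_hours`` hours of activity, giving
    ``nu = -ln(residual_satiation)/active_hours``.  The default
    calibration (12 active hours to effectively full starvation, taken
    as a 5% residual) yields nu = 0.2496 hr^-1.
    """
    if active_hours <= 0:
        raise ValueError("active_hours must be positive")
    if not 0.0 < residual_satiation < 1.0:
        raise ValueError("residual_satiation must lie in (0, 1)")
    return -math.log(residual_satiation) / active_hours
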