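"""Closed-form estimates and stability theory against numerical oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from hopperband.engine import SolverSettings, integrate
from hopperband.grids import SpatialGrid, StateDim, StateGrid, PopulationField, marginal_density
from hopperband.model import ModelParams, local_mobility, social_strength
from hopperband.stability import (
    PointState,
    calibrate_gamma,
    dispersion_rate,
    kernel_transform,
    max_density_large_mass,
    max_growth_rate,
    max_homogeneous_density,
    ratio_F,
    single_state_unstable,
    small_mass_estimates,
    stability_report,
    support_large_mass,
    two_state_critical_fraction,
    two_state_critical_fraction_numeric,
)

VALIDATION_STATE = PointState(ng=0.95, nh=0.55, c=0.0)


def test_ratio_F_anchors(validation_params, params):
    assert ratio_F(PointState(0.5, 0.3, 1.0), params) == 0.0
    # direct evaluation with A=1: fn(0.95)/fl(0.55, 0)
    expected = (1.0 - 2.0 / (1.0 + math.exp(-15.0 * 0.45))) / 0.95
    assert ratio_F(VALIDATION_STATE, validation_params) == pytest.approx(expected, rel=1e-12)
    assert ratio_F(VALIDATION_STATE, validation_params) == pytest.approx(-1.0502, abs=1e-4)
    # food strengthens relative attraction (fl shrinks, fn unchanged)
    f0 = ratio_F(PointState(0.95, 0.55, 0.0), params)
    f1 = ratio_F(PointState(0.95, 0.55, 1.0), params)
    assert abs(f1) > abs(f0)


def test_max_density_large_mass_anchor(validation_params):
    assert max_density_large_mass(VALIDATION_STATE, validation_params) == pytest.approx(2.62, abs=0.01)
    # support = M / max density, linear in M
    M = 96.17
    s = support_large_mass(M, VALIDATION_STATE, validation_params)
    assert s == pytest.approx(M / 2.6159, abs=0.01)
    assert support_large_mass(2 * M, VALIDATION_STATE, validation_params) == pytest.approx(2 * s, rel=1e-12)


def test_max_density_linear_in_F_at_strong_attraction():
    p = ModelParams(D=0.01, gamma=60.0, A=500.0, r=1.0)
    st = PointState(0.95, 0.55, 0.0)
    F = ratio_F(st, p)
    VQ = 2.0 * p.r
    asymptote = -3.0 * VQ * F / (4.0 * p.D * p.gamma)
    assert max_density_large_mass(st, p) == pytest.approx(asymptote, rel=1e-3)


def test_hungrier_states_less_dense(validation_params):
    dens = [max_density_large_mass(PointState(0.95, nh, 0.0), validation_params) for nh in (0.15, 0.55, 0.95)]
    assert dens[0] < dens[1] < dens[2]


def test_calibrate_gamma_roundtrip(validation_params):
    rho_inf = max_density_large_mass(VALIDATION_STATE, validation_params)
    assert calibrate_gamma(rho_inf, VALIDATION_STATE, validation_params) == pytest.approx(validation_params.gamma, rel=1e-10)
    # denser targets need weaker local repulsion
    g1 = calibrate_gamma(2.0, VALIDATION_STATE, validation_params)
    g2 = calibrate_gamma(2.5, VALIDATION_STATE, validation_params)
    assert g2 < g1


def test_repulsive_state_has_no_aggregate(params):
    with pytest.raises(ValueError):
        max_density_large_mass(PointState(0.3, 0.5, 0.0), params)
    with pytest.raises(ValueError):
        small_mass_estimates(1.0, PointState(0.5, 0.5, 0.0), params)


def test_small_mass_scalings(validation_params):
    d1, s1 = small_mass_estimates(0.1, VALIDATION_STATE, validation_params)
    d2, s2 = small_mass_estimates(0.8, VALIDATION_STATE, validation_params)  # 8x mass
    assert d2 / d1 == pytest.approx(4.0, rel=1e-12)   # M^(2/3)
    assert s2 / s1 == pytest.approx(2.0, rel=1e-12)   # M^(1/3)
    # beta-function prefactor
    from scipy.special import beta
    assert beta(2 / 3, 1 / 2) == pytest.approx(2.5871, abs=2e-4)
    # small-mass density estimate sits below the large-mass plateau
    d_small, _ = small_mass_estimates(0.48, VALIDATION_STATE, validation_params)
    assert d_small < max_density_large_mass(VALIDATION_STATE, validation_params)


def test_small_mass_against_flux_balance_quadrature(validation_params):
    """Independent oracle: the diffusion-free steady state with the
    Taylor-expanded kernel satisfies (rb^2)'' = -c^2 rb with
    c^2 = -2F/(r D gamma); shooting from the peak gives M as a quadrature
    in the peak density, inverted numerically here."""
    F = ratio_F(VALIDATION_STATE, validation_params)
    c2 = -2.0 * F / (validation_params.r * validation_params.D * validation_params.gamma)
    I1 = quad(lambda s: math.sqrt(s) / math.sqrt(1.0 - s**1.5), 0, 1)[0]

    def mass_of_peak(rho_max):
        return 2.0 * math.sqrt(3.0 / (4.0 * c2)) * rho_max**1.5 * I1

    # invert numerically for M = 0.1
    M = 0.1
    res = minimize_scalar(lambda rm: (mass_of_peak(rm) - M) ** 2, bounds=(1e-3, 10.0), method="bounded")
    d_est, _ = small_mass_estimates(M, VALIDATION_STATE, validation_params)
    assert d_est == pytest.approx(res.x, rel=1e-4)


def test_dispersion_basics(params):
    st = PointState(0.3, 0.5, 0.0)  # solitarious: never patterns
    q = np.linspace(0.01, 100.0, 300)
    assert np.all(dispersion_rate(q, 5.0, st, params) < 0)
    assert dispersion_rate(0.0, 5.0, st, params) == 0.0
    # diffusion wins at small scales for any state
    stg = PointState(0.95, 0.5, 0.0)
    sig = dispersion_rate(np.array([200.0, 400.0]), 5.0, stg, params)
    assert np.all(sig < 0)


def test_single_state_threshold_matches_mode_oracle(params):
    # closed-form verdict == sign of the numerically maximised growth rate
    for rho_c in (0.5, 2.0, 5.0, 12.0):
        for ng in (0.3, 0.55, 0.7, 0.95):
            st = PointState(ng, 0.5, 0.0)
            verdict, thr = single_state_unstable(rho_c, st, params)
            smax, _ = max_growth_rate(rho_c, st, params)
            assert verdict == (smax > 1e-12), (rho_c, ng, smax, thr)


def test_threshold_minimised_at_optimal_density(params):
    # -F threshold D(1+2 gamma rho^2)/(2 r rho) is minimal at rho = 1/sqrt(2 gamma)
    rho_opt = 1.0 / math.sqrt(2.0 * params.gamma)
    _, thr_opt = single_state_unstable(rho_opt, PointState(0.9), params)
    res = minimize_scalar(
        lambda rc: single_state_unstable(rc, PointState(0.9), params)[1], bounds=(1e-3, 10.0), method="bounded"
    )
    assert res.x == pytest.approx(rho_opt, rel=1e-4)
    assert res.fun == pytest.approx(thr_opt, rel=1e-8)


def test_food_lowers_required_gregariousness(params):
    # with more food (lower mobility) a given state destabilises more easily
    rho_c = 5.0

    def critical_ng(c):
        lo, hi = 0.5, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if single_state_unstable(rho_c, PointState(mid, 0.5, c), params)[0]:
                hi = mid
            else:
                lo = mid
        return hi

    assert critical_ng(1.0) < critical_ng(0.0)


def test_two_state_closed_form_matches_eigen_oracle(params):
    cases = [
        (PointState(0.30, 0.5, 0.0), PointState(0.90, 0.5, 0.0), 5.0),
        (PointState(0.45, 0.3, 0.5), PointState(0.80, 0.8, 0.5), 3.0),
        (PointState(0.40, 0.5, 0.0), PointState(0.60, 0.5, 0.0), 8.0),
    ]
    for nS, nG, rho_c in cases:
        cf = two_state_critical_fraction(nS, nG, rho_c, params)
        num = two_state_critical_fraction_numeric(nS, nG, rho_c, params)
        if math.isfinite(num):
            assert cf.value == pytest.approx(num, rel=1e-8)


def test_two_state_ordering_and_feasibility(params):
    nS = PointState(0.3, 0.5, 0.0)
    with pytest.raises(ValueError):
        two_state_critical_fraction(nS, nS, 5.0, params)
    # if even the all-gregarious population is stable, phi* > 1 (infeasible)
    nG = PointState(0.55, 0.5, 0.0)
    rho_c = 0.005
    assert not single_state_unstable(rho_c, nG, params)[0]
    cf = two_state_critical_fraction(nS, nG, rho_c, params)
    assert cf.value > 1.0 and not cf.feasible


def test_critical_fraction_u_shaped_in_density(params):
    nS, nG = PointState(0.35, 0.5, 0.0), PointState(0.95, 0.5, 0.0)
    rcs = np.logspace(-3.5, 3, 41)
    phi = np.array([two_state_critical_fraction(nS, nG, rc, params).value for rc in rcs])
    imin = int(np.argmin(phi))
    assert 0 < imin < len(rcs) - 1
    assert phi[0] > 10 * phi[imin] and phi[-1] > 10 * phi[imin]


def test_max_homogeneous_density_marginal(params):
    st = PointState(0.95, 0.5, 0.0)
    rc = max_homogeneous_density(st, params)
    assert single_state_unstable(rc * (1 - 1e-6), st, params)[0]
    assert not single_state_unstable(rc * (1 + 1e-6), st, params)[0]
    # hungrier locusts destabilise at lower densities
    rc_hungry = max_homogeneous_density(PointState(0.95, 0.15, 0.0), params)
    assert rc_hungry < max_homogeneous_density(PointState(0.95, 0.95, 0.0), params)


def test_two_thirds_ratio_strong_attraction():
    st = PointState(0.95, 0.55, 0.0)
    p = ModelParams(D=0.01, gamma=60.0, A=150.0, r=1.0)
    F = ratio_F(st, p)
    assert -F >= 100.0 * math.sqrt(p.D**2 * p.gamma) / p.r
    ratio = max_homogeneous_density(st, p) / max_density_large_mass(st, p)
    assert ratio == pytest.approx(2.0 / 3.0, rel=0.01)


def test_monotonicity_grid(params):
    """Directional trends of the estimates over a grid of admissible states."""
    ngs = np.linspace(0.75, 0.99, 10)
    nhs = np.linspace(0.05, 0.95, 10)
    cs = np.linspace(0.0, 2.0, 10)
    # density increases with gregarisation and satiation and food
    for nh, c in ((0.5, 0.0), (0.2, 1.0)):
        d = [max_density_large_mass(PointState(g, nh, c), params) for g in ngs]
        assert np.all(np.diff(d) > 0)
    for ng, c in ((0.95, 0.0), (0.85, 1.0)):
        d = [max_density_large_mass(PointState(ng, h, c), params) for h in nhs]
        assert np.all(np.diff(d) > 0)
    for ng, nh in ((0.95, 0.5), (0.85, 0.3)):
        d = [max_density_large_mass(PointState(ng, nh, c), params) for c in cs]
        assert np.all(np.diff(d) > 0)


def test_linear_growth_rates_match_simulation(params):
    """Seed small cosine perturbations of an unstable homogeneous state and
    fit the exponential growth of each mode against sigma(q)."""
    st = PointState(0.95, 0.5, 0.0)
    rho_c = 5.0
    assert single_state_unstable(rho_c, st, params)[0]
    grid = SpatialGrid(L=3.0, nx=384)
    sg = StateGrid(StateDim.fixed("ng", st.ng), StateDim.fixed("nh", st.nh))
    T = 0.05
    for mode in (1, 2, 3):
        q = 2.0 * math.pi * mode / grid.L
        eps = 1e-6
        rb0 = rho_c * (1.0 + eps * np.cos(q * grid.centers))
        rho = PopulationField(grid, sg, rb0[:, None, None])
        traj = integrate(rho, None, params, SolverSettings(t_end=T, n_snapshots=3, method="heun", cfl=0.1))
        amp = []
        for pf, _ in traj.snapshots:
            rb = marginal_density(pf)
            amp.append(2.0 * np.abs(np.fft.rfft(rb - rb.mean())[mode]) / grid.nx)
        measured = math.log(amp[-1] / amp[0]) / T
        predicted = float(dispersion_rate(q, rho_c, st, params))
        assert measured == pytest.approx(predicted, rel=0.05), (mode, measured, predicted)


def test_stability_report_roundtrip(params):
    rep = stability_report(PointState(0.3, 0.5, 0.0), 5.0, params)
    assert not rep.unstable and rep.max_sigma <= 1e-12
    d = rep.to_dict()
    assert d["rho_c"] == 5.0 and d["unstable"] is False
    rep2 = stability_report(
        PointState(0.95, 0.5, 0.0), 5.0, params, solitarious=PointState(0.3, 0.5, 0.0)
    )
    assert rep2.unstable and rep2.phi_star is not None and 0 < rep2.phi_star < 1
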