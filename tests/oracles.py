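"""Independent reference computations used only by the test suite.

The axisymmetric Helfrich oracle evaluates the bending energy of a
surface of revolution rho(theta) (distance from the origin, polar angle
theta) by 1D quadrature and minimizes over a few Legendre modes.  It shares
no code with the triangle-mesh path it cross-checks.
"""

import numpy as np
from numpy.polynomial import legendre as L
from scipy.optimize import minimize as _sp_minimize


def axisym_energy(coeffs, vbar_target=None, n_grid=2001):
    """(Ebar, vbar) for rho(theta) = 1 + sum_k c_k P_k(cos theta), k >= 2."""
    c = np.zeros(len(coeffs) + 2)
    c[2:] = coeffs
    theta = np.linspace(1e-6, np.pi - 1e-6, n_grid)
    mu = np.cos(theta)
    rho = 1.0 + L.legval(mu, c)
    dc = L.legder(c)
    d2c = L.legder(dc)
    drho_dmu = L.legval(mu, dc)
    d2rho_dmu2 = L.legval(mu, d2c)
    s = np.sin(theta)
    rho_t = -s * drho_dmu
    rho_tt = -mu * drho_dmu + s * s * d2rho_dmu2

    x = rho * s
    z = rho * mu
    x_t = rho_t * s + rho * mu
    z_t = rho_t * mu - rho * s
    x_tt = rho_tt * s + 2 * rho_t * mu - rho * s
    z_tt = rho_tt * mu - 2 * rho_t * s - rho * mu
    g = x_t ** 2 + z_t ** 2
    km = (x_t * z_tt - z_t * x_tt) / g ** 1.5
    kp = z_t / (x * np.sqrt(g))
    h = 0.5 * (km + kp)

    ds = np.sqrt(g)
    area = 2 * np.pi * np.trapezoid(x * ds, theta)
    vol = 2 * np.pi / 3 * np.trapezoid(rho ** 3 * s, theta)
    e = 2.0 * 2 * np.pi * np.trapezoid(h * h * x * ds, theta)  # (1/2)(2H)^2
    ebar = e / (8 * np.pi)
    vbar = np.sqrt(36 * np.pi) * vol / area ** 1.5
    return ebar, vbar


def axisym_min_energy(vbar_target, n_modes=4):
    """Minimal reduced bending energy over axisymmetric shapes at fixed vbar."""

    def cost(coeffs):
        ebar, vbar = axisym_energy(coeffs)
        return ebar + 1e4 * (vbar - vbar_target) ** 2

    res = _sp_minimize(cost, np.zeros(n_modes), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10,
                                "maxiter": 4000})
    ebar, vbar = axisym_energy(res.x)
    assert abs(vbar - vbar_target) < 1e-3
    return ebar


def core_vmax_bruteforce(phi_core, n_coarse=200001):
    """Maximal inflation of the bulb-on-disk shape by scanning cap angles.

    For each opening angle psi the bulb radius follows from the fluid-area
    share; the scan locates where the implied rim disk carries exactly
    phi_core of the area, refining with a local parabola.
    """
    psi = np.linspace(1e-6, np.pi - 1e-6, n_coarse)
    rs = np.sqrt(2 * (1 - phi_core) / (1 + np.cos(psi)))
    resid = (rs * np.sin(psi)) ** 2 / 4.0 - phi_core
    # residual crosses zero once in (0, pi/2-ish)
    idx = np.nonzero(np.diff(np.sign(resid)))[0][0]
    # linear interpolation between the bracketing samples
    p0, p1 = psi[idx], psi[idx + 1]
    r0, r1 = resid[idx], resid[idx + 1]
    ps = p0 - r0 * (p1 - p0) / (r1 - r0)
    rs = np.sqrt(2 * (1 - phi_core) / (1 + np.cos(ps)))
    h = rs * (1 + np.cos(ps))
    vol = np.pi * h * h * (3 * rs - h) / 3.0
    return vol / (4 * np.pi / 3)
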