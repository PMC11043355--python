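"""Membrane tension from thermal contraction balanced by water permeation.

Cooling contracts the bilayer (area thermal-expansion coefficient
kappa = (1/A)(dA/dT) at fixed tension) faster than the enclosed water, which
puts the membrane under tension; tension in turn drives water efflux through
the Laplace pressure 2 tau / R at a rate set by the permeability P:

    dV/dt = -A (2 tau / R) (P / rho).

At constant cooling rate the two rates balance at the steady-state tension

    tau_ss ~ (kappa rho / 4 P) |dT/dt| R^2,

which grows with the square of the vesicle radius — the origin of the
vesicle-size selection of crystal morphologies.  Note R is the vesicle
*radius*: quoted vesicle sizes are usually diameters, and the R^2 scaling
makes the convention worth a factor of four.

The transient model closes the balance with an elastic area relation
tau = K_A (A - A_relaxed)/A_relaxed (K_A the apparent area-stretch modulus,
not part of the steady-state result) on a quasi-spherical vesicle, and
optionally caps tension at the lysis threshold with burst-reseal events that
vent enclosed volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

MICRON = 1e-6


@dataclass(frozen=True)
class ThermalParams:
    """Thermal/permeation constants in the units experimentalists quote.

    kappa: 1/degC; permeability_s_per_um: s/um; rho: kg/m^3;
    cooling_C_per_min: degC/min (magnitude); radius_um: vesicle radius in um;
    lysis_mN_per_m: rupture tension.
    """

    kappa: float = 0.005
    permeability_s_per_um: float = 2.8e-16
    rho: float = 1000.0
    cooling_C_per_min: float = 0.3
    radius_um: float = 5.0
    lysis_mN_per_m: float = 8.5  # middle of the 7-10 mN/m band

    def __post_init__(self):
        for name in ("kappa", "permeability_s_per_um", "rho",
                     "cooling_C_per_min", "radius_um", "lysis_mN_per_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def permeability_s_per_m(self) -> float:
        return self.permeability_s_per_um / MICRON

    @property
    def radius_m(self) -> float:
        return self.radius_um * MICRON

    @property
    def cooling_C_per_s(self) -> float:
        return self.cooling_C_per_min / 60.0


def steady_state_tension(params: ThermalParams) -> float:
    """Steady-state tension (kappa rho / 4 P) |dT/dt| R^2, in mN/m."""
    tau_si = (params.kappa * params.rho / (4.0 * params.permeability_s_per_m)
              * params.cooling_C_per_s * params.radius_m ** 2)
    return tau_si * 1e3


def permeation_volume_rate(area_m2: float, tau_mN_per_m: float, radius_m: float,
                           permeability_s_per_m: float, rho: float) -> float:
    """dV/dt = -A (2 tau / R)(P / rho), SI (m^3/s); zero at zero tension."""
    if tau_mN_per_m < 0:
        raise ValueError("tension must be non-negative")
    tau_si = tau_mN_per_m * 1e-3
    return -area_m2 * (2.0 * tau_si / radius_m) * (permeability_s_per_m / rho)


@dataclass
class TemperatureSchedule:
    """Piecewise-linear T(t): times in seconds, temperatures in degC."""

    times: np.ndarray
    temps: np.ndarray

    @classmethod
    def constant_cooling(cls, rate_C_per_min: float, t_end_s: float,
                         t_start_C: float = 45.0) -> "TemperatureSchedule":
        t = np.array([0.0, t_end_s])
        return cls(t, t_start_C - rate_C_per_min / 60.0 * t)

    def rate(self, t: float) -> float:
        i = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0,
                    len(self.times) - 2)
        dt = self.times[i + 1] - self.times[i]
        return (self.temps[i + 1] - self.temps[i]) / dt


def transient_tension(params: ThermalParams, schedule: TemperatureSchedule,
                      K_A_mN_per_m: float = 240.0,
                      lysis_cap: bool = False,
                      reseal_fraction: float = 0.9,
                      n_eval: int = 400) -> pd.DataFrame:
    """Integrate the contraction/permeation balance along a cooling history.

    State: enclosed volume V and relaxed (tension-free) area A_rel of a
    quasi-spherical vesicle; A(V) is the sphere area, and
    tau = K_A max(0, A - A_rel)/A_rel closes the loop.  With ``lysis_cap``,
    reaching the lysis tension vents volume until tau falls to
    ``reseal_fraction`` of the threshold (burst-reseal).  Returns a
    trajectory frame (t_s, T_C, tau_mN_per_m, A_m2, V_m3, radius_um).
    """
    r0 = params.radius_m
    v0 = 4.0 / 3.0 * np.pi * r0 ** 3
    a_rel0 = 4.0 * np.pi * r0 ** 2
    ka_si = K_A_mN_per_m * 1e-3
    lysis_si = params.lysis_mN_per_m * 1e-3
    p_si = params.permeability_s_per_m

    def sphere_area(v):
        return (36.0 * np.pi) ** (1.0 / 3.0) * v ** (2.0 / 3.0)

    def tau_si_of(v, a_rel):
        return ka_si * max(0.0, sphere_area(v) - a_rel) / a_rel

    def rhs(t, y):
        v, a_rel = y
        a = sphere_area(v)
        r = np.sqrt(a / (4.0 * np.pi))
        tau = tau_si_of(v, a_rel)
        dv = -a * (2.0 * tau / r) * (p_si / params.rho)
        da_rel = params.kappa * a_rel * schedule.rate(t)
        return [dv, da_rel]

    def burst(t, y):
        return tau_si_of(y[0], y[1]) - lysis_si

    burst.terminal = True
    burst.direction = 1.0

    t_end = float(schedule.times[-1])
    rows = []
    t0, y = 0.0, [v0, a_rel0]
    while t0 < t_end - 1e-12:
        t_eval = np.linspace(t0, t_end, max(int(n_eval * (t_end - t0) / t_end), 8))
        sol = solve_ivp(rhs, (t0, t_end), y, method="LSODA",
                        events=burst if lysis_cap else None,
                        t_eval=t_eval, rtol=1e-8, atol=[v0 * 1e-12, a_rel0 * 1e-12])
        for tt, (v, a_rel) in zip(sol.t, sol.y.T):
            rows.append((tt, v, a_rel))
        if sol.status == 1 and lysis_cap:  # burst: vent volume, reseal
            tb = float(sol.t_events[0][0])
            v, a_rel = sol.y_events[0][0]
            a_target = a_rel * (1.0 + reseal_fraction * lysis_si / ka_si)
            v = (a_target / (36.0 * np.pi) ** (1.0 / 3.0)) ** 1.5
            rows.append((tb, v, a_rel))
            t0, y = tb, [v, a_rel]
        else:
            break

    t_arr = np.array([r[0] for r in rows])
    v_arr = np.array([r[1] for r in rows])
    ar_arr = np.array([r[2] for r in rows])
    a_arr = sphere_area(v_arr)
    tau_arr = ka_si * np.maximum(0.0, a_arr - ar_arr) / ar_arr * 1e3
    temp = np.interp(t_arr, schedule.times, schedule.temps)
    return pd.DataFrame({
        "t_s": t_arr, "T_C": temp, "tau_mN_per_m": tau_arr,
        "A_m2": a_arr, "V_m3": v_arr,
        "radius_um": np.sqrt(a_arr / (4 * np.pi)) / MICRON,
    })
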