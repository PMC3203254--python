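"""Well-mixed-solution (WMS) model of the RTA system.

When the toxin/antibody/complex solution in the shell around the cell is
assumed perfectly mixed, the reaction-diffusion system collapses to four
ODEs for the bulk concentrations (uT, uA, uC) and the fraction theta of
occupied surface receptors:

    duT/dt = -k1 uT uA + k_m1 uC - k4 r0 (k2 (1-theta) uT - k_m2 theta)
    dtheta/dt = k2 (1-theta) uT - k_m2 theta - k3 theta
    duA/dt = -k1 uT uA + k_m1 uC
    duC/dt = +k1 uT uA - k_m1 uC

with k4 = S_c/V_Omega the surface-to-volume ratio of the shell.  There is
no influx through the outer boundary, so the antibody obeys the exact
conservation law uA + uC = uA0 and, without internalization (k3 = 0), the
toxin obeys uT + uC + k4 r0 theta = uT0.

The module also provides the steady-state occupancy without internalization
(a closed scalar equation in theta), its explicit quadratic approximation
F(x, y), and the three WMS estimators of the saturation protection factor:
psi2 (steady-state root ratio), psi3 (closed-form ratio) and psi4
(long-time integration ratio).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .parameters import DerivedConstants, RTAParameters, derived_constants

__all__ = [
    "WMSTrajectory",
    "wms_rhs",
    "integrate_wms",
    "steady_state_theta",
    "closed_form_F",
    "psi_sat_wms",
    "conservation_residuals",
]

#: default horizon for long-time saturation estimates (nondimensional time)
T_LONG_DEFAULT = 1.0e4


@dataclass(frozen=True)
class WMSTrajectory:
    """ODE solution sampled at requested output times.

    Arrays t, uT, uA, uC, theta all share one length; rtol/atol/method echo
    the solver settings that produced it.
    """

    t: np.ndarray
    uT: np.ndarray
    uA: np.ndarray
    uC: np.ndarray
    theta: np.ndarray
    rtol: float
    atol: float
    method: str


def wms_rhs(t: float, y: np.ndarray, p: RTAParameters) -> np.ndarray:
    """Right-hand side of the WMS ODEs; y = (uT, uA, uC, theta)."""
    uT, uA, uC, theta = y
    r = p.rates
    d = derived_constants(p)
    complexation = -r.k1 * uT * uA + r.k_m1 * uC
    s = r.k2 * (1.0 - theta) * uT - r.k_m2 * theta  # net binding rate
    return np.array(
        [
            complexation - d.k4 * p.geom.r0_bar * s,
            complexation,
            -complexation,
            s - r.k3 * theta,
        ]
    )


def integrate_wms(
    p: RTAParameters,
    t_end: float,
    out_times: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> WMSTrajectory:
    """Integrate the WMS ODEs from (uT0, uA0, 0, 0) to t_end.

    The system is mildly stiff over long horizons (rates span k3 ~ 1e-5 to
    k2*uT ~ 1e-2); the default LSODA switches to BDF as needed.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if out_times is None:
        out_times = np.linspace(0.0, t_end, 201)
    out_times = np.asarray(out_times, dtype=float)
    if out_times.size and (out_times[0] < 0 or out_times[-1] > t_end):
        raise ValueError("out_times must lie within [0, t_end]")
    y0 = np.array([p.ib.uT0, p.ib.uA0, 0.0, 0.0])
    sol = solve_ivp(
        wms_rhs,
        (0.0, t_end),
        y0,
        method=method,
        t_eval=out_times,
        args=(p,),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"WMS integration failed at t={sol.t[-1]:g}: {sol.message}")
    uT, uA, uC, theta = sol.y
    return WMSTrajectory(
        t=sol.t, uT=uT, uA=uA, uC=uC, theta=theta, rtol=rtol, atol=atol, method=method
    )


def _steady_state_residual(theta: float, uT0: float, uA0: float, d: DerivedConstants) -> float:
    """Residual of the closed steady-state equation (k3 = 0):
    (1-theta)(uT0 - R0 theta - eps uA0 theta / (1 + (eps-1) theta)) - K2 theta.
    """
    speciation = d.eps * uA0 * theta / (1.0 + (d.eps - 1.0) * theta)
    return (1.0 - theta) * (uT0 - d.R0 * theta - speciation) - d.K2 * theta


def steady_state_theta(
    p: RTAParameters,
    uA0: float | None = None,
    xtol: float = 1e-14,
) -> float:
    """Equilibrium receptor occupancy without internalization (k3 = 0).

    Solves the closed scalar equation for theta in [0, 1] by bracketed
    root-finding.  ``uA0`` overrides the antibody concentration of ``p``
    (pass 0.0 for the antibody-free scenario).
    """
    if uA0 is None:
        uA0 = p.ib.uA0
    if uA0 < 0:
        raise ValueError("uA0 must be >= 0")
    uT0 = p.ib.uT0
    if uT0 == 0.0:
        return 0.0
    d = derived_constants(p)
    f0 = _steady_state_residual(0.0, uT0, uA0, d)
    f1 = _steady_state_residual(1.0, uT0, uA0, d)
    if f0 == 0.0:
        return 0.0
    if f1 == 0.0:
        return 1.0
    if f0 * f1 > 0:
        raise RuntimeError(
            "no sign change of the steady-state residual on [0, 1]: "
            f"f(0)={f0:g}, f(1)={f1:g} (uT0={uT0:g}, uA0={uA0:g})"
        )
    return brentq(_steady_state_residual, 0.0, 1.0, args=(uT0, uA0, d), xtol=xtol)


def closed_form_F(x: float, y: float, d: DerivedConstants) -> float:
    """Explicit approximation to the equilibrium occupancy.

    F(x, y) with x the antibody and y the toxin initial concentration:
    the minus-branch root of the quadratic q2 F^2 - q1 F + y = 0 with
    q1 = K2 + eps*x - (eps - 2) y and q2 = q1 - (eps K2 + y).  Valid in the
    regime R0/(eps uA0) << 1 where receptor depletion of toxin is
    negligible.
    """
    if y == 0.0:
        return 0.0
    q1 = d.K2 + d.eps * x - (d.eps - 2.0) * y
    q2 = q1 - (d.eps * d.K2 + y)
    if q2 == 0.0:
        raise ValueError(f"closed form degenerate: q2 = 0 at x={x:g}, y={y:g}")
    disc = q1 * q1 - 4.0 * q2 * y
    if disc < 0:
        raise ValueError(
            f"closed form undefined: negative discriminant {disc:g} at x={x:g}, y={y:g}"
        )
    return (q1 - math.sqrt(disc)) / (2.0 * q2)


def psi_sat_wms(
    p: RTAParameters,
    method: str = "root",
    t_long: float = T_LONG_DEFAULT,
    rtol: float = 1e-10,
) -> float:
    """Saturation protection factor from the WMS model.

    psi_sat = theta_sat(with antibody)/theta_sat(without antibody).
    Methods: "root" (psi2, steady-state equation), "closed_form" (psi3,
    quadratic approximation) and "long_time" (psi4, occupancy ratio at
    t = t_long from full integration).  The steady-state routes neglect
    internalization; with k3 > 0 they fall through to "long_time" with a
    warning.
    """
    uA0 = p.ib.uA0
    if uA0 == 0.0:
        return 1.0
    if p.ib.uT0 == 0.0:
        raise ValueError("psi_sat undefined: uT0 = 0 gives zero occupancy")
    if method in ("root", "closed_form") and p.rates.k3 != 0.0:
        warnings.warn(
            "steady-state psi_sat is derived for k3 = 0; "
            "using long-time integration instead",
            stacklevel=2,
        )
        method = "long_time"
    if method == "root":
        return steady_state_theta(p, uA0) / steady_state_theta(p, 0.0)
    if method == "closed_form":
        d = derived_constants(p)
        return closed_form_F(uA0, p.ib.uT0, d) / closed_form_F(0.0, p.ib.uT0, d)
    if method == "long_time":
        out = np.array([0.0, t_long])
        num = integrate_wms(p, t_long, out, rtol=rtol).theta[-1]
        den = integrate_wms(p.replace(uA0=0.0), t_long, out, rtol=rtol).theta[-1]
        if den == 0.0:
            raise ValueError("psi_sat undefined: antibody-free occupancy is zero")
        return num / den
    raise ValueError(f"unknown method {method!r}")


def conservation_residuals(
    traj: WMSTrajectory, p: RTAParameters
) -> dict[str, np.ndarray]:
    """Residuals of the WMS conservation laws at each output time.

    "antibody": |uA + uC - uA0| (exact for any k3); "toxin":
    |uT + uC + k4 r0 theta - uT0|, exact only when k3 = 0 (with
    internalization the residual equals the toxin internalized so far and
    grows monotonically).
    """
    d = derived_constants(p)
    antibody = np.abs(traj.uA + traj.uC - p.ib.uA0)
    toxin = np.abs(
        traj.uT + traj.uC + d.k4 * p.geom.r0_bar * traj.theta - p.ib.uT0
    )
    return {"antibody": antibody, "toxin": toxin}
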