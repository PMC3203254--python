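"""Closed-form transport diagnostics for toxin uptake by a spherical cell.

These are the steady-state, lumped-parameter relations that classify the
uptake regime without solving the PDE system: the series conductance of
internalization and diffusion, the bioavailability number L, the long-time
asymptote of the protection factor, the mean (effective) diffusivity of the
toxin/complex mixture under fast complexation, and the relation between the
compartment radius and the cell packing density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .parameters import DerivedConstants, Geometry

__all__ = [
    "TransportDiagnostics",
    "conductance",
    "bioavailability",
    "classify_regime",
    "psi_asymptote",
    "mean_diffusivity",
    "compartment_from_density",
    "density_from_compartment",
    "gamma_from_decay",
    "DecayFit",
]


@dataclass(frozen=True)
class TransportDiagnostics:
    """Aggregated regime diagnostics.

    Lambda: reciprocal conductance (inf when uptake vanishes); J: steady
    uptake flux; kappa_star: effective diffusivity; p_ratio = kappa_star/
    kappa_T; L: bioavailability number; L0: its antibody-free counterpart
    K_star k3 rho_c / kappa_T; psi_star: protection-factor asymptote
    prefactor; gamma: depletion-rate difference 1/tau_d - 1/tau_d0.
    """

    Lambda: float
    J: float
    kappa_star: float
    p_ratio: float
    L: float
    L0: float
    psi_star: float
    gamma: float
    regime: str


def conductance(
    d: DerivedConstants,
    geom: Geometry,
    kappa_star: float,
    k3: float,
    uT_outer: float,
) -> tuple[float, float]:
    """Reciprocal conductance Lambda and steady uptake flux J.

    Lambda = 1/(k3 K_star) + rho_c/kappa_star chains the internalization
    and diffusion resistances in series; J = uT_outer/Lambda.  With no
    internalization (k3 K_star = 0) the conductance vanishes: Lambda is
    reported as math.inf and J as 0.
    """
    if not kappa_star > 0:
        raise ValueError("kappa_star must be > 0")
    uptake = k3 * d.K_star
    if uptake < 0:
        raise ValueError("k3 K_star must be >= 0")
    if uptake == 0.0:
        return math.inf, 0.0
    Lambda = 1.0 / uptake + geom.rho_c / kappa_star
    return Lambda, uT_outer / Lambda


def bioavailability(
    d: DerivedConstants, geom: Geometry, kappa_star: float, k3: float
) -> float:
    """Bioavailability number L = K_star k3 rho_c / kappa_star: the ratio
    of internalization conductance to diffusive conductance."""
    if not kappa_star > 0:
        raise ValueError("kappa_star must be > 0")
    return d.K_star * k3 * geom.rho_c / kappa_star


def classify_regime(L: float) -> str:
    """Regime label from L.  The limiting cases are L << 1 (uptake
    controlled by internalization kinetics) and L >> 1 (by diffusion); the
    cutoffs 0.1 and 10 are a reporting convention."""
    if L < 0.1:
        return "internalization-controlled"
    if L > 10.0:
        return "diffusion-controlled"
    return "mixed"


def psi_asymptote(
    L0: float, p_ratio: float, gamma: float = 0.0, t: float | np.ndarray = 0.0
) -> tuple[float, float | np.ndarray]:
    """Long-time protection-factor asymptote.

    psi_star = (1 + L0)/(1 + L0/p) with p = kappa_star/kappa_T >= 1, and
    psi(t) ~ psi_star exp(gamma t) where gamma = 1/tau_d - 1/tau_d0 is the
    depletion-rate difference (gamma = 0 for constant boundary influx).
    Satisfies 1 <= psi_star <= min(p, 1 + L0).
    """
    if p_ratio < 1.0:
        raise ValueError("p_ratio = kappa_star/kappa_T must be >= 1")
    if L0 < 0:
        raise ValueError("L0 must be >= 0")
    psi_star = (1.0 + L0) / (1.0 + L0 / p_ratio)
    return psi_star, psi_star * np.exp(gamma * np.asarray(t, dtype=float))


def mean_diffusivity(uT: float, uC: float, kappa_T: float, kappa_C: float) -> float:
    """Concentration-weighted mean diffusivity of free toxin and complex,
    kappa_star = (uT kappa_T + uC kappa_C)/(uT + uC).

    Valid in the fast-complexation (labile) regime where toxin and complex
    equilibrate quickly relative to diffusion; the antibody's own
    diffusivity does not enter.
    """
    tot = uT + uC
    if not tot > 0:
        raise ValueError("uT + uC must be > 0")
    return (uT * kappa_T + uC * kappa_C) / tot


def compartment_from_density(n: float) -> float:
    """Compartment radius rho_e = (3/(4 pi n))^(1/3) of a cell in a
    uniformly packed culture with cell number density n."""
    if not n > 0:
        raise ValueError("cell density must be > 0")
    return (3.0 / (4.0 * math.pi * n)) ** (1.0 / 3.0)


def density_from_compartment(rho_e: float) -> float:
    """Inverse of :func:`compartment_from_density`."""
    if not rho_e > 0:
        raise ValueError("rho_e must be > 0")
    return 3.0 / (4.0 * math.pi * rho_e**3)


@dataclass(frozen=True)
class DecayFit:
    """Result of an exponential-depletion fit uT(t) = uT(0) exp(-t/tau_d)."""

    inv_tau: float
    log_residual: float
    reliable: bool
    note: str = ""


def gamma_from_decay(
    t: np.ndarray, uT_series: np.ndarray
) -> DecayFit:
    """Fit 1/tau_d by least squares on log uT(t) vs t.

    The series must be strictly positive.  A non-decaying series yields an
    unreliable fit flagged with inv_tau clamped per the gamma = 0 (no
    depletion) convention.
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(uT_series, dtype=float)
    if t.shape != u.shape or t.size < 2:
        raise ValueError("need matching t and uT arrays with >= 2 points")
    if np.any(u <= 0):
        raise ValueError("uT series must be strictly positive for a log fit")
    logu = np.log(u)
    if np.allclose(logu, logu[0], atol=1e-12):
        warnings.warn("constant uT series: no depletion, 1/tau_d = 0", stacklevel=2)
        return DecayFit(inv_tau=0.0, log_residual=0.0, reliable=True,
                        note="constant series; no depletion")
    slope, intercept = np.polyfit(t, logu, 1)
    resid = float(np.sqrt(np.mean((logu - (slope * t + intercept)) ** 2)))
    if slope >= 0:
        warnings.warn("uT series is not decaying; depletion fit unreliable", stacklevel=2)
        return DecayFit(inv_tau=max(-slope, 0.0), log_residual=resid, reliable=False,
                        note="non-decaying series")
    return DecayFit(inv_tau=-float(slope), log_residual=resid, reliable=True)


def diagnostics(
    d: DerivedConstants,
    geom: Geometry,
    kappa_T: float,
    kappa_star: float,
    k3: float,
    uT_outer: float,
    inv_tau_d: float = 0.0,
    inv_tau_d0: float = 0.0,
) -> TransportDiagnostics:
    """Assemble the full diagnostics record from primitive inputs.

    Depletion times are user-supplied (as reciprocals) or fitted from
    simulation output with :func:`gamma_from_decay`; they default to the
    no-depletion case gamma = 0.
    """
    Lambda, J = conductance(d, geom, kappa_star, k3, uT_outer)
    L = bioavailability(d, geom, kappa_star, k3)
    L0 = d.K_star * k3 * geom.rho_c / kappa_T
    p_ratio = kappa_star / kappa_T
    gamma = inv_tau_d - inv_tau_d0
    psi_star, _ = psi_asymptote(L0, max(p_ratio, 1.0), gamma)
    return TransportDiagnostics(
        Lambda=Lambda,
        J=J,
        kappa_star=kappa_star,
        p_ratio=p_ratio,
        L=L,
        L0=L0,
        psi_star=psi_star,
        gamma=gamma,
        regime=classify_regime(L),
    )
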