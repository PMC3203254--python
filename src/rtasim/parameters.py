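"""Model parameters for the receptor-toxin-antibody (RTA) system.

The model describes a toxin T, an antibody A and their complex C diffusing
in a spherical shell of medium around a single cell, with surface receptors
that bind toxin reversibly and internalize it.  All internal computation is
nondimensional; dimensional inputs are converted once, on the way in, using
explicit concentration/time/length scales.

Concentration scale convention: concentrations are number densities (cm^-3).
Second-order rate constants given in molar units (M^-1 s^-1) are converted to
number-density units with Avogadro's number before nondimensionalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

AVOGADRO = 6.02214076e23  # mol^-1

UnitFlag = Literal["nondimensional", "molar", "number_density"]


@dataclass(frozen=True)
class Scales:
    """Nondimensionalization scales: concentration u_star (cm^-3),
    time tau_star (s), length l (cm)."""

    u_star: float
    tau_star: float
    l: float

    def violations(self) -> list[str]:
        out = []
        for name in ("u_star", "tau_star", "l"):
            if not getattr(self, name) > 0:
                out.append(f"scales.{name} must be strictly positive")
        return out


@dataclass(frozen=True)
class RateConstants:
    """Mass-action rate constants.

    k1/k_m1: toxin-antibody association/dissociation;
    k2/k_m2: toxin-receptor association/dissociation;
    k3: internalization rate of receptor-bound toxin.
    """

    k1: float
    k_m1: float
    k2: float
    k_m2: float
    k3: float

    def violations(self) -> list[str]:
        return [
            f"rates.{name} must be >= 0"
            for name in ("k1", "k_m1", "k2", "k_m2", "k3")
            if getattr(self, name) < 0
        ]


@dataclass(frozen=True)
class Diffusivities:
    """Diffusivities of toxin, antibody and toxin-antibody complex."""

    kappa_T: float
    kappa_A: float
    kappa_C: float

    def violations(self) -> list[str]:
        return [
            f"diff.{name} must be > 0"
            for name in ("kappa_T", "kappa_A", "kappa_C")
            if not getattr(self, name) > 0
        ]


@dataclass(frozen=True)
class Geometry:
    """Spherical-shell geometry: cell radius rho_c, outer compartment radius
    rho_e, and the surface receptor concentration r0_bar (receptors per unit
    area, nondimensional)."""

    rho_c: float
    rho_e: float
    r0_bar: float

    def violations(self) -> list[str]:
        out = []
        if not self.rho_c > 0:
            out.append("geom.rho_c must be > 0")
        if not self.rho_e > self.rho_c:
            out.append("geom.rho_e must exceed rho_c")
        if not self.r0_bar > 0:
            out.append("geom.r0_bar must be > 0")
        return out


@dataclass(frozen=True)
class InitialBoundary:
    """Initial and outer-boundary concentrations.  The complex starts at zero
    and is held at zero on the outer boundary."""

    uT0: float
    uA0: float
    uC0: float = 0.0

    def violations(self) -> list[str]:
        out = []
        if self.uT0 < 0:
            out.append("ib.uT0 must be >= 0")
        if self.uA0 < 0:
            out.append("ib.uA0 must be >= 0")
        if self.uC0 != 0.0:
            out.append("ib.uC0 must be 0 at t=0")
        return out


@dataclass(frozen=True)
class RTAParameters:
    """Full parameter set of the RTA model (nondimensional by default)."""

    rates: RateConstants
    diff: Diffusivities
    geom: Geometry
    ib: InitialBoundary
    scales: Scales | None = None

    def violations(self) -> list[str]:
        out = []
        out += self.rates.violations()
        out += self.diff.violations()
        out += self.geom.violations()
        out += self.ib.violations()
        if self.scales is not None:
            out += self.scales.violations()
        return out

    def replace(self, **kw) -> "RTAParameters":
        """Return a copy with leaf fields overridden, e.g.
        ``p.replace(kappa_T=1e-3, uA0=0.0)``."""
        rates, diff, geom, ib = self.rates, self.diff, self.geom, self.ib
        scales = self.scales
        for key, val in kw.items():
            if hasattr(rates, key):
                rates = replace(rates, **{key: val})
            elif hasattr(diff, key):
                diff = replace(diff, **{key: val})
            elif hasattr(geom, key):
                geom = replace(geom, **{key: val})
            elif hasattr(ib, key):
                ib = replace(ib, **{key: val})
            elif scales is not None and hasattr(scales, key):
                scales = replace(scales, **{key: val})
            else:
                raise KeyError(f"unknown parameter field {key!r}")
        return RTAParameters(rates=rates, diff=diff, geom=geom, ib=ib, scales=scales)


@dataclass(frozen=True)
class DerivedConstants:
    """Constants derived from the primary parameters.

    K1 = k_m1/k1 and K2 = k_m2/k2 are the dissociation constants of the
    toxin-antibody and toxin-receptor reactions; eps = K2/K1; b = k3/k2;
    k4 = S_c/V_Omega is the surface-to-volume ratio of the shell;
    R0 = r0_bar * k4 is the receptor concentration referred to the shell
    volume; K_star = R0/(R0 + K1).
    """

    K1: float
    K2: float
    eps: float
    b: float
    k4: float
    R0: float
    K_star: float


class ParameterError(ValueError):
    """Raised for invalid, inconsistent or un-convertible parameter sets."""


def validate(p: RTAParameters) -> list[str]:
    """Return a list of invariant violations (empty when the set is valid)."""
    return p.violations()


def derived_constants(p: RTAParameters) -> DerivedConstants:
    """Compute the derived constants used by the steady-state and transport
    analyses.  Requires k1 > 0 and k2 > 0 (the dissociation-constant ratios
    are undefined otherwise) and rho_e > rho_c."""
    r = p.rates
    g = p.geom
    if r.k1 <= 0:
        raise ParameterError("K1 = k_m1/k1 undefined: k1 must be > 0")
    if r.k2 <= 0:
        raise ParameterError("K2 = k_m2/k2 undefined: k2 must be > 0")
    if not g.rho_e > g.rho_c:
        raise ParameterError("k4 undefined: rho_e must exceed rho_c")
    K1 = r.k_m1 / r.k1
    K2 = r.k_m2 / r.k2
    eps = K2 / K1 if K1 > 0 else math.inf
    b = r.k3 / r.k2
    k4 = 3.0 * g.rho_c**2 / (g.rho_e**3 - g.rho_c**3)
    R0 = g.r0_bar * k4
    K_star = R0 / (R0 + K1) if (R0 + K1) > 0 else 0.0
    return DerivedConstants(K1=K1, K2=K2, eps=eps, b=b, k4=k4, R0=R0, K_star=K_star)


def nondimensionalize(p: RTAParameters, units: UnitFlag = "number_density") -> RTAParameters:
    """Convert a dimensional parameter set to nondimensional form.

    Second-order rates scale as k_bar = tau* u* k, first-order rates as
    k_bar = tau* k, diffusivities as kappa_bar = tau* kappa / l^2, lengths
    divide by l, concentrations by u*.  With ``units="molar"`` the
    second-order rate constants are taken in M^-1 s^-1 and converted to
    cm^3 s^-1 via Avogadro's number first.
    """
    if p.scales is None:
        raise ParameterError("nondimensionalize requires scales")
    bad = p.scales.violations()
    if bad:
        raise ParameterError("; ".join(bad))
    if units not in ("molar", "number_density"):
        raise ParameterError(f"unknown unit flag {units!r}")
    bad = p.violations()
    if bad:
        raise ParameterError("; ".join(bad))
    s = p.scales
    # 1 M^-1 s^-1 = 1 L mol^-1 s^-1 = 1e3 cm^3 mol^-1 s^-1
    # = (1e3/N_A) cm^3 s^-1 per molecule per cm^3
    conv2 = 1e3 / AVOGADRO if units == "molar" else 1.0
    r = p.rates
    rates = RateConstants(
        k1=s.tau_star * s.u_star * (r.k1 * conv2),
        k_m1=s.tau_star * r.k_m1,
        k2=s.tau_star * s.u_star * (r.k2 * conv2),
        k_m2=s.tau_star * r.k_m2,
        k3=s.tau_star * r.k3,
    )
    dfac = s.tau_star / s.l**2
    diff = Diffusivities(
        kappa_T=p.diff.kappa_T * dfac,
        kappa_A=p.diff.kappa_A * dfac,
        kappa_C=p.diff.kappa_C * dfac,
    )
    geom = Geometry(
        rho_c=p.geom.rho_c / s.l,
        rho_e=p.geom.rho_e / s.l,
        # r0 = l u* r0_bar  =>  r0_bar = r0/(l u*)
        r0_bar=p.geom.r0_bar / (s.l * s.u_star),
    )
    ib = InitialBoundary(
        uT0=p.ib.uT0 / s.u_star,
        uA0=p.ib.uA0 / s.u_star,
        uC0=p.ib.uC0 / s.u_star,
    )
    return RTAParameters(rates=rates, diff=diff, geom=geom, ib=ib, scales=p.scales)


def redimensionalize(p: RTAParameters, units: UnitFlag = "number_density") -> RTAParameters:
    """Inverse of :func:`nondimensionalize` with the same scales."""
    if p.scales is None:
        raise ParameterError("redimensionalize requires scales")
    s = p.scales
    conv2 = 1e3 / AVOGADRO if units == "molar" else 1.0
    r = p.rates
    rates = RateConstants(
        k1=r.k1 / (s.tau_star * s.u_star * conv2),
        k_m1=r.k_m1 / s.tau_star,
        k2=r.k2 / (s.tau_star * s.u_star * conv2),
        k_m2=r.k_m2 / s.tau_star,
        k3=r.k3 / s.tau_star,
    )
    dfac = s.tau_star / s.l**2
    diff = Diffusivities(
        kappa_T=p.diff.kappa_T / dfac,
        kappa_A=p.diff.kappa_A / dfac,
        kappa_C=p.diff.kappa_C / dfac,
    )
    geom = Geometry(
        rho_c=p.geom.rho_c * s.l,
        rho_e=p.geom.rho_e * s.l,
        r0_bar=p.geom.r0_bar * s.l * s.u_star,
    )
    ib = InitialBoundary(
        uT0=p.ib.uT0 * s.u_star,
        uA0=p.ib.uA0 * s.u_star,
        uC0=p.ib.uC0 * s.u_star,
    )
    return RTAParameters(rates=rates, diff=diff, geom=geom, ib=ib, scales=p.scales)


#: Named parameter presets.  "default" is the canonical nondimensional set:
#: rho_e = 2, uT0 = 0.5, uA0 = 1.  Alternates change one field each.
_PRESETS = {
    "default": {},
    "rho_e_5": {"rho_e": 5.0},
    "uT0_0.1": {"uT0": 0.1},
}


def table2_defaults(preset: str = "default") -> RTAParameters:
    """The canonical nondimensional parameter set used throughout.

    Rates: k1=1.3e-2, k_m1=1.4e-4, k2=1.25e-2, k_m2=5.2e-4, k3=3.3e-5;
    diffusivities 1e-2 for all species; rho_c=0.1, rho_e=2, r0_bar=2.115e-3;
    uT0=0.5, uA0=1.  Presets: "rho_e_5" (larger compartment), "uT0_0.1"
    (lower toxin dose).
    """
    if preset not in _PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(_PRESETS)}"
        )
    p = RTAParameters(
        rates=RateConstants(k1=1.3e-2, k_m1=1.4e-4, k2=1.25e-2, k_m2=5.2e-4, k3=3.3e-5),
        diff=Diffusivities(kappa_T=1e-2, kappa_A=1e-2, kappa_C=1e-2),
        geom=Geometry(rho_c=0.1, rho_e=2.0, r0_bar=2.115e-3),
        ib=InitialBoundary(uT0=0.5, uA0=1.0),
        scales=Scales(u_star=6.02e13, tau_star=1.0, l=1e-2),
    )
    if _PRESETS[preset]:
        p = p.replace(**_PRESETS[preset])
    return p
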