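"""Closed-form transport diagnostics: uptake regime and psi asymptote.

Classifies toxin uptake by the bioavailability number L (internalization
conductance over diffusive conductance), evaluates the steady uptake flux
through the series-conductance formula, and shows how the effective
diffusivity of the toxin/complex mixture bounds the long-time protection
factor.
"""

from rtasim import (
    bioavailability,
    classify_regime,
    compartment_from_density,
    conductance,
    density_from_compartment,
    derived_constants,
    mean_diffusivity,
    psi_asymptote,
    table2_defaults,
)

p = table2_defaults()
d = derived_constants(p)

for kappa_star in (1e-2, 1e-6):
    L = bioavailability(d, p.geom, kappa_star, p.rates.k3)
    Lam, J = conductance(d, p.geom, kappa_star, p.rates.k3, p.ib.uT0)
    print(f"kappa* = {kappa_star:g}: L = {L:.3e} ({classify_regime(L)}), "
          f"Lambda = {Lam:.4g}, J = {J:.3e}")

print()
kappa_star = mean_diffusivity(uT=0.2, uC=0.8, kappa_T=1e-2, kappa_C=1e-3)
print(f"mean diffusivity of a 20/80 toxin/complex mixture: {kappa_star:.2e}")
L0 = 1.0
psi_star, _ = psi_asymptote(L0=L0, p_ratio=2.0)
print(f"psi asymptote at L0 = {L0}, p = 2: psi* = {psi_star:.4f} "
      f"(bounded by 1 <= psi* <= 1 + L0)")

print()
n = density_from_compartment(2.0)
print(f"compartment radius rho_e = 2 corresponds to cell density n = {n:.4f};")
print(f"inverse check: rho_e({n:.4f}) = {compartment_from_density(n):.4f}")
print()
print("Small L means uptake is limited by internalization kinetics, not by")
print("diffusion; psi* > 1 shows that in a diffusion-limited regime a fast-")
print("diffusing complex can even increase the toxin flux toward the cell.")
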