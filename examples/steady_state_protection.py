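"""Saturation protection factor from the well-mixed model.

Computes the long-time antibody protection factor psi_sat — the ratio of
receptor-bound toxin with antibody present to without — three ways: by
solving the steady-state occupancy equation (psi2), by its closed-form
quadratic approximation (psi3), and by integrating the ODE system to
t = 1e4 (psi4).  Lower psi = stronger protection.
"""

from rtasim import psi_sat_wms, table2_defaults

p = table2_defaults().replace(k3=0.0)  # steady-state theory assumes no internalization

print(f"{'k1':>8} {'k2':>8} {'psi2':>10} {'psi3':>10} {'psi4':>10}")
for k1, k2 in [(1.3e-2, 1.25e-2), (1.3e-2, 2.5e-2), (1.3e-2, 5e-2), (0.13, 1.25e-2)]:
    q = p.replace(k1=k1, k2=k2)
    psi2 = psi_sat_wms(q, "root")
    psi3 = psi_sat_wms(q, "closed_form")
    psi4 = psi_sat_wms(q, "long_time")
    print(f"{k1:8.3g} {k2:8.4g} {psi2:10.6f} {psi3:10.6f} {psi4:10.6f}")

print()
print("psi ~ 0.22 for the base rates: the antibody blocks ~78% of receptor-")
print("bound toxin at saturation. A faster toxin-antibody on-rate k1 (last")
print("row) drives psi down to ~0.027 (97% blocked); a faster toxin-receptor")
print("on-rate k2 lets the receptors outcompete the antibody and psi rises.")
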