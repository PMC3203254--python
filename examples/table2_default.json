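{
  "rates": {"k1": 1.3e-2, "k_m1": 1.4e-4, "k2": 1.25e-2, "k_m2": 5.2e-4, "k3": 3.3e-5},
  "diffusivities": {"kappa_T": 1e-2, "kappa_A": 1e-2, "kappa_C": 1e-2},
  "geometry": {"rho_c": 0.1, "rho_e": 2.0, "r0_bar": 2.115e-3},
  "initial": {"uT0": 0.5, "uA0": 1.0},
  "units": "nondimensional",
  "solver": {"N": 401, "dt": 0.5}
}
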