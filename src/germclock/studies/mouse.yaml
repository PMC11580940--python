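# Lindsay et al. 2019 pedigrees: published regression-based decomposition
# (the per-offspring count data are not redistributed here; the trio
# regression route is exercised on simulated pedigrees instead).
species: mouse
kind: decomposition
mu_E: 3.75e-9
mu_gam: 1.64e-9
mu_E_bounds: [2.89e-9, 4.6e-9]
mu_gam_bounds: [4.10e-10, 2.85e-9]
puberty_age: 0.15
generation_time: 0.75
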