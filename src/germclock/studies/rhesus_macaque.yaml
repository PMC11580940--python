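# Wang et al. 2020: combined parental-age slope and mutation load at puberty,
# already per site, used without further transformation.
species: rhesus_macaque
kind: slope_intercept
slope: 4.3e-10
intercept: 3.9e-9
intercept_offset_years: 0.0
puberty_age: 3.5
generation_time: 8.0
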