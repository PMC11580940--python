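# Thomas et al. 2018: per-site parental-age slope and y-intercept; one year
# of gamete accumulation is added to the intercept to reach the load at
# puberty (age 1).
species: owl_monkey
kind: slope_intercept
slope: 6.62e-10
intercept: 3.74e-9
intercept_offset_years: 1.0
puberty_age: 1.0
generation_time: 6.6
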