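# Wang et al. 2022: rate at puberty (0.5 y) and mean rate over the observed
# reproductive span (mean reproductive age 3.8 y).
species: domestic_cat
kind: mean_rate
rate_at_puberty: 5.9e-9
mean_rate: 8.6e-9
puberty_age: 0.5
mean_reproductive_age: 3.8
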