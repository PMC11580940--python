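# Zhang et al. 2024: sex-specific slopes/intercepts read off the published
# bar plots, already per site; puberty taken as 1 year.
species: domestic_dog
kind: sex_specific
units: per_site
maternal_slope: 1.0e-10
paternal_slope: 3.5e-10
maternal_intercept: 8.0e-10
paternal_intercept: 2.5e-9
maternal_ref_age: 0.0
paternal_ref_age: 0.0
puberty_age: 1.0
generation_time: 4.0
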