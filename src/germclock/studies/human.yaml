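# Jonsson et al. 2017 sex-specific Poisson regression of DNM counts on
# parental age (per diploid genome; intercepts extrapolated to age 0).
species: human
kind: sex_specific
units: per_genome
maternal_slope: 0.37
paternal_slope: 1.51
maternal_intercept: 3.61
paternal_intercept: 6.05
maternal_ref_age: 0.0
paternal_ref_age: 0.0
accessible_haploid_size: 2722501677
puberty_age: 13.0
generation_time: 30.0
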