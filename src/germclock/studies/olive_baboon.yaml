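# Wu et al. 2020 sex-specific regression (per diploid genome); intercepts
# apply at the source's earliest observed ages rather than at birth.  Note:
# the published summary values (mu_E = 5.0e-9, mu_gam = 1.4e-10) round
# differently from what these inputs yield (about 5.1e-9 and 1.55e-10), so
# this species is a documented approximate case.
species: olive_baboon
kind: sex_specific
units: per_genome
maternal_slope: 0.65
paternal_slope: 0.15
maternal_intercept: 0.23
paternal_intercept: 22.16
maternal_ref_age: 0.55
paternal_ref_age: 0.15
accessible_haploid_size: 2.581e9
puberty_age: 5.41
generation_time: 10.0
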