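# Venn et al. paternal age effect (per diploid genome per year; the source's
# "per site" wording is a typo — the arithmetic divides by genome size);
# maternal contribution is a flat 6.65 mutations per generation.
species: chimpanzee
kind: sex_specific
units: per_genome
maternal_slope: 0.0
paternal_slope: 2.95
maternal_intercept: 6.65
paternal_intercept: -23.8
maternal_ref_age: 0.0
paternal_ref_age: 0.0
accessible_haploid_size: 2.36e9
puberty_age: 14.0
generation_time: 25.0
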