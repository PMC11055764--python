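variant_name,upstream,stop_codon,downstream,plus_four,cdna_codon_index,stop_class_provenance,plus_four_provenance
p.S49X,,TAA,,,49,stated,unverified
p.S68X,,TGA,,G,68,stated,stated
p.Y141X,,TAG,,T,141,stated,stated
p.R168X,,TGA,,G,168,stated,stated
p.K175X,,TAG,,C,175,stated,stated
p.K177X,,TAA,,,177,stated,unverified
p.R198X,,TGA,,C,198,stated,stated
p.S204X,,TGA,,G,204,stated,stated
p.Q244X,,TAG,,G,244,stated,stated
p.R255X,,TGA,,A,255,stated,stated
p.R270X,,TGA,,A,270,stated,stated
p.R294X,,TAG,,,294,inferred-by-count,unverified
p.K363X,,TAG,,,363,stated,unverified
p.Q406X,,TAG,,,406,stated,unverified
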