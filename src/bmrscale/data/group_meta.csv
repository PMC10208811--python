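# Clade-level metadata for the nine vertebrate groups used in the
# cross-clade regressions. Divergence times (mya) and extant species
# counts are published clade values; sleep_h and tb_c are reconstructed
# group means (synthetic summaries compiled from secondary sleep and
# body-temperature literature; see docs/methods.md) and are only
# populated for the six endotherm groups.
group,mya,sleep_h,tb_c,n_species
Fishes,465,,,25000
Amphibia,365,,,4000
Reptilia,322,,,8000
Monotremata,217,14.0,32.0,4
Marsupialia,193,13.0,35.5,346
Eutheria,115,10.8,37.0,5136
Palaeognathae,110,9.5,38.3,57
Non-Passeriformes,90,9.0,39.8,4000
Passeriformes,50,8.5,40.5,6000
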