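# Published per-clade allometric summaries (basal/standard metabolic
# rate, ml O2/h, mass in g). a_common is the allometric coefficient
# refitted at the endotherm common slope b = 0.7248 (ectotherms at
# b = 0.840); b_ols is the clade's own OLS scaling exponent (blank for
# Monotremata, n = 3, excluded from exponent comparisons); a_ols and
# bmr_ratio are only defined for the six endotherm clades; n_bmr is the
# number of species with BMR measurements behind each endotherm fit.
group,mya,a_common,b_ols,a_ols,bmr_ratio,n_bmr
Fishes,465,0.264,0.88,,,
Amphibia,365,0.366,0.88,,,
Reptilia,322,0.398,0.76,,,
Monotremata,217,1.63,,5.861,0.264,3
Marsupialia,193,2.69,0.75,2.3,0.435,84
Eutheria,115,3.53,0.74,3.326,0.571,730
Palaeognathae,110,3.29,0.73,3.221,0.532,9
Non-Passeriformes,90,4.65,0.69,5.507,0.752,404
Passeriformes,50,6.18,0.67,7.379,1.000,587
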