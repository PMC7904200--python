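# Literature-derived trophic enrichment / discrimination factor presets.
# TEF: bulk diet-to-tissue enrichment per isotope (permil).
# TDF: amino-acid (Glu - Phe) discrimination per trophic level, with beta
#      (trophic-source spread in primary producers).
tef:
  madigan-muscle:
    tissue: muscle
    dC_mean: 1.8
    dC_sd: 0.0
    dN_mean: 1.9
    dN_sd: 0.4
  madigan-muscle-bayes-c:
    # variant with the carbon enrichment used in the Bayesian TP row
    tissue: muscle
    dC_mean: 1.1
    dC_sd: 0.6
    dN_mean: 1.9
    dN_sd: 0.4
  madigan-liver:
    tissue: liver
    dC_mean: 1.2
    dC_sd: 0.0
    dN_mean: 1.1
    dN_sd: 0.0
tdf:
  bradley-tuna:
    tdf_mean: 6.3
    tdf_sd: 0.4
    beta_mean: 3.4
    beta_sd: 0.9
  bradley-teleost:
    tdf_mean: 5.7
    tdf_sd: 0.3
    beta_mean: 3.4
    beta_sd: 0.9
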