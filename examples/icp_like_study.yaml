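# A synthetic study shaped like the ICP -> cardiovascular-disease analysis:
# 11 strong instruments from a ~155k-sample exposure GWAS, a ~485k-sample
# binary outcome GWAS, and a small true log-odds effect (OR ~ 1.004).
seed: 20240430
simulate:
  n_snps: 11
  n_exposure: 154780
  n_outcome: 484598
  gamma_sd: 0.5
  theta: 0.004
exposure_label: ICP-like exposure
outcome_label: CVD-like outcome
presso_n_sim: 1000
n_boot: 1000
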