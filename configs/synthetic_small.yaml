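# Small synthetic dataset for quick end-to-end runs of every subcommand.
simulate:
  n_genes: 400
  de_fraction: 0.15
  effect_size_log2: 2.0
  noise_sd: 0.25
  term_size: 30
  term_overlap: 20
  n_background_terms: 30

de:
  sam_n_perm: 100

stem:
  n_perm: 500

network:
  threshold: 0.6
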