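# Demo pipeline: simulate a paired-trait dataset, run every stage.
seed: 7
stages: [simulate, gwas, clump, conjfdr, ldsc, greml, clinical]
n_ref: 500
simulation:
  m_snps: 4000
  n1: 30000
  n2: 30000
  block_size: 25
  block_rho: 0.8
  pi_shared: 0.01
  sign_concordance: 0.7
  h2_a: 0.4
  h2_b: 0.4
gwas:
  h2: 0.4
  n_causal: 40
conjfdr:
  n_prune: 10
  threshold: 0.05
clinical:
  n_cases: 150
  n_controls: 300
  effects:
    scz: {pons: -0.4, wbs: -0.3}
    pd: {midbrain: 0.4}
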