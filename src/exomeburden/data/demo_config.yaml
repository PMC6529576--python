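outdir: demo_run
seed: 11
stages:
  simulate: true
  filter: true
  annotate: true
  burden: true
  dnds: true
  signatures: true
  enrich: true
  validate_external: false
genome:
  n_genes: 80
  mean_cds_length: 600
cohort:
  n_patients: 10
  somatic_rate: 600
  germline_rate: 150
  burden_effects:
  - - G0010
    - 20.0
  - - G0042
    - 15.0
  - - G0007
    - 12.0
  - - G0033
    - 10.0
  - - G0055
    - 8.0
  - - G0071
    - 6.0
  mortality_fraction: 0.4
catalog: synthetic
gmt: src/exomeburden/data/demo_library.gmt
burden_alpha: 0.05
signature_threshold: 0.05
n_bootstrap: 100
subsampling:
  n_subsamples: 200
  size_min: 8
  size_max: 20
  alpha: 0.05
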