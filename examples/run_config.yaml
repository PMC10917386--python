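# Full-pipeline configuration for `cpmconn run --config ... --out ...`
# (also loadable with cpmconn.load_config). Omitted keys take the study
# defaults; `paths` may replace `simulate` to analyse data on disk, e.g.
#   paths:
#     model:      {edges: model_edges.csv,      pheno: model_pheno.csv}
#     validation: {edges: validation_edges.csv, pheno: validation_pheno.csv}

seed: 1                      # mandatory; drives every random draw
simulate:
  n_model: 150
  n_validation: 170
  n_control: 36
  n_nodes: 160
  n_true_edges: 40
filter:
  mfd_max: 0.2
  min_site_size: 20
harmonize: true
harmonize_mode: parametric   # or: nonparametric
p_threshold: 0.01
n_perm: 200                  # study default is 1000; 200 keeps a demo quick
tail: both
scores: [total, communication]
subtypes: [all, CA]
min_n: 30
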