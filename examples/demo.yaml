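# Demo run: every scaling method x every classifier family on a simulated
# cohort with an age-threshold confounder. Takes a few minutes on one CPU.
#
#   metadrift run-all --config examples/demo.yaml --outdir demo_out --auto-accept
simulate:
  n_samples: 200
  seed: 11
scaling:
  methods: [none, centering, autoscaling, pareto, range, vast, level, log10, power]
classify:
  families: [knn, ridge, svr_threshold, random_forest, dnn]
  cv_folds: 5
  epochs: 80
drift:
  replicates: 2
correction:
  strategy: segmentation
seed: 11
log_level: INFO
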