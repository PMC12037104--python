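# Minimal fast run used in the README worked example.
#
#   metadrift run-all --config examples/quickstart.yaml --outdir quickstart_out --auto-accept
simulate:
  n_samples: 500
  seed: 7
scaling:
  methods: [autoscaling]
classify:
  families: [knn]
correction:
  strategy: segmentation
seed: 7
log_level: WARNING
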