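# MS-imaging-style run: per-pixel spectra already normalized so each sample's
# total ion count sums to 1.0. The clamp setting uses the full training set
# minus the test pixel - the limit in which the local-balanced model
# coincides with the global base classifier.
name: imaging-like
seed: 0
dataset:
  kind: synthetic
  generator: drift_table
  params: {n_per_class: 40, n_features: 30}
preprocess:
  normalize_total: unit1
  scale: true
sizes: clamp
base: {name: svm}
protocol: loo
positive: Low
output: lbm_out/imaging-like
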