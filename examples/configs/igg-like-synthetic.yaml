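# Small drift-dominated two-class abundance table (synthetic stand-in for a
# 21 + 21 sample glycopeptide relative-abundance study). Compare base vs
# local-balanced:  localbalance compare examples/configs/igg-like-synthetic.yaml
name: igg-like-synthetic
seed: 0
dataset:
  kind: synthetic
  generator: drift_table
  params: {}          # defaults: 21 per class, 15 features, drift 0.85-1.15
preprocess:
  normalize_total: none   # leave the drift in; that is the point of the demo
  scale: false
sizes: {n_low: 9, n_hi: 9}
base: {name: svm, C: 1.0, gamma: auto, score: decision}
protocol: loo
positive: Low
output: lbm_out/igg-like
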