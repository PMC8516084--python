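# Imbalanced Gaussian clouds (~10% minority) where the global SVM tends to
# collapse into the majority-state model.
name: imbalanced-clouds
seed: 0
dataset:
  kind: synthetic
  generator: imbalanced_clouds
  params: {}
preprocess:
  scale: true
sizes: {n_low: 10, n_hi: 18}
base: {name: svm, score: decision}
protocol: loo
positive: Low
output: lbm_out/clouds
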