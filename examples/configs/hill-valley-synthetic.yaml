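# Synthetic noisy hill/valley traces (structural stand-in for the public
# noisy Hill-Valley benchmark; the real generation recipe is unknown).
name: hill-valley-synthetic
seed: 0
dataset:
  kind: synthetic
  generator: hill_valley
  params: {n_samples: 400}
preprocess:
  scale: true
sizes: {n_low: 90, n_hi: 90}
base: {name: svm, score: decision}
protocol: loo
positive: Low
output: lbm_out/hill-valley-synthetic
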