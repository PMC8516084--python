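# Noisy Hill-Valley benchmark (UCI; use the *with-noise* files).
# Concatenate the distribution's training+testing CSVs into one file with a
# header row and a "class" column; 1212 samples x 100 features.
name: hill-valley
seed: 0
dataset:
  kind: delimited
  path: data/hill_valley_noisy.csv
  label_column: class
  delimiter: ","
preprocess:
  scale: true
sizes: {n_low: 90, n_hi: 90}
base: {name: svm}
protocol: loo
positive: Low
output: lbm_out/hill-valley
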