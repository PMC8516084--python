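# Statlog (Landsat Satellite) benchmark: class "4" (damp grey soil) vs rest.
# Download sat.trn + sat.tst from the UCI Machine Learning Repository, convert
# to one CSV with a header row and a "class" column, and point `path` at it.
# LOO with the optimized sizes (10 minority, 18 majority).
name: satellite
seed: 0
dataset:
  kind: delimited
  path: data/satellite.csv
  label_column: class
  delimiter: ","
  target: "4"            # one-vs-rest: 4 -> Low (target), others -> Hi
preprocess:
  scale: true
sizes: {n_low: 10, n_hi: 18}
base: {name: svm}
protocol: train_test
split: {test_last: 965}   # first 5470 samples train, last 965 test
positive: Low
output: lbm_out/satellite
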