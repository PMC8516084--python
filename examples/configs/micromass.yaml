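# MicroMass bacterial MALDI-MS typing: Gram-positive vs Gram-negative.
# Download the "pure_spectra" ARFF from the UCI repository; map the genus
# labels onto the two Gram groups with an explicit label_map (Gram-positive
# genera QWP/WNJ/QBG/RTO -> Low, Gram-negative JNH/NYV/BUT/EMD/AUG -> Hi),
# or pre-relabel the file. Raw abundances, all-zero features removed.
name: micromass
seed: 0
dataset:
  kind: arff
  path: data/micromass_train.arff
  label_attribute: class
preprocess:
  drop_zero_features: true
  scale: false            # raw MS abundances
sizes: {n_low: 130, n_hi: 130}
base: {name: svm}
protocol: loo
positive: Low
output: lbm_out/micromass
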