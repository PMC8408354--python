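# Main nondifferential grid: 5 x 4 x 2 = 40 scenarios, 40% validation sample.
grid:
  r2: [0.2, 0.4, 0.6, 0.8, 0.9]
  skewness: [0.1, 1, 1.5, 3]
  linear: [true, false]
  differential: [false]
  val_fraction: [0.40]
n: 650
n_reps: 5000
seed: 20210420
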