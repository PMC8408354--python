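# Differential measurement error: WC and IR share a latent Bernoulli(0.5)
# variable; tau is fixed at 0.44 (the R^2 = 0.8 value under the linear
# mechanism), skewness 0.1, 40% validation sample.
grid:
  r2: [0.8]
  skewness: [0.1]
  linear: [true]
  differential: [true]
  val_fraction: [0.40]
n: 650
n_reps: 5000
seed: 20210420
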