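# Two-dimensional linear (Ornstein-Uhlenbeck) benchmark:
# stable drift A = -I, additive noise sigma = 1, sparse kernel score with
# M = 100 inducing points refreshed every step, adaptive RBF length scale.
model:
  name: ou
  params:
    dimension: 2
    sigma: 1.0
simulation:
  N: 1000
  dt: 1.0e-3
  T: 3.0
  seed: 0
  record_every: 10
  init_mean: [0.5, 0.5]
  init_cov: 0.0025
score:
  class: sparse
  lambda: 1.0e-3
  jitter: 1.0e-6
  kernel:
    length_scale: adaptive
  inducing:
    M: 100
    strategy: uniform_box
  reference: zero
stages: [simulate, baseline, compare]
compare:
  metric: w1
out: fpe_ou2d
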