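# Reference microcircuit: oscillates at ~6.4 Hz (q = 0) / ~5.7 Hz (q = 1).
# Dependent weights w2, w6, w7 are filled from w3 by the connectivity
# ratio rule; sigmoid constants and tau take their defaults.
model:
  P: 1.428
  w1: 24.368
  w3: 9.677
  w4: 27.249
  w5: 30.913
  q: 0.0

# Constant drive for 10 s, then a sinusoid 3 Hz above the natural
# frequency, switched at an initial phase difference of 3pi/2.
drive:
  Lambda: 0.4
  f_in: 9.0
  delta_phi: 3pi/2

sweep:
  f_in_min: 3.0
  f_in_max: 10.0
  f_in_step: 0.5
  lambda_min: 0.1
  lambda_max: 0.6
  lambda_step: 0.1
  q_values: [0.0, 0.5, 1.0]

sampling:
  n_draws: 2000
  target_valid: 10

seed: 1
out_dir: results
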