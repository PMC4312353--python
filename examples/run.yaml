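# Example run configuration for the limitedoffer CLI.
# The task section encodes the long (8-trial) game; agent may be a preset
# name or explicit parameters (prior_precision, hazard_scale, sensitivity).
task:
  horizon: 8
  low_offer: 35
  high_offer: 80
  base_withdrawal_hazard: 0.12
  base_offer_prob: 0.15
  offer_decay: 0.8
agent:
  preset: control
simulation:
  n_games: 256
  seed: 7
fit:
  grid:
    alpha: [2.0, 32.0, 5]
    eta: [0.25, 4.0, 5]
    c: [1.5, 24.0, 5]
recover:
  settings:
    - {prior_precision: 4.0}
    - {prior_precision: 8.0}
    - {prior_precision: 16.0}
  n_games: 256
  n_reps: 10
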