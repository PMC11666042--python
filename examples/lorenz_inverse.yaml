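# Inverse Lorenz benchmark: recover time-varying sigma(t), rho(t) and the
# constant beta from 21 noiseless observations (desk-scale budget).
system: lorenz_inverse
kind: inverse
preset: grad
window: [0.0, 2.0]
u0: [1.0, 1.0, 1.0]
n_obs: 21
phase_steps: [2000, 20000, 10000]
n_hidden_layers: 4
width: 64
param_hidden_layers: 4
param_width: 10
n_collocation: 96
alpha: 0.99
balance_every: 100
eval_every: 1000
patience: 30
eval_points: 300
eval_grid: 300
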