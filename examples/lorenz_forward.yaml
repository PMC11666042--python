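# Forward Lorenz problem on a short window, desk-scale budget.
# Full-scale phase budgets used by the published benchmark runs are listed
# in pinnode.experiments.FULL_SCALE_PHASES.
system: lorenz
kind: forward
preset: grad_causal
window: [0.0, 1.5]
u0: [1.0, 1.0, 1.0]
n_obs: 1
phase_steps: [500, 100000, 40000]
n_hidden_layers: 3
width: 32
n_collocation: 64
alpha: 0.99
balance_every: 100
eval_every: 1000
patience: 15
eval_points: 200
eval_grid: 300
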