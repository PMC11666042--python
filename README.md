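# pinnode

Physics-informed neural networks (PINNs) for forward and inverse problems
on systems of ordinary differential equations, with the four training
enhancements that make multi-equation ODE systems tractable: per-dimension
**min–max ODE normalization**, per-equation **gradient balancing**, a
3-phase **causal training** schedule, and **time-domain decomposition**
with overlap handoff.

## Who this is for

Modellers who have a mechanistic ODE system — an epidemiological or
ecological compartment model, a chemical network, a dynamical-systems
benchmark — plus sparse observations, and who want a neural surrogate that
(a) solves the system forward from an initial condition, or (b) jointly
recovers unknown rate parameters and the state from data. Two benchmark
systems ship built in: the Lorenz system and a 10-stage stage-structured
model of mosquito population dynamics driven by seasonal temperature.

## The method

A network `U(t')` of normalized time approximates the normalized state.
With observations `D_u = {(t_j, u_j)}` (size `N_u`) and `F` equations
`du/dt = f_i(t, u, θ)`, training minimizes

    L = L_data + (1/F) Σ_i λ_i L_f(i)

where `L_data` is the mean squared misfit to the normalized observations
and `L_f(i)` is the mean squared normalized residual of equation `i` at
`N_f` collocation times resampled every step:

    r_i(t') = dU_i/dt' − (2/(U_u,i − L_u,i)) · ((T_max − T_min)/2) · f_i(t, u, θ)

Time maps onto [−1, 1]; each state dimension and each parameter maps
through its own bounds `(L, U)` (narrow bounds are widened around their
midpoint to width ≥ 2). The weights `λ_i` are adapted every `N` steps by
gradient balancing, `λ̂_i = mean|∇_W L_data| / max|∇_W L_f(i)|`, smoothed
as `λ_i ← α λ_i + (1 − α) λ̂_i` (defaults α = 0.99, N = 100; the data-loss
weight stays 1). Training runs in three phases — data fitting, progressive
causal training with a collocation interval that grows linearly over the
window, and final tuning with early stopping on an evaluation loss in
which every `λ` is reset to 1. Long windows are split into `S` equal
subdomains trained sequentially, each anchored by the previous network's
predictions on the overlap; unknown parameters are learnable scalars
(constants) or small networks of time, trained jointly with `U`.

Derivatives are computed analytically by a purpose-built differentiable
MLP (GELU activations, Glorot init): forward-mode tangents give `dU/dt'`,
reverse mode through the tangent pass gives exact weight gradients of the
residual loss, and Adam performs the updates.

## Worked example

Recover the decay rate of `du/dt = −θ u` (θ = 0.5) from 21 noiseless
observations while interpolating the state:

```python
import numpy as np
from pinnode import PINNRegressor, ODESystem, ParamSpec, integrate, make_observations

system = ODESystem(
    "decay", 1,
    rhs=lambda t, u, th: -th[:, [0]] * u,
    param_spec=[ParamSpec("theta", "learn_constant", 0.5, bounds=(0.0, 2.0))],
)
truth = integrate(system, [1.0], (0.0, 2.0), params={"theta": 0.5})
obs = make_observations(truth, np.linspace(0, 2, 21))

est = PINNRegressor(system, window=(0.0, 2.0),
                    phase_steps=(1000, 10000, 6000),
                    n_hidden_layers=3, width=32, n_collocation=64,
                    eval_every=500, eval_points=200, random_state=0)
est.fit(obs)
print("recovered theta:", round(float(est.predict_params([1.0])[0, 0]), 4))
print("state RMSE:", round(float(np.sqrt(np.mean(
    (est.predict(truth.times) - truth.states) ** 2))), 5))
```

prints

```
recovered theta: 0.5
state RMSE: 0.00012
```

— the constant rate is recovered to four decimals and the surrogate
interpolates the state to about one part in 10⁴ of its unit scale.

A command-line runner mirrors the library (`pinnode simulate | train |
invert | decompose | identify | report`, each taking `--config exp.yaml
--seed N --out dir/`), writing trajectory/prediction CSVs, loss traces and
JSON summaries.

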