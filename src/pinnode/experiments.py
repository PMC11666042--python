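"""Config-driven experiment runner for the benchmark matrix.

Experiments are plain dictionaries (or YAML files) naming a system, a
problem kind and an ablation preset; :func:`run_experiment` generates the
ground truth with the reference solver, trains the configured model and
writes traces, predictions, an error report and a JSON summary.

Ablation presets (switch combinations):

========================  =========  =======  ======  =========
preset                    normalize  balance  causal  decompose
========================  =========  =======  ======  =========
orig                      no         no       no      no
baseline                  yes        no       no      no
grad                      yes        yes      no      no
causal                    yes        no       yes     no
grad_causal               yes        yes      yes     no
grad_causal_domain        yes        yes      yes     yes
========================  =========  =======  ======  =========
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import DecomposedPINNRegressor, PINNRegressor
from .metrics import error_report
from .normalization import bounds_from_states
from .simulate import integrate, make_observations
from .systems import get_system

__all__ = ["PRESETS", "load_config", "run_experiment", "subdomain_sweep"]

PRESETS: dict[str, dict] = {
    "orig": dict(normalize=False, balance=False, causal=False, decompose=False),
    "baseline": dict(normalize=True, balance=False, causal=False, decompose=False),
    "grad": dict(normalize=True, balance=True, causal=False, decompose=False),
    "causal": dict(normalize=True, balance=False, causal=True, decompose=False),
    "grad_causal": dict(normalize=True, balance=True, causal=True, decompose=False),
    "grad_causal_domain": dict(normalize=True, balance=True, causal=True, decompose=True),
}

#: step budgets used by the published benchmark runs (full scale)
FULL_SCALE_PHASES = {
    "lorenz_forward_t2": (1000, 199000, 100000),
    "lorenz_inverse": (10000, 200000, 100000),
    "lorenz_forward_t20_per_subdomain": (5000, 100000, 45000),
    "mosquito_forward_per_subdomain": (10000, 100000, 100000),
}

_DEFAULTS = dict(
    kind="forward",
    preset="grad_causal",
    window=(0.0, 2.0),
    u0=None,
    n_obs=1,
    phase_steps=(1000, 20000, 10000),
    n_hidden_layers=4,
    width=100,
    param_hidden_layers=4,
    param_width=10,
    n_collocation=128,
    alpha=0.99,
    balance_every=100,
    learning_rate=1e-3,
    eval_every=1000,
    patience=100,
    eval_points=1000,
    n_subdomains=1,
    overlap=0.05,
    handoff_points=100,
    system_kwargs={},
    eval_grid=500,
)


def load_config(source) -> dict:
    """A config dict from a dict or a YAML path, validated against presets."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    unknown = set(cfg) - set(_DEFAULTS) - {"system", "seed"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "system" not in cfg:
        raise ValueError("config must name a system")
    out = dict(_DEFAULTS)
    out.update(cfg)
    if out["preset"] not in PRESETS:
        raise ValueError(f"unknown preset {out['preset']!r}; choose from {sorted(PRESETS)}")
    if out["kind"] not in ("forward", "inverse"):
        raise ValueError("kind must be 'forward' or 'inverse'")
    if out["kind"] == "inverse" and PRESETS[out["preset"]]["decompose"]:
        raise ValueError("domain decomposition is implemented for forward problems only")
    return out


def _config_hash(cfg: dict, seed: int) -> str:
    blob = json.dumps({**{k: str(v) for k, v in sorted(cfg.items())}, "seed": seed},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(config, seed: int = 0, out_dir=None) -> dict:
    """Run one benchmark experiment; returns (and optionally writes) a summary.

    Ground truth is integrated from the system's printed initial condition
    and true parameters; observations are the initial state (forward) or
    ``n_obs`` evenly spaced samples (inverse); the configured estimator is
    fitted and scored on a dense grid.
    """
    cfg = load_config(config)
    switches = PRESETS[cfg["preset"]]
    system = get_system(cfg["system"], **cfg["system_kwargs"])
    window = (float(cfg["window"][0]), float(cfg["window"][1]))
    u0 = np.asarray(cfg["u0"], dtype=float) if cfg["u0"] is not None else np.ones(system.state_dim)

    sim_span = (min(0.0, window[0]), window[1])
    truth = integrate(system, u0, sim_span)
    grid = np.linspace(window[0], window[1], int(cfg["eval_grid"]))
    truth_states = truth.at(grid)

    if cfg["kind"] == "forward" and int(cfg["n_obs"]) <= 1:
        obs_times = np.array([window[0]])
    else:
        obs_times = np.linspace(window[0], window[1], int(cfg["n_obs"]))
    obs = make_observations(truth, obs_times, seed=seed)

    lo, hi = bounds_from_states(truth_states)
    common = dict(
        n_hidden_layers=cfg["n_hidden_layers"], width=cfg["width"],
        n_collocation=cfg["n_collocation"], phase_steps=tuple(cfg["phase_steps"]),
        alpha=cfg["alpha"], balance_every=cfg["balance_every"],
        learning_rate=cfg["learning_rate"], eval_every=cfg["eval_every"],
        patience=cfg["patience"], eval_points=cfg["eval_points"],
        random_state=seed,
    )
    if switches["decompose"]:
        est = DecomposedPINNRegressor(
            system, window=window, n_subdomains=cfg["n_subdomains"],
            overlap=cfg["overlap"], handoff_points=cfg["handoff_points"],
            reference=truth, **common,
        )
    else:
        est = PINNRegressor(
            system, window=window, normalize=switches["normalize"],
            balance=switches["balance"], causal=switches["causal"],
            state_bounds=(lo, hi),
            param_hidden_layers=cfg["param_hidden_layers"],
            param_width=cfg["param_width"], **common,
        )
    est.fit(obs)

    pred = est.predict(grid)
    report = error_report(pred, truth_states, system.state_names)
    summary = {
        "config_hash": _config_hash(cfg, seed),
        "system": cfg["system"],
        "kind": cfg["kind"],
        "preset": cfg["preset"],
        "seed": seed,
        "n_obs": int(obs.n_obs),
        "rmse_u": float(report.loc["Overall", "RMSE"]),
        "mdape_u": float(report.loc["Overall", "MDAPE"]),
    }
    if hasattr(est, "eval_loss_"):
        summary["eval_loss"] = float(est.eval_loss_)
        summary["n_steps"] = int(est.n_steps_)
        st = est.state_
        if st.loss_trace:
            last = st.loss_trace[-1]
            summary["final_L_data"] = float(last["L_data"])
    if cfg["kind"] == "inverse":
        theta_pred = est.predict_params(grid)
        theta_true = system.true_params(grid)
        learn = system.learnable_indices
        p_report = error_report(theta_pred[:, learn], theta_true[:, learn],
                                [system.param_names[j] for j in learn])
        summary["rmse_theta"] = float(p_report.loc["Overall", "RMSE"])
        summary["mdape_theta"] = float(p_report.loc["Overall", "MDAPE"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "error_report.csv")
        pd.DataFrame(pred, columns=system.state_names).assign(t=grid).to_csv(
            out / "predictions.csv", index=False)
        if hasattr(est, "state_"):
            est.state_.loss_frame().to_csv(out / "loss_trace.csv", index=False)
            pd.DataFrame(est.state_.lambda_trace).to_csv(out / "lambda_trace.csv", index=False)
        if cfg["kind"] == "inverse":
            p_report.to_csv(out / "param_error_report.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary


def subdomain_sweep(base_config, S_values, seed: int = 0) -> pd.DataFrame:
    """One decomposed run per subdomain count; rows (S, steps, RMSE)."""
    cfg = load_config(base_config)
    if cfg["kind"] != "forward":
        raise ValueError("the subdomain sweep is a forward-problem experiment")
    rows = []
    for S in S_values:
        c = dict(cfg)
        c["n_subdomains"] = int(S)
        c["preset"] = "grad_causal_domain" if S > 1 else "grad_causal"
        summary = run_experiment(c, seed=seed)
        steps = summary.get("n_steps", sum(cfg["phase_steps"]) * int(S))
        rows.append({"S": int(S), "steps": int(sum(cfg["phase_steps"]) * S),
                     "rmse": summary["rmse_u"]})
    return pd.DataFrame(rows)
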