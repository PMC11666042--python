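"""Error metrics: RMSE, MAE, MDAPE and normalized RMSE.

MDAPE is the median of |pred - truth| / |truth| over entries whose true
value is not (numerically) zero; it is reported as a fraction (0.0019 for
0.19%).  nRMSE divides the RMSE by a normalizer: the range of the truth by
default, falling back to mean |truth| when the range is zero.  Overall rows
pool every (dimension, time) entry rather than averaging the
per-dimension metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rmse", "mae", "mdape", "nrmse", "error_report"]

#: |truth| below this floor is excluded from the MDAPE median
MDAPE_FLOOR = 1e-12


def _check(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty arrays")
    return pred, truth


def rmse(pred, truth) -> float:
    pred, truth = _check(pred, truth)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def mae(pred, truth) -> float:
    pred, truth = _check(pred, truth)
    return float(np.mean(np.abs(pred - truth)))


def mdape(pred, truth) -> float:
    """Median absolute percentage error as a fraction; NaN if every true
    value sits below the near-zero exclusion floor."""
    pred, truth = _check(pred, truth)
    keep = np.abs(truth) > MDAPE_FLOOR
    if not np.any(keep):
        return float("nan")
    return float(np.median(np.abs(pred[keep] - truth[keep]) / np.abs(truth[keep])))


def nrmse(pred, truth, mode: str = "range") -> float:
    """RMSE divided by a normalizer of the truth.

    ``mode="range"`` uses max - min (falling back to mean |truth| when the
    truth is constant); ``mode="mean"`` uses mean |truth|.  NaN when both
    normalizers vanish.
    """
    pred, truth = _check(pred, truth)
    r = rmse(pred, truth)
    rng_ = float(truth.max() - truth.min())
    mean_ = float(np.mean(np.abs(truth)))
    if mode == "range":
        norm = rng_ if rng_ > 0 else mean_
    elif mode == "mean":
        norm = mean_
    else:
        raise ValueError(f"unknown nRMSE mode {mode!r}")
    if norm == 0:
        return float("nan")
    return r / norm


def error_report(pred, truth, names=None, nrmse_mode: str = "range") -> pd.DataFrame:
    """Per-dimension metric table plus a pooled Overall row.

    ``pred`` and ``truth`` are (n_times, V); rows are dimensions, columns
    the four metrics.  The Overall row pools all entries.
    """
    pred, truth = _check(pred, truth)
    if pred.ndim == 1:
        pred, truth = pred[:, None], truth[:, None]
    V = pred.shape[1]
    names = list(names) if names is not None else [f"dim_{i + 1}" for i in range(V)]
    rows = []
    for i in range(V):
        rows.append({
            "name": names[i],
            "RMSE": rmse(pred[:, i], truth[:, i]),
            "MAE": mae(pred[:, i], truth[:, i]),
            "MDAPE": mdape(pred[:, i], truth[:, i]),
            "nRMSE": nrmse(pred[:, i], truth[:, i], nrmse_mode),
        })
    rows.append({
        "name": "Overall",
        "RMSE": rmse(pred, truth),
        "MAE": mae(pred, truth),
        "MDAPE": mdape(pred, truth),
        "nRMSE": nrmse(pred.ravel(), truth.ravel(), nrmse_mode),
    })
    df = pd.DataFrame(rows).set_index("name")
    df.attrs["nrmse_mode"] = nrmse_mode
    return df
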