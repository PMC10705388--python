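"""Derivative-free point estimation of the 7 normalized EP parameters.

The mismatch between a surrogate 12-lead ECG and a target ECG (both
nondimensional, same grid) is the mean squared difference over all leads
and time points.  Nelder-Mead is restarted from many uniform random
initial points in [-1,1]^7; iterates are clamped to the box, and the final
estimate is the componentwise mean of the trial optima — the optimization
landscape is not convex and single runs are not unique, so averaging
many trials stabilizes the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from cardiotwin.blnm import BLNMModel, EcgDataset, predict_12lead
from cardiotwin.ecg import ECG12


@dataclass
class CalibrationResult:
    theta_nm: np.ndarray            # averaged normalized estimate (7,)
    trials: np.ndarray              # (n_trials, 7) per-trial optima
    trial_losses: np.ndarray        # (n_trials,)
    target_mse: float               # mismatch at the averaged estimate
    n_averaged: int = 0             # trials inside the loss band of the best

    def __post_init__(self):
        if np.any(np.abs(self.theta_nm) > 1 + 1e-12):
            raise ValueError("averaged estimate must lie in [-1,1]^7")

    def to_json(self, path, space=None):
        import json

        d = dict(
            theta_nm=self.theta_nm.tolist(),
            target_mse=self.target_mse,
            trial_loss_mean=float(self.trial_losses.mean()),
            trial_loss_sd=float(self.trial_losses.std()),
            trial_spread_sd=self.trials.std(axis=0).tolist(),
        )
        if space is not None:
            d["theta_dimensional"] = space.denormalize(self.theta_nm).tolist()
        with open(path, "w") as f:
            json.dump(d, f, indent=1)

    def trials_to_csv(self, path):
        import pandas as pd

        df = pd.DataFrame(self.trials, columns=[f"theta_{i}" for i in range(7)])
        df["loss"] = self.trial_losses
        df.to_csv(path, index=False)


def ecg_mismatch(ecg_a: ECG12, ecg_b: ECG12) -> float:
    """Mean squared difference over all 12 leads and time points."""
    if len(ecg_a.t) != len(ecg_b.t) or np.max(np.abs(ecg_a.t - ecg_b.t)) > 1e-9:
        raise ValueError("ECGs must share one time grid")
    return float(np.mean((ecg_a.traces - ecg_b.traces) ** 2))


def _surrogate_cost(model: BLNMModel, dataset: EcgDataset, target: ECG12):
    tgt = target.traces
    t = target.t

    def cost(theta_norm):
        pred = predict_12lead(model.config, model.weights, np.clip(theta_norm, -1, 1), t, dataset.normalizer)
        return float(np.mean((pred.traces - tgt) ** 2))

    return cost


def nelder_mead_calibrate(
    model: BLNMModel,
    dataset: EcgDataset,
    target: ECG12,
    n_trials: int = 100,
    seed: int = 0,
    max_fev: int = 2000,
    xatol: float = 1e-4,
    init_points: np.ndarray | None = None,
    loss_band: float = 0.1,
) -> CalibrationResult:
    """Multi-start Nelder-Mead on the ECG mismatch.

    Each trial starts from a seeded uniform draw in [-1,1]^7 (or from the
    given ``init_points`` rows); convergence at simplex size < xatol or
    max_fev evaluations; out-of-box proposals are clamped before surrogate
    evaluation (the surrogate is trained only on the box).  The estimate
    is the componentwise mean of the trial optima whose final loss lies
    within ``loss_band`` (relative) of the best trial."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    cost = _surrogate_cost(model, dataset, target)
    rng = np.random.default_rng(seed)
    optima, losses = [], []
    for trial in range(n_trials):
        if init_points is not None and trial < len(init_points):
            x0 = np.asarray(init_points[trial], float)
        else:
            x0 = rng.uniform(-1.0, 1.0, 7)
        res = optimize.minimize(
            cost, x0, method="Nelder-Mead",
            options=dict(maxfev=max_fev, xatol=xatol, fatol=1e-12),
        )
        optima.append(np.clip(res.x, -1.0, 1.0))
        losses.append(res.fun)
    optima = np.asarray(optima)
    losses = np.asarray(losses)
    # average only the trials that reached (within loss_band, relative)
    # the best final loss: on rough surrogate landscapes many restarts
    # stall in clearly inferior local optima, and a flat average over
    # those destroys the estimate
    best = losses.min()
    keep = losses <= best * (1.0 + loss_band) + 1e-12
    theta_nm = optima[keep].mean(axis=0)
    if not np.all(np.isfinite(theta_nm)):
        raise RuntimeError("calibration failed: non-finite averaged estimate")
    return CalibrationResult(theta_nm, optima, losses, cost(theta_nm),
                             n_averaged=int(keep.sum()))
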