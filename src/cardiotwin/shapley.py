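"""Variance-based global sensitivity via Shapley effects.

Shapley effects distribute the variance of a scalar output across
(possibly dependent) inputs by averaging, over permutations, the marginal
increase in explained variance when an input joins the conditioning set.
The random-permutation estimator is used: for a sampled permutation pi
and prefix J, the value function

    v(J) = E_{X_-J} [ Var(Y | X_-J) ]

is estimated with n_outer conditioning draws of the complement and
n_inner inner draws each; the increment v(J u {i}) - v(J) is credited to
parameter i, and effects are normalized by the total variance (estimated
from n_var independent draws).  Bootstrap confidence intervals resample
the per-permutation increments.

The input law is a Gaussian copula with normal marginals centered at the
calibrated parameters (scale 0.2 by default); with the identity copula
the inputs are independent and conditionals collapse to marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cardiotwin.blnm import BLNMModel, EcgDataset, forward
from cardiotwin.ecg import ECG12, _M12


@dataclass
class InputDistribution:
    """Normal marginals N(center_i, scale) tied by a Gaussian copula."""

    center: np.ndarray
    scale: float = 0.2
    corr: np.ndarray | None = None      # copula correlation; None = identity
    clamp: tuple | None = (-1.0, 1.0)   # clip samples before cost evaluation

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.d = len(self.center)
        if self.corr is None:
            self.corr = np.eye(self.d)
        self.corr = np.asarray(self.corr, float)
        self._chol = np.linalg.cholesky(self.corr)

    def sample(self, n, rng):
        z = rng.standard_normal((n, self.d)) @ self._chol.T
        return self.center + self.scale * z

    def conditional_sample(self, free: np.ndarray, fixed: np.ndarray,
                           x_fixed: np.ndarray, n: int, rng):
        """Draw the ``free`` coordinates given values of the ``fixed``
        ones (standard Gaussian conditioning on the copula scale)."""
        if len(fixed) == 0:
            return self.sample(n, rng)[:, free]
        C = self.corr
        Cff = C[np.ix_(free, free)]
        Cfx = C[np.ix_(free, fixed)]
        Cxx = C[np.ix_(fixed, fixed)]
        sol = np.linalg.solve(Cxx, (x_fixed - self.center[fixed]) / self.scale)
        mean = self.center[free] + self.scale * (Cfx @ sol)
        cov = Cff - Cfx @ np.linalg.solve(Cxx, Cfx.T)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(free)))
        z = rng.standard_normal((n, len(free))) @ chol.T
        return mean + self.scale * z


@dataclass
class ShapleyResult:
    effects: np.ndarray        # normalized, sum ~ 1
    ci_low: np.ndarray
    ci_high: np.ndarray
    total_variance: float
    settings: dict

    def ranking(self) -> np.ndarray:
        """Parameter indices from most to least influential."""
        return np.argsort(self.effects)[::-1]

    def to_csv(self, path, names=None):
        import pandas as pd

        names = names or [f"theta_{i}" for i in range(len(self.effects))]
        pd.DataFrame(
            dict(parameter=names, effect=self.effects, ci_low=self.ci_low, ci_high=self.ci_high)
        ).to_csv(path, index=False)


def shapley_effects(
    cost,
    dist: InputDistribution,
    n_perm: int = 2000,
    n_var: int = 5000,
    n_outer: int = 50,
    n_inner: int = 3,
    n_boot: int = 500,
    seed: int = 0,
) -> ShapleyResult:
    """Random-permutation Shapley effects of ``cost`` under ``dist``.

    ``cost`` must accept an (B, d) array and return (B,) values."""
    rng = np.random.default_rng(seed)
    d = dist.d

    def evaluate(x):
        x = np.asarray(x, float)
        if dist.clamp is not None:
            x = np.clip(x, *dist.clamp)
        return np.asarray(cost(x), float)

    y_var = evaluate(dist.sample(n_var, rng))
    total_var = float(np.var(y_var, ddof=1))
    if total_var <= 0:
        raise ValueError("constant cost: zero total variance")

    identity = np.allclose(dist.corr, np.eye(d))
    increments = np.zeros((n_perm, d))
    for p in range(n_perm):
        perm = rng.permutation(d)
        prev = 0.0
        for j in range(d):
            J = perm[: j + 1]
            if j == d - 1:
                v = total_var
            else:
                comp = perm[j + 1 :]
                if identity:
                    outer = dist.center[comp] + dist.scale * rng.standard_normal((n_outer, len(comp)))
                else:
                    outer = dist.sample(n_outer, rng)[:, comp]
                x = np.empty((n_outer, n_inner, d))
                x[:, :, comp] = outer[:, None, :]
                if identity:
                    x[:, :, J] = dist.center[J] + dist.scale * rng.standard_normal((n_outer, n_inner, len(J)))
                else:
                    for o in range(n_outer):
                        x[o][:, J] = dist.conditional_sample(J, comp, outer[o], n_inner, rng)
                y = evaluate(x.reshape(-1, d)).reshape(n_outer, n_inner)
                v = float(np.mean(np.var(y, axis=1, ddof=1)))
            increments[p, perm[j]] = v - prev
            prev = v

    effects = increments.mean(axis=0) / total_var
    boot = np.empty((n_boot, d))
    for b in range(n_boot):
        pick = rng.integers(0, n_perm, n_perm)
        boot[b] = increments[pick].mean(axis=0) / total_var
    ci_low = np.percentile(boot, 2.5, axis=0)
    ci_high = np.percentile(boot, 97.5, axis=0)
    return ShapleyResult(
        effects, ci_low, ci_high, total_var,
        settings=dict(n_perm=n_perm, n_var=n_var, n_outer=n_outer,
                      n_inner=n_inner, n_boot=n_boot, seed=seed),
    )


def mismatch_cost_factory(model: BLNMModel, dataset: EcgDataset, target: ECG12):
    """Vectorized ECG-mismatch cost of normalized parameters.

    Returns a function mapping (B, 7) parameter arrays to (B,) MSE values
    against the target 12-lead ECG (nondimensional)."""
    t_norm = dataset.normalizer.normalize_time(target.t)
    T = len(t_norm)
    tgt = target.traces  # (12, T)

    def cost(theta):
        theta = np.atleast_2d(np.asarray(theta, float))
        B = len(theta)
        tt = np.tile(t_norm, B)
        th = np.repeat(theta, T, axis=0)
        out = forward(model.config, model.weights, tt, th)[:, :9]
        leads9 = out.reshape(B, T, 9).transpose(0, 2, 1)     # (B, 9, T)
        ecg12 = np.einsum("lk,bkt->blt", _M12, leads9)
        return np.mean((ecg12 - tgt[None]) ** 2, axis=(1, 2))

    return cost
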