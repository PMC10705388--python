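"""Branched Latent Neural Map (BLNM) surrogate of the parametrized
12-lead ECG.

A BLNM is a feedforward partially-connected network mapping normalized
time t in [0,1] and 7 normalized electrophysiology parameters in [-1,1]^7
to n_states outputs: the first 9 are the physical leads (V1..V6, LA, RA,
F, nondimensional), the remainder are unsupervised latent states that
shape training only through shared weights.  For the first d
("disentanglement level") hidden layers the temporal input feeds a
temporal branch of floor(n/2) neurons and the parameters a parameter
branch of ceil(n/2) neurons, with no cross-connections; from layer d+1 the
layers are fully connected; the output layer is linear.  Hidden
activations are tanh.

Training is full-batch BFGS on the mean squared error of the 9 physical
outputs (latent outputs unpenalized); gradients come from hand-written
backpropagation, so the whole model runs on numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from cardiotwin.ecg import ECG12, Normalizer, ecg12_from_9

N_PARAMS = 7  # cell-to-organ EP parameters


@dataclass(frozen=True)
class BLNMConfig:
    n_layers: int
    n_neurons: int
    n_states: int
    disentanglement: int

    def __post_init__(self):
        if self.n_states < 9:
            raise ValueError("need at least the 9 physical lead outputs")
        if not (1 <= self.disentanglement <= self.n_layers):
            raise ValueError("disentanglement level must lie in {1..n_layers}")
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons for the two branches")

    @property
    def width_t(self) -> int:
        return self.n_neurons // 2

    @property
    def width_p(self) -> int:
        return self.n_neurons - self.n_neurons // 2


def _layer_dims(cfg: BLNMConfig):
    """Sequence of weight blocks as (n_in, n_out, kind) with kind in
    {'t', 'p', 'full', 'out'}."""
    dims = []
    in_t, in_p = 1, N_PARAMS
    for layer in range(1, cfg.n_layers + 1):
        if layer <= cfg.disentanglement:
            dims.append((in_t, cfg.width_t, "t"))
            dims.append((in_p, cfg.width_p, "p"))
            in_t, in_p = cfg.width_t, cfg.width_p
        else:
            n_in = in_t + in_p if layer == cfg.disentanglement + 1 else cfg.n_neurons
            dims.append((n_in, cfg.n_neurons, "full"))
    n_last = cfg.n_neurons  # == width_t + width_p when fully branched
    dims.append((n_last, cfg.n_states, "out"))
    return dims


def count_parameters(cfg: BLNMConfig) -> int:
    """Closed-form trainable-parameter count (weights plus biases)."""
    return sum(n_in * n_out + n_out for n_in, n_out, _ in _layer_dims(cfg))


def init_weights(cfg: BLNMConfig, seed: int = 0) -> np.ndarray:
    """Seeded Glorot-uniform initialization, flattened."""
    rng = np.random.default_rng(seed)
    parts = []
    for n_in, n_out, _ in _layer_dims(cfg):
        lim = np.sqrt(6.0 / (n_in + n_out))
        parts.append(rng.uniform(-lim, lim, size=n_in * n_out))
        parts.append(np.zeros(n_out))
    return np.concatenate(parts)


def _unflatten(cfg: BLNMConfig, w: np.ndarray):
    if len(w) != count_parameters(cfg):
        raise ValueError(
            f"weight vector length {len(w)} != expected {count_parameters(cfg)}"
        )
    blocks = []
    k = 0
    for n_in, n_out, kind in _layer_dims(cfg):
        W = w[k : k + n_in * n_out].reshape(n_in, n_out)
        k += n_in * n_out
        b = w[k : k + n_out]
        k += n_out
        blocks.append((W, b, kind))
    return blocks


def forward(cfg: BLNMConfig, weights: np.ndarray, t: np.ndarray, theta: np.ndarray,
            return_cache: bool = False):
    """Evaluate the map at rows (t_i, theta_i).

    t: (B,) normalized time; theta: (B, 7) or (7,) broadcast.  Returns
    (B, n_states); with return_cache=True also the per-layer activations
    needed by backprop.
    """
    t = np.atleast_1d(np.asarray(t, float))
    theta = np.asarray(theta, float)
    if theta.ndim == 1:
        theta = np.broadcast_to(theta, (len(t), N_PARAMS))
    blocks = _unflatten(cfg, np.asarray(weights, float))
    a_t, a_p = t[:, None], theta
    merged = None
    cache = []
    i = 0
    while i < len(blocks):
        W, b, kind = blocks[i]
        if kind == "t":
            Wp, bp, _ = blocks[i + 1]
            z_t = a_t @ W + b
            z_p = a_p @ Wp + bp
            cache.append(("branch", a_t, a_p, z_t, z_p))
            a_t, a_p = np.tanh(z_t), np.tanh(z_p)
            i += 2
        elif kind == "full":
            if merged is None:
                merged = np.concatenate([a_t, a_p], axis=1)
            z = merged @ W + b
            cache.append(("full", merged, z))
            merged = np.tanh(z)
            i += 1
        else:  # out
            if merged is None:
                merged = np.concatenate([a_t, a_p], axis=1)
            out = merged @ W + b
            cache.append(("out", merged, out))
            i += 1
    if return_cache:
        return out, cache
    return out


def loss_and_grad(cfg: BLNMConfig, weights: np.ndarray, t: np.ndarray,
                  theta: np.ndarray, targets: np.ndarray):
    """MSE over the 9 physical outputs and its gradient w.r.t. the flat
    weight vector (hand-written backprop)."""
    out, cache = forward(cfg, weights, t, theta, return_cache=True)
    B = out.shape[0]
    resid = np.zeros_like(out)
    resid[:, :9] = out[:, :9] - targets
    loss = float(np.mean(resid[:, :9] ** 2))
    d_out = (2.0 / (9 * B)) * resid

    blocks = _unflatten(cfg, weights)
    grads = [None] * len(blocks)

    # walk the cache backwards
    bi = len(blocks) - 1
    ci = len(cache) - 1
    kind, merged, _ = cache[ci]
    W_o, _, _ = blocks[bi]
    grads[bi] = (merged.T @ d_out, d_out.sum(axis=0))
    delta = d_out @ W_o.T  # gradient w.r.t. the last hidden activations
    bi -= 1
    ci -= 1

    while ci >= 0:
        entry = cache[ci]
        if entry[0] == "full":
            _, a_in, z = entry
            dz = delta * (1.0 - np.tanh(z) ** 2)
            W, _, _ = blocks[bi]
            grads[bi] = (a_in.T @ dz, dz.sum(axis=0))
            delta = dz @ W.T
            bi -= 1
        else:  # branch layer: delta covers concat([t, p]) activations
            _, a_t, a_p, z_t, z_p = entry
            d_t = delta[:, : cfg.width_t] * (1.0 - np.tanh(z_t) ** 2)
            d_p = delta[:, cfg.width_t :] * (1.0 - np.tanh(z_p) ** 2)
            Wp, _, _ = blocks[bi]
            grads[bi] = (a_p.T @ d_p, d_p.sum(axis=0))
            Wt, _, _ = blocks[bi - 1]
            grads[bi - 1] = (a_t.T @ d_t, d_t.sum(axis=0))
            delta = np.concatenate([d_t @ Wt.T, d_p @ Wp.T], axis=1)
            bi -= 2
        ci -= 1

    flat = np.concatenate([np.concatenate([gW.ravel(), gb]) for gW, gb in grads])
    return loss, flat


def forward_with_param_jac(cfg: BLNMConfig, weights: np.ndarray, t: np.ndarray,
                           theta: np.ndarray):
    """Outputs and their Jacobian w.r.t. the 7 parameters, forward-mode.

    Returns (out (B, n_states), jac (B, n_states, 7))."""
    t = np.atleast_1d(np.asarray(t, float))
    theta = np.asarray(theta, float)
    if theta.ndim == 1:
        theta = np.broadcast_to(theta, (len(t), N_PARAMS))
    blocks = _unflatten(cfg, np.asarray(weights, float))
    B = len(t)
    a_t, a_p = t[:, None], theta
    j_t = np.zeros((B, N_PARAMS, 1))           # tangents stored (B, p, width)
    j_p = np.broadcast_to(np.eye(N_PARAMS), (B, N_PARAMS, N_PARAMS)).copy()
    merged = j_m = None

    def push(j, W, act=None):
        # (B, p, n_in) @ (n_in, n_out) via one BLAS call on (B*p, n_in)
        out = (j.reshape(-1, j.shape[-1]) @ W).reshape(j.shape[0], j.shape[1], -1)
        if act is not None:
            out *= (1.0 - act**2)[:, None, :]
        return out

    i = 0
    while i < len(blocks):
        W, b, kind = blocks[i]
        if kind == "t":
            Wp, bp, _ = blocks[i + 1]
            a_t, a_p = np.tanh(a_t @ W + b), np.tanh(a_p @ Wp + bp)
            j_t = push(j_t, W, a_t)
            j_p = push(j_p, Wp, a_p)
            i += 2
        elif kind == "full":
            if merged is None:
                merged = np.concatenate([a_t, a_p], axis=1)
                j_m = np.concatenate([j_t, j_p], axis=2)
            merged = np.tanh(merged @ W + b)
            j_m = push(j_m, W, merged)
            i += 1
        else:
            if merged is None:
                merged = np.concatenate([a_t, a_p], axis=1)
                j_m = np.concatenate([j_t, j_p], axis=2)
            out = merged @ W + b
            jac = push(j_m, W).transpose(0, 2, 1)   # (B, n_states, 7)
            i += 1
    return out, jac


# --------------------------------------------------------------------------
# dataset container
# --------------------------------------------------------------------------

@dataclass
class EcgDataset:
    """Normalized ECG ensemble on the fixed 0..600 ms / 5 ms grid.

    ``params`` are dimensional 7-vectors; ``params_norm`` their [-1,1]^7
    images; ``leads`` are (n, 9, T) nondimensional traces; ``train_idx`` /
    ``test_idx`` partition the samples; the fitted ``normalizer`` is
    carried so targets and new predictions share one scale."""

    t: np.ndarray
    params: np.ndarray
    params_norm: np.ndarray
    leads: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    normalizer: Normalizer
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.params)
        if self.leads.shape != (n, 9, len(self.t)):
            raise ValueError("leads must be (n_samples, 9, n_times)")
        overlap = np.intersect1d(self.train_idx, self.test_idx)
        if len(overlap):
            raise ValueError("train/test overlap")

    @property
    def n_samples(self) -> int:
        return len(self.params)

    def rows(self, idx: np.ndarray):
        """Flatten samples x times into training rows (t, theta, y)."""
        T = len(self.t)
        tt = np.tile(self.t / self.normalizer.t_hb, len(idx))
        th = np.repeat(self.params_norm[idx], T, axis=0)
        y = self.leads[idx].transpose(0, 2, 1).reshape(len(idx) * T, 9)
        return tt, th, y

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f["time"] = self.t
            f["params"] = self.params
            f["params_norm"] = self.params_norm
            f["leads"] = self.leads
            f["split/train"] = self.train_idx
            f["split/test"] = self.test_idx
            f["normalizer/lo"] = self.normalizer.lo
            f["normalizer/hi"] = self.normalizer.hi
            f.attrs["t_hb"] = self.normalizer.t_hb
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path):
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                t=f["time"][:],
                params=f["params"][:],
                params_norm=f["params_norm"][:],
                leads=f["leads"][:],
                train_idx=f["split/train"][:],
                test_idx=f["split/test"][:],
                normalizer=Normalizer(f["normalizer/lo"][:], f["normalizer/hi"][:], float(f.attrs["t_hb"])),
                meta=json.loads(f.attrs["meta"]),
            )


# --------------------------------------------------------------------------
# training / tuning / prediction
# --------------------------------------------------------------------------

@dataclass
class BLNMModel:
    config: BLNMConfig
    weights: np.ndarray
    loss_history: list = field(default_factory=list)

    def __call__(self, t_norm, theta_norm):
        return forward(self.config, self.weights, t_norm, theta_norm)

    def to_json(self, path):
        cfg = self.config
        with open(path, "w") as f:
            json.dump(
                {
                    "config": dict(
                        n_layers=cfg.n_layers, n_neurons=cfg.n_neurons,
                        n_states=cfg.n_states, disentanglement=cfg.disentanglement,
                    ),
                    "weights": self.weights.tolist(),
                },
                f,
            )

    @classmethod
    def from_json(cls, path):
        with open(path) as f:
            d = json.load(f)
        return cls(BLNMConfig(**d["config"]), np.asarray(d["weights"]))


def _bfgs_minimize(fun, w0, max_iters, gtol=0.0, callback=None):
    """Full-memory BFGS with strong-Wolfe line search.

    The inverse-Hessian update is applied with rank-one outer products
    (O(n^2) per iteration); scipy's BFGS forms the same update with dense
    matrix products (O(n^3)), which is intractable at the network sizes
    used here.  ``fun`` returns (loss, grad)."""
    from scipy.optimize import line_search

    from scipy.linalg.blas import dger

    w = np.asarray(w0, float).copy()
    f, g = fun(w)
    n = len(w)
    H = np.eye(n, order="F")
    for it in range(max_iters):
        if np.linalg.norm(g) <= gtol:
            break
        p = -(H @ g)
        alpha, _, _, f_new, _, g_new = line_search(
            lambda x: fun(x)[0], lambda x: fun(x)[1], w, p, gfk=g, old_fval=f,
            maxiter=30,
        )
        if alpha is None:
            # strong-Wolfe failure: backtracking Armijo fallback
            alpha = 1.0
            for _ in range(40):
                f_try, g_try = fun(w + alpha * p)
                if f_try <= f + 1e-4 * alpha * (g @ p):
                    f_new, g_new = f_try, g_try
                    break
                alpha *= 0.5
            else:
                break  # no descent possible: converged to tolerance
        if g_new is None:
            _, g_new = fun(w + alpha * p)
        s = alpha * p
        y = g_new - g
        sy = s @ y
        w = w + s
        f, g = f_new, g_new
        if sy > 1e-12 * np.linalg.norm(s) * np.linalg.norm(y):
            rho = 1.0 / sy
            Hy = H @ y
            yHy = y @ Hy
            # H' = H - rho (Hy s^T + s (Hy)^T) + rho^2 (sy + yHy) s s^T,
            # applied as in-place rank-1 (BLAS ger) updates
            H = dger(-rho, Hy, s, a=H, overwrite_a=1)
            H = dger(-rho, s, Hy, a=H, overwrite_a=1)
            H = dger(rho + rho * rho * yHy, s, s, a=H, overwrite_a=1)
        if callback is not None:
            callback(w, f)
    return w, f


def dataset_mse(model_or, cfg, weights, tt, th, y) -> float:
    out = forward(cfg, weights, tt, th)
    return float(np.mean((out[:, :9] - y) ** 2))


def train(
    cfg: BLNMConfig,
    dataset: EcgDataset,
    max_iters: int = 2000,
    seed: int = 0,
    idx: np.ndarray | None = None,
    tol: float = 0.0,
) -> BLNMModel:
    """Full-batch BFGS fit of the MSE loss on the training split (or the
    given sample indices).  Deterministic given the seed."""
    if idx is None:
        idx = dataset.train_idx
    if len(idx) == 0:
        raise ValueError("empty training split")
    tt, th, y = dataset.rows(np.asarray(idx))
    w0 = init_weights(cfg, seed=seed)
    history = []
    memo = {}

    def fun(w):
        key = w.tobytes()
        if key not in memo:
            loss, grad = loss_and_grad(cfg, w, tt, th, y)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at iteration {len(history)}")
            memo.clear()
            memo[key] = (loss, grad)
        return memo[key]

    def cb(w, f):
        history.append(float(f))

    w_opt, _ = _bfgs_minimize(fun, w0, max_iters, gtol=tol, callback=cb)
    return BLNMModel(cfg, w_opt, loss_history=history)


TUNING_RANGES = dict(
    n_layers=(1, 8),
    n_neurons=(10, 30),
    n_states=(9, 12),
)


def kfold_tune(
    dataset: EcgDataset,
    K: int = 5,
    n_configs: int = 50,
    iters_per_fit: int = 200,
    seed: int = 0,
):
    """Latin-hypercube search over (layers, neurons, states,
    disentanglement) with K-fold cross validation on the training split.
    Returns (best BLNMConfig, table) where the table lists every sampled
    configuration and its mean validation MSE across folds."""
    train_idx = np.asarray(dataset.train_idx)
    if len(train_idx) < K:
        raise ValueError("training split smaller than K")
    rng = np.random.default_rng(seed)
    u = qmc.LatinHypercube(d=4, seed=rng.integers(2**31)).random(n_configs)

    def scale(col, lo, hi):
        return np.minimum(lo + np.floor(col * (hi - lo + 1)).astype(int), hi)

    layers = scale(u[:, 0], *TUNING_RANGES["n_layers"])
    neurons = scale(u[:, 1], *TUNING_RANGES["n_neurons"])
    states = scale(u[:, 2], *TUNING_RANGES["n_states"])
    dis = np.minimum(scale(u[:, 3], 1, 8), layers)  # d <= that config's layers

    perm = rng.permutation(train_idx)
    folds = np.array_split(perm, K)

    rows = []
    for ci in range(n_configs):
        cfg = BLNMConfig(int(layers[ci]), int(neurons[ci]), int(states[ci]), int(dis[ci]))
        fold_mse = []
        for k in range(K):
            val = folds[k]
            tr = np.concatenate([folds[j] for j in range(K) if j != k])
            model = train(cfg, dataset, max_iters=iters_per_fit, seed=seed + 1000 * k, idx=tr)
            tt, th, y = dataset.rows(val)
            fold_mse.append(dataset_mse(None, cfg, model.weights, tt, th, y))
        rows.append(
            dict(
                n_layers=cfg.n_layers, n_neurons=cfg.n_neurons, n_states=cfg.n_states,
                disentanglement=cfg.disentanglement,
                n_parameters=count_parameters(cfg), cv_mse=float(np.mean(fold_mse)),
            )
        )
    import pandas as pd

    table = pd.DataFrame(rows)
    best = table["cv_mse"].idxmin()
    r = table.loc[best]
    best_cfg = BLNMConfig(int(r.n_layers), int(r.n_neurons), int(r.n_states), int(r.disentanglement))
    return best_cfg, table


def predict_12lead(
    cfg: BLNMConfig,
    weights: np.ndarray,
    theta_norm: np.ndarray,
    t_ms: np.ndarray,
    normalizer: Normalizer,
    denormalize: bool = False,
) -> ECG12:
    """Surrogate 12-lead ECG at normalized parameters theta_norm on the
    t_ms grid.  With denormalize=True the 9 leads are mapped back to the
    physical scale before the lead algebra; otherwise the ECG stays
    nondimensional (the calibration/UQ convention)."""
    t_norm = normalizer.normalize_time(np.asarray(t_ms, float))
    out = forward(cfg, weights, t_norm, np.asarray(theta_norm, float))
    leads9 = out[:, :9].T
    if denormalize:
        leads9 = normalizer.invert(leads9)
    return ecg12_from_9(t_ms, leads9)
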