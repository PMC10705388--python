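"""Bayesian inverse uncertainty quantification for the 12-lead ECG match.

The observation model treats the clinical (or synthetic-twin) ECG as a
multivariate normal centered on the surrogate prediction,

    z_clinical ~ N( z_ECG(theta),  sigma_meas^2 I + k(t, t'; sigma_GP, l_GP) ),

with fixed measurement noise sigma_meas = 0.1 and a zero-mean Gaussian
process (squared-exponential kernel in normalized time) absorbing the
surrogate discrepancy.  Full inter-lead correlation is realized as the
Kronecker block J_12 (x) K_t (all-ones lead block times the shared time
kernel), so the 12T x 12T covariance never has to be formed: in the lead
eigenbasis it splits into one T x T block sigma_meas^2 I + 12 K_t and
eleven diagonal blocks.

Priors: each normalized parameter is uniform on the Nelder-Mead estimate
+- iota (clipped to [-1,1], iota = 0.2); the GP amplitude and correlation
length carry N(0.01, 1.0) hyperpriors truncated to positive values.

Sampling uses an in-package No-U-Turn Sampler (Hoffman-Gelman doubling
with slice acceptance, dual-averaged step size at 90% target acceptance
and a diagonal metric adapted during warm-up) on an unconstrained
reparametrization (logit for the box, log for the positive scales).
Convergence is certified with the Gelman-Rubin potential scale reduction
factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from cardiotwin.blnm import BLNMModel, EcgDataset, forward_with_param_jac
from cardiotwin.ecg import ECG12, _M12

LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ErrorModel:
    sigma_meas: float = 0.1
    hyper_mean: float = 0.01      # N(0.01, 1.0) hyperpriors, truncated > 0
    hyper_scale: float = 1.0
    structure: str = "shared_time_kernel"   # or "per_lead"


@dataclass
class PriorSpec:
    """Uniform box theta_NM_i +- iota, clipped to [-1, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def from_center(cls, center: np.ndarray, iota: float = 0.2) -> "PriorSpec":
        center = np.asarray(center, float)
        lo = np.maximum(center - iota, -1.0)
        hi = np.minimum(center + iota, 1.0)
        if np.any(hi <= lo):
            raise ValueError("empty prior interval")
        return cls(lo, hi)


QUANTITY_NAMES = (
    "G_CaL", "G_Na", "G_Kr", "D_ani", "D_iso", "D_purk", "t_LV_stim",
    "sigma_GP", "l_GP",
)


@dataclass
class PosteriorSamples:
    """Per-chain draws of the 7 normalized EP parameters plus the two GP
    hyperparameters, with convergence diagnostics."""

    draws: np.ndarray          # (chains, n_draws, 9)
    names: tuple = QUANTITY_NAMES
    divergences: np.ndarray | None = None      # per chain
    step_sizes: np.ndarray | None = None

    @property
    def n_chains(self):
        return self.draws.shape[0]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def rhat(self) -> np.ndarray:
        return np.array([gelman_rubin(self.draws[:, :, q]) for q in range(self.draws.shape[-1])])

    def summary(self):
        import pandas as pd

        flat = self.flat()
        return pd.DataFrame(
            dict(
                quantity=list(self.names),
                mean=flat.mean(axis=0),
                sd=flat.std(axis=0, ddof=1),
                q2_5=np.percentile(flat, 2.5, axis=0),
                q50=np.percentile(flat, 50, axis=0),
                q97_5=np.percentile(flat, 97.5, axis=0),
                rhat=self.rhat(),
            )
        )

    def to_csv(self, path):
        import pandas as pd

        C, N, Q = self.draws.shape
        df = pd.DataFrame(self.flat(), columns=list(self.names))
        df.insert(0, "draw", np.tile(np.arange(N), C))
        df.insert(0, "chain", np.repeat(np.arange(C), N))
        df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

class EcgLikelihood:
    """Gaussian log likelihood of a 12-lead target given surrogate
    parameters and GP hyperparameters, with analytic gradients.

    Exploits the lead-eigenbasis factorization of
    sigma^2 I_{12T} + J_12 (x) K_t described in the module docstring."""

    def __init__(self, model: BLNMModel, dataset: EcgDataset, target: ECG12,
                 error_model: ErrorModel = ErrorModel(), jitter: float = 1e-10):
        self.model = model
        self.dataset = dataset
        self.t_ms = np.asarray(target.t, float)
        self.t_norm = dataset.normalizer.normalize_time(self.t_ms)
        self.target = np.asarray(target.traces, float)     # (12, T)
        self.T = len(self.t_ms)
        self.em = error_model
        self.jitter = jitter
        d = self.t_norm
        self.D2 = (d[:, None] - d[None, :]) ** 2

    # -- surrogate 12-lead prediction and its parameter Jacobian ----------
    def predict(self, theta):
        out, jac = forward_with_param_jac(
            self.model.config, self.model.weights, self.t_norm, np.asarray(theta, float)
        )
        leads9 = out[:, :9].T                                 # (9, T)
        jac9 = jac[:, :9, :]                                  # (T, 9, 7)
        m12 = _M12 @ leads9                                   # (12, T)
        j12 = np.tensordot(_M12, jac9, axes=([1], [1]))       # (12, T, 7)
        return m12, j12

    def _lead_count(self):
        return 12 if self.em.structure == "shared_time_kernel" else 1

    def _chol(self, A):
        jit = self.jitter
        for _ in range(6):
            try:
                return cho_factor(A + jit * np.eye(self.T), lower=True)
            except np.linalg.LinAlgError:
                jit *= 100.0
        raise np.linalg.LinAlgError("covariance factorization failed at max jitter")

    def log_likelihood(self, theta, sigma_gp, l_gp, with_grad: bool = False):
        """Log density (and optionally its gradient w.r.t. (theta, sigma_gp,
        l_gp) as a 9-vector)."""
        s2 = self.em.sigma_meas**2
        m12, j12 = self.predict(theta)
        R = self.target - m12                               # (12, T)
        K = sigma_gp**2 * np.exp(-self.D2 / (2.0 * l_gp**2))

        if self.em.structure == "per_lead":
            # independent leads sharing the kernel: 12 identical T x T blocks
            A = s2 * np.eye(self.T) + K
            cf = self._chol(A)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            AinvRT = cho_solve(cf, R.T)                     # (T, 12)
            quad = float(np.sum(R.T * AinvRT))
            ll = -0.5 * (quad + 12.0 * logdet + 12.0 * self.T * LOG_2PI)
            if not with_grad:
                return ll
            SinvR = AinvRT.T                                # (12, T)
            grad_theta = np.einsum("lt,ltp->p", SinvR, j12)
            Ainv = cho_solve(cf, np.eye(self.T))
            dK_ds = 2.0 * K / sigma_gp
            dK_dl = K * self.D2 / l_gp**3
            # per-lead: sum over leads of the standard GP gradient
            B = AinvRT.T                                    # (12, T), rows A^-1 r_l
            g_s = 0.5 * np.einsum("lt,ts,ls->", B, dK_ds, B) - 6.0 * np.sum(Ainv * dK_ds)
            g_l = 0.5 * np.einsum("lt,ts,ls->", B, dK_dl, B) - 6.0 * np.sum(Ainv * dK_dl)
            return ll, np.concatenate([grad_theta, [g_s, g_l]])

        # shared time kernel with full inter-lead correlation
        u = np.full(12, 1.0 / np.sqrt(12.0))
        s = u @ R                                           # (T,)
        A = s2 * np.eye(self.T) + 12.0 * K
        cf = self._chol(A)
        logdetA = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Ainv_s = cho_solve(cf, s)
        fro = float(np.sum(R * R))
        ss = float(s @ s)
        quad = (fro - ss) / s2 + float(s @ Ainv_s)
        logdet = 11.0 * self.T * np.log(s2) + logdetA
        ll = -0.5 * (quad + logdet + 12.0 * self.T * LOG_2PI)
        if not with_grad:
            return ll

        # Sigma^-1 R in lead-trace form
        SinvR = (R - np.outer(u, s)) / s2 + np.outer(u, Ainv_s)
        grad_theta = np.einsum("lt,ltp->p", SinvR, j12)
        Ainv = cho_solve(cf, np.eye(self.T))
        dK_ds = 12.0 * 2.0 * K / sigma_gp
        dK_dl = 12.0 * K * self.D2 / l_gp**3
        g_s = 0.5 * (Ainv_s @ dK_ds @ Ainv_s) - 0.5 * np.sum(Ainv * dK_ds)
        g_l = 0.5 * (Ainv_s @ dK_dl @ Ainv_s) - 0.5 * np.sum(Ainv * dK_dl)
        return ll, np.concatenate([grad_theta, [g_s, g_l]])


def log_likelihood(model: BLNMModel, dataset: EcgDataset, target: ECG12,
                   theta, sigma_gp, l_gp,
                   error_model: ErrorModel = ErrorModel()) -> float:
    """Convenience wrapper around :class:`EcgLikelihood`."""
    return EcgLikelihood(model, dataset, target, error_model).log_likelihood(theta, sigma_gp, l_gp)


def dense_log_likelihood(model: BLNMModel, dataset: EcgDataset, target: ECG12,
                         theta, sigma_gp, l_gp,
                         error_model: ErrorModel = ErrorModel()) -> float:
    """Reference evaluation building the dense 12T x 12T covariance (cross
    check for the factorized path; quadratic memory, small grids only)."""
    lik = EcgLikelihood(model, dataset, target, error_model)
    m12, _ = lik.predict(theta)
    r = (lik.target - m12).ravel()                  # stacked lead-major
    T = lik.T
    K = sigma_gp**2 * np.exp(-lik.D2 / (2.0 * l_gp**2))
    if error_model.structure == "per_lead":
        Sigma = np.kron(np.eye(12), K)
        Sigma += 1e-10 * np.eye(12 * T)
    else:
        Sigma = np.kron(np.ones((12, 12)), K)
        # jitter on the lead-mean block only, mirroring the factorized path
        Sigma += 1e-10 * np.kron(np.full((12, 12), 1.0 / 12.0), np.eye(T))
    Sigma += error_model.sigma_meas**2 * np.eye(12 * T)
    cf = cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    return -0.5 * (quad + logdet + 12 * T * LOG_2PI)


# --------------------------------------------------------------------------
# posterior in unconstrained coordinates
# --------------------------------------------------------------------------

def _sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


class _Posterior:
    """Log posterior and gradient on R^9: logit-transformed box for the 7
    parameters, log-transformed positive GP scales."""

    def __init__(self, lik: EcgLikelihood, priors: PriorSpec):
        self.lik = lik
        self.lo = priors.lo
        self.hi = priors.hi
        self.em = lik.em

    def constrain(self, x):
        sig = _sigmoid(x[:7])
        theta = self.lo + (self.hi - self.lo) * sig
        return theta, np.exp(x[7]), np.exp(x[8])

    def logp_and_grad(self, x):
        # keep the logit map away from its poles (exact 0/1 would give
        # -inf Jacobian terms and NaN gradients)
        sig = np.clip(_sigmoid(x[:7]), 1e-12, 1.0 - 1e-12)
        theta = self.lo + (self.hi - self.lo) * sig
        sgp, lgp = np.exp(x[7]), np.exp(x[8])
        ll, g = self.lik.log_likelihood(theta, sgp, lgp, with_grad=True)

        # box Jacobian: log|dtheta/dx| = log(hi-lo) + log sig + log(1-sig)
        logj = np.sum(np.log(self.hi - self.lo) + np.log(sig) + np.log1p(-sig))
        # truncated-normal hyperpriors on the positive scale + log Jacobian
        m, s = self.em.hyper_mean, self.em.hyper_scale
        logp = ll + logj
        logp += -0.5 * ((sgp - m) / s) ** 2 + x[7]
        logp += -0.5 * ((lgp - m) / s) ** 2 + x[8]

        grad = np.empty(9)
        grad[:7] = g[:7] * (self.hi - self.lo) * sig * (1 - sig) + (1.0 - 2.0 * sig)
        grad[7] = g[7] * sgp - (sgp - m) / s**2 * sgp + 1.0
        grad[8] = g[8] * lgp - (lgp - m) / s**2 * lgp + 1.0
        return logp, grad

    def initial_point(self, rng, n_candidates: int = 1):
        """Independent prior draw(s) mapped to unconstrained coordinates.

        With n_candidates > 1 the highest-log-posterior draw is kept:
        prior draws occasionally land in narrow spurious likelihood
        spikes of negligible posterior mass (squeezed against the box
        boundary by surrogate wiggles), and a chain started there cannot
        cross the barrier back to the dominant mode."""
        best_x, best_lp = None, -np.inf
        for _ in range(max(1, n_candidates)):
            u = rng.uniform(0.02, 0.98, 7)      # away from the logit poles
            x = np.empty(9)
            x[:7] = np.log(u / (1 - u))
            for k in (7, 8):
                v = -1.0
                while v <= 0:
                    v = rng.normal(self.em.hyper_mean, self.em.hyper_scale)
                x[k] = np.log(v)
            if n_candidates <= 1:
                return x
            lp = self.logp_and_grad(x)[0]
            if lp > best_lp:
                best_x, best_lp = x, lp
        return best_x


# --------------------------------------------------------------------------
# No-U-Turn sampler
# --------------------------------------------------------------------------

_DELTA_MAX = 1000.0


def _nuts_chain(logp_and_grad, x0, n_warmup, n_draws, target_accept, rng,
                max_depth=10):
    """One NUTS chain: Hoffman-Gelman doubling with slice acceptance,
    dual-averaged step size and a diagonal metric re-estimated mid-warmup.
    Returns (draws, n_divergent, step_size)."""
    dim = len(x0)
    metric = np.ones(dim)              # diagonal inverse mass
    x = np.asarray(x0, float)
    logp, grad = logp_and_grad(x)

    def leapfrog(x, p, grad, eps):
        p = p + 0.5 * eps * grad
        x = x + eps * metric * p
        logp, grad = logp_and_grad(x)
        p = p + 0.5 * eps * grad
        return x, p, logp, grad

    def kinetic(p):
        return 0.5 * float(np.sum(metric * p * p))

    # reasonable initial step size
    eps = 0.1
    p0 = rng.standard_normal(dim) / np.sqrt(metric)
    H0 = logp - kinetic(p0)
    x1, p1, logp1, _ = leapfrog(x, p0, grad, eps)
    H1 = logp1 - kinetic(p1)
    a = 1.0 if (H1 - H0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**a
        x1, p1, logp1, _ = leapfrog(x, p0, grad, eps)
        H1 = logp1 - kinetic(p1)
        if not np.isfinite(H1) or a * (H1 - H0) < a * np.log(0.5):
            break

    mu = np.log(10.0 * eps)
    log_eps_bar, H_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    # expanding metric-adaptation windows (initial buffer, doubling
    # windows, terminal step-size-only buffer)
    init_buffer, term_buffer, base_window = 75, 50, 25
    window_ends = []
    if n_warmup >= init_buffer + term_buffer + base_window:
        end = init_buffer + base_window
        size = base_window
        while True:
            nxt_size = size * 2
            if end + nxt_size + term_buffer > n_warmup:
                end = n_warmup - term_buffer
                window_ends.append(end)
                break
            window_ends.append(end)
            size = nxt_size
            end += size
    window = []

    divergent = 0
    draws = np.empty((n_draws, dim))

    n_total = n_warmup + n_draws
    for it in range(n_total):
        p0 = rng.standard_normal(dim) / np.sqrt(metric)
        H0 = logp - kinetic(p0)
        log_u = H0 + np.log(rng.uniform())

        x_minus = x_plus = x
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        x_new, logp_new, grad_new = x, logp, grad
        n_good = 1
        keep_going = True
        depth = 0
        alpha_sum, n_alpha = 0.0, 0
        diverged = False

        def build(x, p, g, direction, depth):
            nonlocal alpha_sum, n_alpha, diverged
            if depth == 0:
                x1, p1, logp1, g1 = leapfrog(x, p, g, direction * eps)
                H1 = logp1 - kinetic(p1)
                if not np.isfinite(H1):
                    H1 = -np.inf
                n1 = 1 if log_u <= H1 else 0
                s1 = log_u < H1 + _DELTA_MAX
                if not s1:
                    diverged = True
                alpha_sum += np.exp(min(0.0, H1 - H0)) if np.isfinite(H1) else 0.0
                n_alpha += 1
                return x1, p1, g1, x1, p1, g1, x1, logp1, g1, n1, s1
            xm, pm, gm, xp, pp, gp, xc, lc, gc, n1, s1 = build(x, p, g, direction, depth - 1)
            if s1:
                if direction == -1:
                    xm, pm, gm, _, _, _, xc2, lc2, gc2, n2, s2 = build(xm, pm, gm, direction, depth - 1)
                else:
                    _, _, _, xp, pp, gp, xc2, lc2, gc2, n2, s2 = build(xp, pp, gp, direction, depth - 1)
                if n1 + n2 > 0 and rng.uniform() < n2 / (n1 + n2):
                    xc, lc, gc = xc2, lc2, gc2
                dx = xp - xm
                s1 = s2 and (dx @ (metric * pm)) >= 0 and (dx @ (metric * pp)) >= 0
                n1 += n2
            return xm, pm, gm, xp, pp, gp, xc, lc, gc, n1, s1

        while keep_going and depth < max_depth:
            direction = -1 if rng.uniform() < 0.5 else 1
            if direction == -1:
                x_minus, p_minus, g_minus, _, _, _, xc, lc, gc, n_sub, s_sub = build(
                    x_minus, p_minus, g_minus, -1, depth
                )
            else:
                _, _, _, x_plus, p_plus, g_plus, xc, lc, gc, n_sub, s_sub = build(
                    x_plus, p_plus, g_plus, 1, depth
                )
            if s_sub and n_sub > 0 and rng.uniform() < min(1.0, n_sub / n_good):
                x_new, logp_new, grad_new = xc, lc, gc
            n_good += n_sub
            dx = x_plus - x_minus
            keep_going = s_sub and (dx @ (metric * p_minus)) >= 0 and (dx @ (metric * p_plus)) >= 0
            depth += 1

        x, logp, grad = x_new, logp_new, grad_new
        if it >= n_warmup and diverged:
            divergent += 1

        if it < n_warmup:
            # dual averaging toward the target acceptance statistic
            adapt_count += 1
            accept_stat = alpha_sum / max(n_alpha, 1)
            H_bar = (1 - 1 / (adapt_count + t0)) * H_bar + (target_accept - accept_stat) / (adapt_count + t0)
            log_eps = mu - np.sqrt(adapt_count) / gamma * H_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= init_buffer:
                window.append(x.copy())
            if window_ends and it == window_ends[0] - 1:
                window_ends.pop(0)
                if len(window) > 10:
                    var = np.var(np.asarray(window), axis=0, ddof=1)
                    n_w = len(window)
                    # regularized toward unity as Stan does
                    metric = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                    metric = np.maximum(metric, 1e-8)
                window = []
                # restart step-size adaptation around the current value
                mu = np.log(10.0 * eps)
                H_bar, log_eps_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x

    return draws, divergent, eps


def run_nuts(
    model: BLNMModel,
    dataset: EcgDataset,
    target: ECG12,
    priors: PriorSpec,
    error_model: ErrorModel = ErrorModel(),
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    target_accept: float = 0.9,
    seed: int = 0,
    max_depth: int = 10,
    init_candidates: int = 25,
) -> PosteriorSamples:
    """Sample the joint posterior of (theta, sigma_GP, l_GP).

    Each chain is initialized from its own independent prior draws (the
    best of ``init_candidates`` by log posterior, see
    ``_Posterior.initial_point``) and seeded from ``seed``; more than 10%
    divergent draws in any chain is flagged in the result (not fatal)."""
    lik = EcgLikelihood(model, dataset, target, error_model)
    post = _Posterior(lik, priors)
    all_draws = np.empty((chains, draws, 9))
    divs = np.empty(chains, dtype=int)
    epss = np.empty(chains)
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        x0 = post.initial_point(rng, n_candidates=init_candidates)
        xs, d, e = _nuts_chain(post.logp_and_grad, x0, warmup, draws, target_accept, rng,
                               max_depth=max_depth)
        # map back to the constrained scale
        sig = _sigmoid(xs[:, :7])
        all_draws[c, :, :7] = post.lo + (post.hi - post.lo) * sig
        all_draws[c, :, 7] = np.exp(xs[:, 7])
        all_draws[c, :, 8] = np.exp(xs[:, 8])
        divs[c] = d
        epss[c] = e
    return PosteriorSamples(all_draws, divergences=divs, step_sizes=epss)


# --------------------------------------------------------------------------
# diagnostics and posterior predictive
# --------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float:
    """Classic (non-split) potential scale reduction factor.

    ``chains``: (n_chains, n_draws) for one quantity.  Identical chains
    give sqrt((n-1)/n) < 1; diverging chain means drive the statistic far
    above 1."""
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * np.var(means, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def posterior_predictive(
    samples: PosteriorSamples,
    model: BLNMModel,
    dataset: EcgDataset,
    t_ms: np.ndarray | None = None,
    n_sd: float = 5.0,
    max_draws: int = 400,
    seed: int = 0,
):
    """Push posterior parameter draws through the surrogate.

    Returns (t_ms, mean (12, T), sd (12, T), band) where band is the pair
    (mean - n_sd * sd, mean + n_sd * sd) per lead and time point."""
    from cardiotwin.blnm import predict_12lead

    if t_ms is None:
        t_ms = dataset.t
    flat = samples.flat()
    if len(flat) > max_draws:
        rng = np.random.default_rng(seed)
        flat = flat[rng.choice(len(flat), max_draws, replace=False)]
    preds = np.stack([
        predict_12lead(model.config, model.weights, row[:7], t_ms, dataset.normalizer).traces
        for row in flat
    ])
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0)
    return t_ms, mean, sd, (mean - n_sd * sd, mean + n_sd * sd)
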