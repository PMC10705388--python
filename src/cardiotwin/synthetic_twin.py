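"""Synthetic-twin data layer: Latin-hypercube simulation campaigns over
the 7-parameter space, dataset assembly, and a noisy "virtual patient"
target with known ground truth.

The parameter space is the calibration range of the physics-based model:
three ionic conductances (G_CaL, G_Na, G_Kr), three conductivities
(D_ani, D_iso, D_purk) and the left-bundle stimulation delay t_LV_stim.
A campaign forward-simulates each draw for one 600 ms beat on a synthetic
anatomy, samples the 9 electrode leads every 5 ms, nondimensionalizes
per lead on the training split and stores everything as an EcgDataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import qmc

from cardiotwin import anatomy as anat
from cardiotwin import monodomain as mono
from cardiotwin import ttp_ionic as ion
from cardiotwin.blnm import EcgDataset
from cardiotwin.ecg import ECG12, LEAD9, LEAD12, Normalizer, ecg12_from_9, fit_normalizer

PARAM_NAMES = ("G_CaL", "G_Na", "G_Kr", "D_ani", "D_iso", "D_purk", "t_LV_stim")


@dataclass(frozen=True)
class ParameterSpace:
    """The 7 sampled intervals (units: G_CaL cm/ms/uF; G_Na, G_Kr nS/pF;
    conductivities mm^2/ms; t_LV_stim ms)."""

    lo: tuple = (1.99e-5, 7.42, 0.08, 0.008298, 0.002766, 1.0, 0.0)
    hi: tuple = (7.96e-5, 29.68, 0.31, 0.033192, 0.011064, 3.5, 100.0)

    def __post_init__(self):
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        if len(lo) != 7 or len(hi) != 7 or np.any(hi <= lo):
            raise ValueError("need 7 nonempty intervals")

    @property
    def lo_arr(self):
        return np.asarray(self.lo, float)

    @property
    def hi_arr(self):
        return np.asarray(self.hi, float)

    def normalize(self, theta: np.ndarray) -> np.ndarray:
        """Affine map of dimensional draws onto [-1, 1]^7."""
        return 2.0 * (np.asarray(theta, float) - self.lo_arr) / (self.hi_arr - self.lo_arr) - 1.0

    def denormalize(self, theta_norm: np.ndarray) -> np.ndarray:
        return self.lo_arr + (np.asarray(theta_norm, float) + 1.0) * 0.5 * (self.hi_arr - self.lo_arr)

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, float)
        return bool(np.all(theta >= self.lo_arr - 1e-12) and np.all(theta <= self.hi_arr + 1e-12))


def lhs_sample(space: ParameterSpace, n: int, seed: int = 0) -> np.ndarray:
    """Plain (maximin-free) Latin hypercube: one draw per stratum per
    dimension, seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = qmc.LatinHypercube(d=7, seed=seed).random(n)
    return space.lo_arr + u * (space.hi_arr - space.lo_arr)


def _simulate_draw(anatomy, theta, dt, stride_ms):
    """One forward beat: theta -> raw 9-lead traces on the 5 ms grid."""
    cond = mono.ConductivityParams(D_ani=theta[3], D_iso=theta[4], D_purk=theta[5])
    ionic = ion.IonicConductances(g_CaL=theta[0], g_Na=theta[1], g_Kr=theta[2])
    stim = mono.StimulusProtocol(t_LV_stim=theta[6])
    res = mono.run_simulation(
        anatomy, cond=cond, ionic=ionic, stimulus=stim,
        dt=dt, output_stride=stride_ms, compute_maps=False,
    )
    return res.lead_traces


def generate_dataset(
    anatomy: anat.Anatomy | None = None,
    n_sims: int = 40,
    seed: int = 0,
    space: ParameterSpace = ParameterSpace(),
    dt: float = 0.05,
    stride_ms: float = 5.0,
    train_fraction: float = 0.75,
) -> EcgDataset:
    """Run an LHS campaign and assemble the normalized dataset.

    The train/test partition keeps the published 3:1 proportion (desk
    default 40 simulations -> 30/10).  The normalizer is fitted on the
    training split only; failed simulations are excluded together with
    their parameter rows and counted in ``meta``."""
    if anatomy is None:
        anatomy = anat.slab_preset()
    draws = lhs_sample(space, n_sims, seed=seed)
    traces, kept, failures = [], [], 0
    for i, theta in enumerate(draws):
        try:
            lt = _simulate_draw(anatomy, theta, dt, stride_ms)
            traces.append(lt.traces)
            kept.append(i)
        except (FloatingPointError, RuntimeError):
            failures += 1
    if not kept:
        raise RuntimeError("every simulation in the campaign failed")
    params = draws[kept]
    leads_raw = np.stack(traces)          # (n, 9, T)
    t = lt.t

    n = len(params)
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])

    normalizer = fit_normalizer(leads_raw[train_idx], t_hb=600.0)
    leads = np.stack([normalizer.apply(tr) for tr in leads_raw])
    return EcgDataset(
        t=t,
        params=params,
        params_norm=space.normalize(params),
        leads=leads,
        train_idx=train_idx,
        test_idx=test_idx,
        normalizer=normalizer,
        meta=dict(seed=seed, n_requested=n_sims, n_failed=failures,
                  dt=dt, stride_ms=stride_ms),
    )


@dataclass
class VirtualPatient:
    """Synthetic stand-in for the clinical recording: a forward-simulated
    12-lead ECG at known ground-truth parameters plus i.i.d. Gaussian
    noise of sd 0.1 on the nondimensional scale."""

    theta_true: np.ndarray          # dimensional (7,)
    theta_true_norm: np.ndarray
    ecg_clean: ECG12
    ecg_noisy: ECG12
    noise_sd: float
    seed: int

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "virtual_patient.json", "w") as f:
            json.dump(
                dict(theta_true=self.theta_true.tolist(),
                     theta_true_norm=self.theta_true_norm.tolist(),
                     noise_sd=self.noise_sd, seed=self.seed),
                f, indent=1,
            )
        self.ecg_clean.to_csv(d / "ecg_clean.csv")
        self.ecg_noisy.to_csv(d / "ecg_noisy.csv")


def make_virtual_patient(
    anatomy: anat.Anatomy,
    normalizer: Normalizer,
    theta: np.ndarray | None = None,
    seed: int = 0,
    noise_sd: float = 0.1,
    noise_seed: int = 0,
    space: ParameterSpace = ParameterSpace(),
    dt: float = 0.05,
    stride_ms: float = 5.0,
) -> VirtualPatient:
    """Forward-simulate a ground-truth beat and add measurement noise.

    theta defaults to a seeded draw from the interior (middle 60%) of the
    parameter space so the target sits inside the design."""
    if theta is None:
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.2, 0.8, 7)
        theta = space.lo_arr + u * (space.hi_arr - space.lo_arr)
    theta = np.asarray(theta, float)
    if not space.contains(theta):
        raise ValueError("ground-truth parameters outside the sampled space")
    lt = _simulate_draw(anatomy, theta, dt, stride_ms)
    leads9 = normalizer.apply(lt.traces)
    clean = ecg12_from_9(lt.t, leads9)
    rng_n = np.random.default_rng(noise_seed)
    noisy = ECG12(lt.t, clean.traces + noise_sd * rng_n.standard_normal(clean.traces.shape), validate=noise_sd == 0.0)
    return VirtualPatient(theta, space.normalize(theta), clean, noisy, noise_sd, seed)


def surrogate_virtual_patient(
    model, dataset: EcgDataset, theta_norm: np.ndarray,
    noise_sd: float = 0.1, noise_seed: int = 0,
) -> VirtualPatient:
    """Virtual patient whose clean ECG comes from the trained surrogate
    itself (self-consistency targets for recovery and coverage studies)."""
    from cardiotwin.blnm import predict_12lead

    theta_norm = np.asarray(theta_norm, float)
    clean = predict_12lead(model.config, model.weights, theta_norm, dataset.t, dataset.normalizer)
    rng = np.random.default_rng(noise_seed)
    noisy = ECG12(clean.t, clean.traces + noise_sd * rng.standard_normal(clean.traces.shape), validate=noise_sd == 0.0)
    space = ParameterSpace()
    return VirtualPatient(space.denormalize(theta_norm), theta_norm, clean, noisy, noise_sd, noise_seed)


# --------------------------------------------------------------------------
# plain-text interchange (published-repository layout)
# --------------------------------------------------------------------------

def write_published_layout(dataset: EcgDataset, clinical: ECG12, path):
    """Write the plain-text layout ``read_published_dataset`` expects:

        <path>/train/parameters.csv     rows x 7 named columns
        <path>/train/ecg_<i>.csv        t_ms + 9 lead columns per sample
        <path>/test/...                 likewise
        <path>/clinical_ecg.csv         t_ms + 12 lead columns
    """
    import pandas as pd

    root = Path(path)
    for split, idx in (("train", dataset.train_idx), ("test", dataset.test_idx)):
        d = root / split
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(dataset.params[idx], columns=PARAM_NAMES).to_csv(d / "parameters.csv", index=False)
        for j, i in enumerate(idx):
            df = pd.DataFrame({"t_ms": dataset.t, **{l: dataset.leads[i, k] for k, l in enumerate(LEAD9)}})
            df.to_csv(d / f"ecg_{j:03d}.csv", index=False)
    clinical.to_csv(root / "clinical_ecg.csv")


def read_published_dataset(path) -> tuple[EcgDataset, ECG12]:
    """Read a local copy of the public simulation dataset in the layout of
    ``write_published_layout`` and return (EcgDataset, clinical ECG12).

    Files must already be present locally (no downloading)."""
    import pandas as pd

    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory {root} not found")
    space = ParameterSpace()
    params, leads, split_sizes = [], [], []
    for split in ("train", "test"):
        d = root / split
        pfile = d / "parameters.csv"
        if not pfile.exists():
            raise FileNotFoundError(f"missing {pfile}")
        p = pd.read_csv(pfile)
        missing = set(PARAM_NAMES) - set(p.columns)
        if missing:
            raise ValueError(f"{pfile} lacks columns {sorted(missing)}")
        split_sizes.append(len(p))
        params.append(p[list(PARAM_NAMES)].to_numpy())
        for j in range(len(p)):
            f = d / f"ecg_{j:03d}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing {f}")
            df = pd.read_csv(f)
            leads.append(df[list(LEAD9)].to_numpy().T)
    t = df["t_ms"].to_numpy()
    params = np.concatenate(params)
    leads = np.stack(leads)
    n_train = split_sizes[0]
    normalizer = fit_normalizer(leads[:n_train], t_hb=float(t[-1]))
    cdf = pd.read_csv(root / "clinical_ecg.csv")
    clinical = ECG12(cdf["t_ms"].to_numpy(), cdf[list(LEAD12)].to_numpy().T)
    dataset = EcgDataset(
        t=t, params=params, params_norm=space.normalize(params), leads=leads,
        train_idx=np.arange(n_train), test_idx=np.arange(n_train, len(params)),
        normalizer=normalizer, meta=dict(source=str(root)),
    )
    return dataset, clinical
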