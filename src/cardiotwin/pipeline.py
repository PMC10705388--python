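"""Config-driven orchestration of the digital-twin workflow.

Stages mirror the analysis end to end on the synthetic twin:

    dataset      LHS campaign of forward simulations -> HDF5 ensemble
    tune         K-fold LHS hyperparameter search for the surrogate
    train        fit the BLNM on the training split
    patient      simulate the noisy virtual patient (known ground truth)
    calibrate    multi-start Nelder-Mead point estimate
    sensitivity  Shapley effects of the ECG mismatch around the estimate
    uq           NUTS posterior for parameters + GP hyperparameters
    trial        baseline vs left/right bundle-branch-block maps
    report       collate summaries of everything present

Each stage reads its upstream artifacts from the output directory, writes
versioned outputs plus a JSON-lines log entry (stage, seed, wall time,
config hash), and never mutates another stage's artifacts.  A single
global seed fans out to per-stage seeds through numpy's SeedSequence.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from cardiotwin import anatomy as anat
from cardiotwin import monodomain as mono
from cardiotwin import synthetic_twin as twin
from cardiotwin.blnm import BLNMConfig, BLNMModel, EcgDataset, count_parameters, dataset_mse, kfold_tune, predict_12lead, train
from cardiotwin.calibrate import CalibrationResult, nelder_mead_calibrate
from cardiotwin.ecg import ECG12
from cardiotwin.shapley import InputDistribution, mismatch_cost_factory, shapley_effects
from cardiotwin.uq import ErrorModel, PriorSpec, posterior_predictive, run_nuts

STAGES = ("dataset", "tune", "train", "patient", "calibrate", "sensitivity", "uq", "trial", "report")

DEFAULT_CONFIG = dict(
    anatomy=dict(preset="slab"),
    dataset=dict(n_sims=40, dt=0.05, stride_ms=5.0),
    tune=dict(enabled=False, K=5, n_configs=50, iters_per_fit=200),
    blnm=dict(n_layers=4, n_neurons=16, n_states=10, disentanglement=1, max_iters=3000),
    patient=dict(noise_sd=0.1),
    calibrate=dict(n_trials=100),
    shapley=dict(n_perm=2000, n_outer=50, n_inner=3, n_var=5000, scale=0.2),
    uq=dict(chains=4, warmup=1000, draws=1000, target_accept=0.9, iota=0.2,
            sigma_meas=0.1, stride_ms=5.0, max_depth=10),
)


def _merge(base, override):
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def load_config(path=None):
    cfg = DEFAULT_CONFIG
    if path is not None:
        import yaml

        with open(path) as f:
            cfg = _merge(cfg, yaml.safe_load(f) or {})
    return _merge(cfg, {})


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)])
    return int(ss.generate_state(1)[0] % (2**31))


def _log(outdir: Path, stage: str, seed: int, t0: float, cfg_section):
    entry = dict(
        stage=stage, seed=seed, wall_s=round(time.time() - t0, 2),
        config_hash=hashlib.sha256(json.dumps(cfg_section, sort_keys=True).encode()).hexdigest()[:12],
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    with open(outdir / "pipeline_log.jsonl", "a") as f:
        f.write(json.dumps(entry) + "\n")


def _anatomy(cfg):
    kind = cfg["anatomy"].get("preset", "slab")
    if kind == "slab":
        return anat.slab_preset()
    if kind == "hlhs":
        return anat.hlhs_preset()
    raise ValueError(f"unknown anatomy preset {kind!r}")


def _require(path: Path, producer: str):
    if not path.exists():
        raise FileNotFoundError(f"missing artifact {path.name}: run the '{producer}' stage first")
    return path


def run_stage(stage: str, config: dict, seed: int, outdir) -> dict:
    """Run one stage; returns a dict of artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    s = stage_seed(seed, stage)
    art = {}

    if stage == "dataset":
        ds = twin.generate_dataset(
            anatomy=_anatomy(config), seed=s, **config["dataset"]
        )
        ds.to_hdf5(outdir / "dataset.h5")
        art["dataset"] = outdir / "dataset.h5"

    elif stage == "tune":
        ds = EcgDataset.from_hdf5(_require(outdir / "dataset.h5", "dataset"))
        c = config["tune"]
        best, table = kfold_tune(ds, K=c["K"], n_configs=c["n_configs"],
                                 iters_per_fit=c["iters_per_fit"], seed=s)
        table.to_csv(outdir / "tuning_table.csv", index=False)
        with open(outdir / "tuned_config.json", "w") as f:
            json.dump(dict(n_layers=best.n_layers, n_neurons=best.n_neurons,
                           n_states=best.n_states, disentanglement=best.disentanglement), f)
        art["table"] = outdir / "tuning_table.csv"

    elif stage == "train":
        ds = EcgDataset.from_hdf5(_require(outdir / "dataset.h5", "dataset"))
        c = dict(config["blnm"])
        tuned = outdir / "tuned_config.json"
        if tuned.exists():
            c.update(json.load(open(tuned)))
        cfg = BLNMConfig(c["n_layers"], c["n_neurons"], c["n_states"], c["disentanglement"])
        model = train(cfg, ds, max_iters=c["max_iters"], seed=s)
        model.to_json(outdir / "blnm_model.json")
        tt, th, y = ds.rows(ds.test_idx)
        test_mse = dataset_mse(None, cfg, model.weights, tt, th, y) if len(ds.test_idx) else float("nan")
        with open(outdir / "training_summary.json", "w") as f:
            json.dump(dict(n_parameters=count_parameters(cfg),
                           final_train_mse=model.loss_history[-1] if model.loss_history else None,
                           test_mse=test_mse), f, indent=1)
        art["model"] = outdir / "blnm_model.json"

    elif stage == "patient":
        ds = EcgDataset.from_hdf5(_require(outdir / "dataset.h5", "dataset"))
        vp = twin.make_virtual_patient(
            _anatomy(config), ds.normalizer, seed=s,
            noise_sd=config["patient"]["noise_sd"], noise_seed=s + 1,
        )
        vp.save(outdir / "patient")
        art["patient"] = outdir / "patient"

    elif stage == "calibrate":
        ds = EcgDataset.from_hdf5(_require(outdir / "dataset.h5", "dataset"))
        model = BLNMModel.from_json(_require(outdir / "blnm_model.json", "train"))
        target = _load_patient_ecg(outdir)
        res = nelder_mead_calibrate(model, ds, target, n_trials=config["calibrate"]["n_trials"], seed=s)
        res.to_json(outdir / "calibration.json", space=twin.ParameterSpace())
        res.trials_to_csv(outdir / "calibration_trials.csv")
        art["calibration"] = outdir / "calibration.json"

    elif stage == "sensitivity":
        ds = EcgDataset.from_hdf5(_require(outdir / "dataset.h5", "dataset"))
        model = BLNMModel.from_json(_require(outdir / "blnm_model.json", "train"))
        target = _load_patient_ecg(outdir)
        cal = json.load(open(_require(outdir / "calibration.json", "calibrate")))
        c = config["shapley"]
        dist = InputDistribution(center=np.asarray(cal["theta_nm"]), scale=c["scale"])
        res = shapley_effects(
            mismatch_cost_factory(model, ds, target), dist,
            n_perm=c["n_perm"], n_var=c["n_var"], n_outer=c["n_outer"],
            n_inner=c["n_inner"], seed=s,
        )
        res.to_csv(outdir / "shapley.csv", names=list(twin.PARAM_NAMES))
        art["shapley"] = outdir / "shapley.csv"

    elif stage == "uq":
        ds = EcgDataset.from_hdf5(_require(outdir / "dataset.h5", "dataset"))
        model = BLNMModel.from_json(_require(outdir / "blnm_model.json", "train"))
        target = _load_patient_ecg(outdir)
        cal = json.load(open(_require(outdir / "calibration.json", "calibrate")))
        c = config["uq"]
        stride = int(round(c["stride_ms"] / (target.t[1] - target.t[0]))) or 1
        sub = ECG12(target.t[::stride], target.traces[:, ::stride], validate=False)
        priors = PriorSpec.from_center(np.asarray(cal["theta_nm"]), iota=c["iota"])
        em = ErrorModel(sigma_meas=c["sigma_meas"])
        ps = run_nuts(model, ds, sub, priors, error_model=em,
                      chains=c["chains"], warmup=c["warmup"], draws=c["draws"],
                      target_accept=c["target_accept"], seed=s, max_depth=c["max_depth"])
        ps.to_csv(outdir / "posterior_draws.csv")
        summ = ps.summary()
        summ.to_csv(outdir / "posterior_summary.csv", index=False)
        t_ms, mean, sd, band = posterior_predictive(ps, model, ds)
        import pandas as pd

        rows = {"t_ms": t_ms}
        from cardiotwin.ecg import LEAD12

        for i, l in enumerate(LEAD12):
            rows[f"{l}_mean"] = mean[i]
            rows[f"{l}_sd"] = sd[i]
        pd.DataFrame(rows).to_csv(outdir / "posterior_predictive.csv", index=False)
        with open(outdir / "uq_summary.json", "w") as f:
            json.dump(dict(
                rhat_max=float(summ["rhat"].max()),
                divergences=ps.divergences.tolist(),
                mean_sigma_gp2=float(np.mean(ps.flat()[:, 7] ** 2)),
            ), f, indent=1)
        art["posterior"] = outdir / "posterior_draws.csv"

    elif stage == "trial":
        cal = json.load(open(_require(outdir / "calibration.json", "calibrate")))
        theta = np.asarray(cal["theta_dimensional"])
        anatomy = _anatomy(config)
        from cardiotwin.io import write_mesh_vtu
        from cardiotwin.monodomain import bundle_branch_block, maps_to_csv
        from cardiotwin.ttp_ionic import IonicConductances

        scen = {"baseline": anatomy.purkinje,
                "left_block": bundle_branch_block(anatomy.purkinje, "LEFT"),
                "right_block": bundle_branch_block(anatomy.purkinje, "RIGHT")}
        tdir = outdir / "trial"
        tdir.mkdir(exist_ok=True)
        for name, purk in scen.items():
            a = anat.Anatomy(anatomy.mesh, anatomy.phi, anatomy.fibers, purk,
                             anatomy.electrodes, anatomy.cell_types)
            res = mono.run_simulation(
                a,
                cond=mono.ConductivityParams(D_ani=theta[3], D_iso=theta[4], D_purk=theta[5]),
                ionic=IonicConductances(g_CaL=theta[0], g_Na=theta[1], g_Kr=theta[2]),
                stimulus=mono.StimulusProtocol(t_LV_stim=theta[6]),
            )
            maps_to_csv(tdir / f"{name}_maps.csv", res.activation, res.repolarization)
            write_mesh_vtu(tdir / f"{name}.vtu", anatomy.mesh,
                           point_data=dict(activation=np.nan_to_num(res.activation, nan=-1.0),
                                           repolarization=np.nan_to_num(res.repolarization, nan=-1.0)))
        art["trial"] = tdir

    elif stage == "report":
        art["report"] = write_report(outdir)

    else:
        raise ValueError(f"unknown stage {stage!r}; stages: {STAGES}")

    _log(outdir, stage, s, t0, config.get(stage, {}))
    return art


def _load_patient_ecg(outdir: Path) -> ECG12:
    import pandas as pd

    from cardiotwin.ecg import LEAD12

    f = _require(outdir / "patient" / "ecg_noisy.csv", "patient")
    df = pd.read_csv(f)
    return ECG12(df["t_ms"].to_numpy(), df[list(LEAD12)].to_numpy().T, validate=False)


def write_report(outdir) -> Path:
    """Markdown summary of whatever stages have produced artifacts."""
    outdir = Path(outdir)
    lines = ["# Synthetic-twin pipeline report", ""]
    cal = outdir / "calibration.json"
    if cal.exists():
        d = json.load(open(cal))
        lines += ["## Calibrated parameters (Nelder-Mead average)", "",
                  "| parameter | normalized | dimensional |", "|---|---|---|"]
        from cardiotwin.synthetic_twin import PARAM_NAMES, ParameterSpace

        dim = d.get("theta_dimensional", ParameterSpace().denormalize(np.asarray(d["theta_nm"])).tolist())
        units = ("cm/ms/uF", "nS/pF", "nS/pF", "mm^2/ms", "mm^2/ms", "mm^2/ms", "ms")
        for n, v, x, u in zip(PARAM_NAMES, d["theta_nm"], dim, units):
            lines.append(f"| {n} | {v:+.3f} | {x:.4g} {u} |")
        lines += ["", f"Target MSE at the averaged estimate: {d['target_mse']:.4g}", ""]
    shp = outdir / "shapley.csv"
    if shp.exists():
        import pandas as pd

        df = pd.read_csv(shp)
        lines += ["## Shapley effects (fraction of mismatch variance)", "",
                  df.to_markdown(index=False), ""]
    summ = outdir / "posterior_summary.csv"
    if summ.exists():
        import pandas as pd

        df = pd.read_csv(summ)
        lines += ["## Posterior summary", "", df.to_markdown(index=False), ""]
        bad = df[df["rhat"] >= 1.1]
        if len(bad):
            lines += ["**WARNING: Gelman-Rubin >= 1.1 for: "
                      + ", ".join(bad["quantity"]) + "**", ""]
        else:
            lines += ["All Gelman-Rubin statistics < 1.1.", ""]
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
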