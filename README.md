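# cardiotwin

Desk-scale digital twinning of cardiac electrophysiology. The package
implements the full chain that turns a mechanistic heart model into a
statistically calibrated replica of a 12-lead ECG:

1. **Forward model** — the monodomain reaction-diffusion equation on a
   tetrahedral anatomy, coupled one-way to a 1D endocardial Purkinje
   network, with the ten Tusscher–Panfilov (2006) human ventricular ionic
   model (12 gating variables, 6 concentration-like variables) at every
   node and rule-based fiber fields. Pseudo-ECGs are computed as the
   infinite-conductor integral Φₑ(xₑ) = −∫ ∇Φ·∇(1/‖x−xₑ‖) dV at nine
   torso electrodes and expanded into the standard 12 leads
   (I = LA−RA, II = F−RA, III = F−LA, aVL = (I−III)/2, aVR = −(I+II)/2,
   aVF = (II+III)/2).
2. **Surrogate** — a Branched Latent Neural Map (BLNM): a partially
   connected feedforward network z(t) = BLNM(t, θ_EP; w) from normalized
   time and 7 cell-to-organ parameters
   θ_EP = (G_CaL, G_Na, G_Kr, D_ani, D_iso, D_purk, t_LVstim) to the 9
   electrode leads plus unsupervised latent states, trained full-batch
   with BFGS on the MSE of the physical outputs.
3. **Calibration, sensitivity, UQ** — multi-start Nelder-Mead matching of
   a target 12-lead ECG; variance-based Shapley effects of the mismatch
   under a Gaussian-copula input law; and a No-U-Turn sampler over the 7
   parameters plus the amplitude and length of a Gaussian-process
   discrepancy term,
   z_clinical ~ N(z_ECG(θ), σ_meas² I + k(t̃,t̃′; σ_GP, l_GP)),
   with Gelman-Rubin convergence checks and posterior-predictive bands.

Because no patient data ship with the package, a synthetic-twin data
layer stands in for the clinic: Latin-hypercube simulation campaigns over
the calibration ranges generate the training ensemble, and a noisy
"virtual patient" with known ground-truth parameters provides the
calibration target, so every stage of the workflow can be exercised and
scored end to end.

## Worked example

```python
import numpy as np
from cardiotwin import (slab_preset, generate_dataset, train, BLNMConfig,
                        surrogate_virtual_patient, nelder_mead_calibrate)

dataset = generate_dataset(n_sims=40, seed=1234)       # ~7 min: 40 beats
model = train(BLNMConfig(4, 16, 10, 1), dataset, max_iters=3000, seed=0)

theta_true = np.array([0.25, -0.30, 0.10, 0.40, -0.20, 0.15, -0.35])
patient = surrogate_virtual_patient(model, dataset, theta_true,
                                    noise_sd=0.1, noise_seed=77)
cal = nelder_mead_calibrate(model, dataset, patient.ecg_noisy,
                            n_trials=30, seed=5)
print(np.round(cal.theta_nm, 3), round(cal.target_mse, 4))
```

prints (one run on the authors' machine)

```
[ 0.161 -0.093 -0.024  0.388 -0.235  0.281 -0.347] 0.0104
```

— the averaged normalized estimate of the 7 parameters and the
nondimensional MSE between the fitted surrogate ECG and the noisy
target. The MSE sits at the sd-0.1 noise floor (0.1² = 0.01), i.e. the
surrogate matches the target to within measurement noise; well-sensed
components (here D_ani, D_iso, t_LVstim) land near their true values
while weakly identified ones drift, which is exactly what the Shapley
ranking and the posterior widths of the UQ stage quantify.

The same workflow is scriptable end to end:

```bash
cardiotwin all --seed 1 --out runs/demo       # dataset ... uq, trial, report
```

which leaves a markdown report with the calibration table, Shapley
effects and posterior summary under `runs/demo/`.

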