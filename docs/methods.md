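# Methods

This note records the models, numerical choices and design decisions
behind `cardiotwin`, and what the synthetic-twin experiments do and do
not demonstrate.

## Forward electrophysiology model

**Ionic model.** The ten Tusscher–Panfilov 2006 human ventricular model
is transcribed in `ttp_constants.py`/`ttp_ionic.py` with the published
constants: 12 Hodgkin-Huxley-type gating variables, 6 concentration-like
variables (cytosolic, SR and dyadic-subspace Ca²⁺, Na⁺, K⁺, and the
ryanodine-receptor recovery variable), and transmural variants that
differ in the transient-outward and slow-delayed-rectifier conductances
and the s-gate kinetics. Three maximal conductances (G_CaL, G_Na, G_Kr)
are exposed for calibration; each current term is exactly linear in its
conductance. Time stepping is operator-split: Rush-Larsen for the gates,
explicit Euler for concentrations and potential, ionic variables before
the potential. Default dt is 0.02 ms standalone and 0.05 ms in tissue.
The tissue path uses voltage-lookup tables (0.02 mV grid) for all purely
voltage-dependent terms plus an optional fused numba kernel; table and
exact paths agree to ~0.006 mV over an action potential, far below the
time-discretization error. A test oracle (`tests/oracles/`) transcribes
the model a second time in a different style; both transcriptions agree
to 1e-13 under identical stepping, and the fixed-step scheme converges
to an adaptively integrated (LSODA) reference to < 1 mV at dt = 2.5 µs.
The model rests near −85 mV (the reference model's resting value; no
tuning toward "approximately −90 mV" is applied).

**Tissue model.** The monodomain equation with conductivity tensor
D_M = D_iso I + D_ani f₀⊗f₀ in the myocardium and D_purk I on the 1D
Purkinje network is discretized with P1 finite elements and an
implicit-explicit scheme: reaction explicitly at the nodes (ionic-current
interpolation), diffusion implicitly with a sparse LU factorization
reused across steps. The **consistent** mass matrix is used deliberately:
on the coarse desk-scale meshes, mass lumping blocks wave propagation
outright, while the consistent matrix conducts. Empirically the TTP06
wavefront at the sampled conductivities needs h ≈ 0.5 mm to propagate at
all desk-accessible settings; at the lowest sampled D_iso the transverse
direction still blocks, so Latin-hypercube draws near that corner
produce partially activated beats. These are retained in the ensemble as
legitimate (if extreme) study conditions rather than discarded.

**Coupling and stimulation.** The Purkinje network is advanced first
each step; coupling is one-way. Each Purkinje-myocardial junction fires
once, when its network potential first crosses 0 mV upward, delivering a
2 ms suprathreshold stimulus to a 1.5 mm ball of myocardial vertices (a
single coarse-grid vertex cannot capture the tissue). The right bundle
root (plus its one-ring, for the same capture reason) is stimulated at
t = 0 and the left at t_LVstim ∈ [0, 100] ms; one 600 ms beat is
simulated. Activation maps take the first upward crossing of 0 mV and
repolarization the last downward crossing of −70 mV, linearly
interpolated between 1 ms snapshots; the thresholds bracket the plateau
robustly.

**Anatomy.** Desk-scale stand-ins replace patient geometry: a structured
slab (default 8×8×3 mm at h = 0.5 mm, endocardial face split into
left/right halves so both bundles exist) and a voxelized
two-truncated-ellipsoid biventricular preset with a deliberately
underdeveloped left cavity. The transmural coordinate solves a
Laplace-Dirichlet problem (0 endocardium, 1 epicardium); fibers rotate
linearly in that coordinate from +60° (endo) to −60° (epi) helix angle
with ∓20° transmural tilt; cell types layer endo/mid/epi by transmural
thirds. The Purkinje tree is a seeded binary fractal surface tree (not
the full fractal-tree-and-projection algorithm): per the sensitivity
results downstream, network geometry ranks far below conductances, so a
simplified generator suffices for the synthetic twin. Electrodes sit on
a virtual torso box scaled from the mesh bounding box — V1–V6 on an
anterior arc, LA/RA lateral-superior, F inferior — at least 10 mm off
the tissue, so the 1/r pseudo-ECG kernel is smooth at element scale and
per-tet centroid quadrature is adequate.

## Surrogate

The BLNM maps (t̃, θ̃) ∈ [0,1]×[−1,1]⁷ to n_states outputs; the first 9
are the electrode leads, the rest are unsupervised latent states. For
the first d layers the temporal input feeds a ⌊n/2⌋-wide branch and the
parameters a ⌈n/2⌉-wide branch with no cross-talk; later layers are
dense; hidden activations tanh, output linear. This branch-width
convention reproduces the published optimized configuration's 2,398
trainable parameters exactly (98 + 200 + 5·380 + 200 for 7 layers, 19
neurons, 10 states, d = 2). Weights are Glorot-initialized from a seed.

Training minimizes the MSE of the 9 physical outputs by full-batch BFGS
with strong-Wolfe line search. The inverse-Hessian update is applied
in-package with O(n²) rank-1 (BLAS `ger`) updates; scipy's BFGS forms
the same update with dense matrix products (O(n³) per iteration, ~16 s
at 3,852 weights) and is unusable at these sizes. Gradients come from
hand-written backprop; a forward-mode pass supplies the 7-parameter
Jacobian used by the samplers. K-fold tuning Latin-hypercube samples
(layers, neurons, states, disentanglement) over the published integer
ranges and picks the lowest mean validation MSE.

Desk defaults: 40-simulation campaign on the slab (30 train / 10 test,
the published 3:1 proportion), per-lead min-max normalization to [−1,1]
fitted on the training split, surrogate 4 layers × 16 neurons × 10
states, d = 1, 3,000 BFGS iterations (test MSE ≈ 8·10⁻³ nondimensional;
generalization is seed-sensitive at this ensemble size — occasional
restarts land near 10⁻¹). Lead reconstruction is applied directly on the
normalized traces: the identities I + III = II and aVL + aVR + aVF = 0
are scale-free, and calibration/UQ stay entirely nondimensional.
Observed (noisy) 12-lead targets carry independent per-lead noise and
therefore do not satisfy the identities exactly; the container validates
reconstructed ECGs strictly and skips validation for observational
traces.

## Calibration

The mismatch L(θ̃) is the mean squared difference over all 12 leads and
time points between the surrogate ECG and the target. Nelder-Mead is
restarted from seeded uniform points in [−1,1]⁷ (100 trials by default;
simplex tolerance 1e-4 or 2,000 evaluations; out-of-box iterates are
clamped to the trained domain). The estimate averages the trials whose
final loss lies within 10% (relative) of the best trial. A flat average
over *all* trials was tried first and rejected: on the desk-scale
surrogate the landscape is multimodal, the best restarts hit the global
optimum essentially exactly (loss ~1e-13 on noise-free self-consistent
targets) while stalled restarts pull a flat average ~0.3 away, which
also mis-centers the downstream priors. The full per-trial table is
retained so any other aggregation can be recomputed.

## Shapley effects

Variance-based sensitivity of the mismatch to the 7 parameters uses the
random-permutation estimator with value function
v(J) = E[Var(Y | X₋J)]: per sampled permutation, prefix increments are
estimated with n_outer = 50 conditioning draws × n_inner = 3 inner draws
and credited to the entering parameter; effects normalize by the total
variance and bootstrap CIs resample permutations. The input law is a
Gaussian copula with N(θ̃_NM, 0.2) marginals (independence by default);
samples are clamped to [−1,1] before evaluation. Defaults: 2,000
permutations; the total-variance sample budget is 5,000 draws — the
standard error of a variance estimate scales as √(2/n), and 5,000 keeps
the normalization noise near 2% so it no longer dominates the
estimator's error. On additive test models the estimator matches the
closed-form shares (aᵢ²/Σaⱼ², and the conditional-variance decomposition
in the correlated case) to a few hundredths.

## Bayesian UQ

The likelihood treats the stacked 12×T target as multivariate normal
around the surrogate ECG with covariance σ_meas² I + J₁₂ ⊗ K_t, where
σ_meas = 0.1 is fixed, K_t is a squared-exponential kernel in normalized
time with amplitude σ_GP and length l_GP, and J₁₂ (all-ones lead block)
realizes full inter-lead correlation through the shared time kernel. In
the lead eigenbasis the covariance splits into one T×T block
σ_meas² I + 12 K_t and eleven diagonal blocks, so evaluation and
gradients cost O(T³) instead of O((12T)³); a per-lead block-diagonal
alternative is selectable. A jitter ladder (1e-10 ×100 steps) guards the
Cholesky factorization.

Priors: uniform θ̃_NM,i ± 0.2 clipped to [−1,1] for the parameters;
N(0.01, 1.0) truncated to positive values for σ_GP and l_GP (scale read
as a standard deviation; truncation because both are scales). Sampling
runs an in-package No-U-Turn sampler (Hoffman-Gelman doubling with slice
acceptance, Δ_max = 1000) on unconstrained coordinates — logit for the
box, log for the positive scales, with the Jacobian terms in the target
— using dual-averaged step size at the 90% target acceptance and a
diagonal metric re-estimated over expanding warm-up windows. Each chain
initializes from its own prior draws, keeping the best of 25 by log
posterior: surrogate wiggles occasionally carve narrow spurious spikes
of negligible mass against the box boundary, and a chain started inside
one cannot cross back (the barrier far exceeds the kinetic energy), so
raw single-draw initialization can wreck the convergence diagnostic for
reasons unrelated to the posterior proper. Convergence is summarized by
the classic (non-split) Gelman-Rubin factor; four identical chains give
√((n−1)/n) < 1, and the null case agrees with arviz's split variant to
< 0.02 on stationary chains. Posterior-predictive bands push draws
through the surrogate and report mean ± 5 sd per lead. The observation
grid may be subsampled (10 ms is used for the long acceptance runs) for
tractability.

## Synthetic twin and what it shows

The generator's defaults are the study conditions: 40 Latin-hypercube
draws over the calibration ranges (G_CaL [1.99e-5, 7.96e-5] cm ms⁻¹µF⁻¹,
G_Na [7.42, 29.68] nS/pF, G_Kr [0.08, 0.31] nS/pF, D_ani [0.008298,
0.033192] and D_iso [0.002766, 0.011064] mm²/ms, D_purk [1.0, 3.5]
mm²/ms, t_LVstim [0, 100] ms), one 600 ms beat each, 9 leads sampled
every 5 ms (121 points), and a virtual patient at interior parameters
with sd-0.1 Gaussian noise on the nondimensional 12-lead traces. Failed
simulations would be excluded and counted (none occur at these
settings). The ensemble brackets interior-parameter patients' traces,
mirroring the containment of the clinical recordings within the
simulated variability.

What passing tests show: the forward model's physics (conduction-velocity
monotonicity and √-diffusion anisotropy scaling, resting-state
preservation, transmural APD ordering), the exactness of the lead
algebra and architecture accounting, estimator correctness against
closed-form oracles, chain convergence, and exact recovery of the
sensitivity-ranked parameters from noise-free self-consistent targets.

What they do not show: fidelity to a real heart. The slab ECG is weakly
sensitive to the conductivities, the surrogate's error (~8e-3 MSE) is
comparable to the sd-0.1 noise, and consequently several parameters are
practically non-identifiable at desk scale: calibration centers for weak
components can drift beyond the 0.2 prior half-width, and the
all-component posterior-coverage experiment fails in roughly half the
replicates — an honest desk-scale limitation, consistent with the
general observation that sensitivity and practical identifiability go
together. Paper-scale anatomies, ensembles and training budgets are the
stated remedy, not adjustments to the estimator.

## Problem sizes

Chosen once for a single-CPU workflow: slab campaign beats ≈ 10 s each
(h = 0.5 mm, dt = 0.05 ms, 2,023 myocardial nodes); surrogate training
≈ 25 s (3,000 iterations, ~1,000 weights); 100-trial calibration
≈ 15–35 s; the 4-chain NUTS run ≈ 8–10 min on the 10 ms grid. Coverage
replicates use 2 chains × (150 + 150) draws. Conduction velocities are
measured on 20 mm bars: the D_ani-monotonicity trend at h = 0.5 mm, the
quantitative anisotropy ratio at h = 0.125 mm, where the transverse
upstroke is resolved and CV_∥/CV_⊥ converges to the continuum
√((D_ani+D_iso)/D_iso) within ~1% (at h = 0.5 the grid-limited
transverse front overshoots the ratio by ~2×).
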