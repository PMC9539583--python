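# Methods

## Signal model

The package treats a voxel's diffusion-weighted magnitude signal as the
two-compartment IVIM biexponential

S(b) = S0 · [(1 − f)·exp(−b·D) + f·exp(−b·D\*)],

with D the tissue diffusion coefficient, D\* the pseudo-diffusion
coefficient of the capillary compartment and f the fraction of signal in
that compartment. Assumptions inherited from the model: mono-exponential
decay within each compartment (no kurtosis term), no exchange between
compartments, and D\* > D for a physically meaningful voxel. The default
acquisition scheme is nine b-values (0, 25, 50, 75, 100, 150, 300, 800,
1000 s/mm²): dense low-b sampling resolves the fast compartment, the two
high-b points anchor D.

Parameter sampling ranges (uniform, per region): D ∈ [5·10⁻⁴, 2·10⁻³]
mm²/s, f ∈ [0.025, 0.4], D\* ∈ [5·10⁻³, 0.1] mm²/s — wide literature-based
ranges covering healthy and lesioned tissue. Parameters are kept in these
physical units everywhere outside the feature/standardization layer.

## Phantom simulator

Each phantom is a 64×64 single-slice image built from a Shepp–Logan-style
layout: one head ellipse whose interior is region 1, plus five disjoint
inner ellipses (regions 2–6). The exact ellipse coordinates are fixed
constants of the package (`phantom.SHEPP_LOGAN_ELLIPSES`); any six-region
elliptical layout serves the purpose of the phantom, which is to provide
heterogeneous parameter regions and easy visual inspection. Each region
receives one uniformly drawn (D, f, D\*) triplet and one b0 level drawn
uniformly from [0.5, 1.5] arbitrary units; the b0 spread exercises the
voxel-wise SNR scaling without affecting b0-normalized features.

Noise is Rician: each sample becomes √((S+g₁)² + g₂²) with g₁, g₂
independent zero-mean Gaussians. The Gaussian scale is σ = S0/SNR per
voxel — the conventional magnitude-MRI SNR definition — so every
foreground voxel of a phantom sees exactly the same SNR regardless of its
b0. An alternative reading of "noise scaled by 1/SNR" (σ² = S0/SNR) is
available behind the `variance_mode` flag of `add_rician_noise` but is not
the default, because only the σ-reading makes per-phantom SNR homogeneity
exact. Background voxels carry zero signal and pure Rician noise at the
median foreground scale; they are excluded from training and from every
metric.

Reproducibility: phantom RNG streams are derived from
(master_seed, snr_index, phantom_index) counter keys, so any subset of a
grid regenerates identically and in any order. Within each SNR level the
first half of the phantoms is the training split, the second half the
test split.

What the simulator does **not** emulate: motion/ghosting artifacts,
partial-volume mixing at region borders, spatially correlated noise,
multi-slice geometry, non-Rician (e.g. non-central chi) noise from
multi-coil reconstruction, and within-region parameter gradients. Tests
passing on these phantoms therefore demonstrate correctness of the
estimator under the stated noise model, not robustness to everything real
data can do.

## Features and targets

Per-voxel network inputs are the signals normalized to the measured b0
(Sb/Sb0, using the noisy b0 as one would in practice), optionally
augmented with ln(Sb/Sb0) — 9 → 18 features for the default scheme. The
log of the *normalized* signal is used rather than the log of raw
intensities so that the b0-invariance the normalization buys is not
reintroduced. Each feature is affinely mapped to [−1, 1] by per-feature
min/max recorded over the whole training set (not per voxel, which would
destroy amplitude information); values outside the training range are
deliberately not clipped. Normalized magnitudes can reach 0 in degenerate
voxels, so logs are floored at 10⁻⁶. The b0-ratio feature (and its log)
is constant by construction and is mapped to the interval midpoint 0; any
*other* constant feature is treated as a data error.

Targets are z-scored per parameter against training-set ground truth
(mean 0, std 1) and the inverse transform is applied to network outputs.
With standardization disabled (the ablation arm) both transforms are
identity maps. Outputs are not clipped to the physical ranges by default
— the failure-rate analysis must see raw estimator behaviour — and a clip
option exists for map rendering. All scaling constants are serialized
inside the model file; prediction refuses to run without them.

## Network and training

The regressor is a fully connected net: n_inputs → width^depth (tanh) → 3
(linear), default 18 inputs, 3 hidden layers, width 32. Width is not a
structural commitment of the method; 32 was chosen as the smallest width
whose validation MSE was not improved upon by doubling it. Weights are
initialized uniform ±1/√fan_in from the seeded generator; the train/
validation split (80/20) is random per seed at the voxel level.

Two optimizers share the stopping criteria (gradient floor 10⁻⁷,
iteration cap 5000, validation patience 6):

* **Damped Levenberg–Marquardt** (`optimizer="lm"`): full-Jacobian
  Gauss–Newton with damping μ starting at 10⁻³, ×0.1 on an accepted step,
  ×10 on a rejected one; only loss-decreasing steps are accepted, so the
  training loss is monotone. Exact but dense — the Jacobian costs
  n_samples × 3 × n_params memory — so it is the default for runs up to a
  few thousand voxels and is what the unit tests exercise.
* **First-order fallback** (`optimizer="adam"`): mini-batch Adam
  (batch 2048, step 10⁻³) for pooled training sets of 10⁵–10⁶ voxels,
  with a validation check per epoch mirroring LM's per-iteration check.
  The adaptive-rate semantics are applied to the global step size: when
  validation fails to improve for `validation_patience` consecutive
  epochs, the best weights are restored and the step size is multiplied
  by the decrease factor (0.1); after three such plateaus the patience
  stop fires. This keeps the plateau-driven decrease/stop behaviour of
  the second-order scheme at a scale where forming Jacobians is not
  feasible.

Training aborts loudly on NaN loss; the model file (a single JSON
document with a version field) records the architecture, all scaling
constants, weights, the stop reason and the loss curves.

## Least-squares baseline

The conventional fitter is segmented-then-full: D and the intercept 1−f
from log-linear regression on b ≥ 300 s/mm² (the natural split in the
default scheme, where b jumps 300 → 800), then f and D\* refined on all
b with D fixed, then bounded trust-region least squares on all three
parameters initialized from the segmented result — so the full fit's
residual never exceeds its initializer's. Box bounds default to the
sampling ranges expanded ×2 each way (f capped to [0, 1]) so estimates
near a range edge are not pinned. On noiseless signals the fitter
recovers generating triplets to better than 10⁻⁴ relative error except
where D\* ≈ D makes the model non-identifiable; this makes it the
inversion oracle for the simulator and the network alike.

## Metrics and comparison

Per (method, parameter, SNR) cell, pooling foreground voxels over all
phantoms: MdAE = median |est−true|/true, MdB = median (est−true)/true,
FR = fraction of voxels with |est−true|/true > 0.5 (reported as %, stored
as a fraction), and RCV = 1.4826·MAD/median of the *estimates* computed
per region per phantom, aggregated by the median across regions and
phantoms. Voxels with exactly zero ground truth are excluded with a
count (none occur on foreground by construction). The across-SNR summary
rows aggregate per-SNR values as median ± MAD (a mean option exists);
note MdAE ≥ |MdB| does not hold in general and is not asserted anywhere.

Methods are compared with a Kruskal–Wallis omnibus test followed by Tukey
HSD on the pooled ranks (the rank analogue of the usual post-hoc), at
α = 0.05. External fitters plug into the same evaluation by supplying
parameter maps; nothing in the report builder is specific to the in-repo
methods.

## Desk-scale study sizes

The full-scale campaign behind the method (2000 phantoms per SNR,
> 10⁷ training signals, second-order training) is a multi-day
computation. The package's standard study (`experiments.scaled_down_study`,
also what `scripts/acceptance.py` runs) keeps the protocol and scales the
counts: 100 training + 50 held-out phantoms per SNR level, training
voxels subsampled to 4·10⁵, first-order optimizer, epoch cap 300 (runs
terminate earlier via the patience criterion). This trains in ~2 minutes
and evaluates ~1.2·10⁶ held-out voxels.

Two consequences of the scaling are worth keeping in mind. First, the
training set contains ~4200 distinct region triplets instead of ~36000,
which leaves the worst-case (lowest-SNR) errors for f and D\* a few
percent above their full-scale counterparts. Second, 50 test phantoms per
SNR means only 300 distinct triplets per SNR level enter the median-based
metrics, so seed-to-seed variability of the reported quantities — the
worst-case median bias of f especially — is larger than the full-scale
figures suggest; the across-seed centre matches.

## Known limitations

Single-slice phantoms and Rician noise only; uniform parameter priors
(accurate but not precision-optimal training distributions); a trained
model is locked to its b-value scheme and SNR range (different schemes
require retraining); the Bayesian and other published learning-based
fitters are not re-implemented — they enter only through the map-level
plug-in evaluation interface.
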