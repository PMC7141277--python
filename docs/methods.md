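# Methods

## Scope and model

The pipeline has four stages: (1) simulate a multi-shell diffusion-MRI
cohort, (2) reconstruct per-voxel orientation distribution functions by
generalized q-sampling (GQI) and derive GFA/ISO/NQA scalar maps, (3)
compress each map with a 3D convolutional autoencoder and flatten the
bottleneck into a feature vector, (4) classify suicidal-ideation (SI)
subjects against non-ideation subjects (HC + NS) under an imbalance-aware,
iterated cross-validation protocol. Eddy/motion correction and template
registration are out of scope: synthetic volumes are generated already
aligned on a shared grid. Tractography, multi-peak fiber enumeration and
classifiers beyond gradient-boosted trees and logistic regression are also
out of scope.

## Synthetic cohort generator

Each voxel follows a two-pool multi-tensor model:
`S(ĝ, b) = S₀ [ f · exp(−b ĝᵀDĝ) + (1 − f) · exp(−b d_iso) ]`, with one
axially symmetric fiber tensor (axial diffusivity λ∥ = 1.7×10⁻³, radial
λ⊥ = 0.3×10⁻³ mm²/s — typical white-matter literature values) and free
water at d_iso = 3.0×10⁻³ mm²/s. Noise is Rician,
`|S + n₁ + i n₂|, n ~ N(0, σ)`, default σ = 2 at S₀ = 100 (SNR 50 on the
b = 0 image — a clean acquisition); the Rician model is exact at σ = 0,
and a zero-clipped Gaussian option exists for debugging.

Cohort structure, all configurable through `CohortSpec`:

- **Groups** 58 HC / 54 NS / 41 SI / 33 SA, the reference composition.
- **Gradient table** one b = 0 row plus three shells (1000/1500/2000
  s/mm²) of 64 directions each — 192 weighted directions total, split
  evenly because no per-shell allocation is specified anywhere.
  Directions use a deterministic spherical-Fibonacci spiral per shell
  (phase-shifted between shells); the seed only permutes acquisition
  order, so layouts are reproducible without an electrostatic optimizer.
- **Anatomy** an ellipsoidal "brain" inscribed in the grid with a uniform
  fiber population aligned near +z; outside the mask the signal is exactly
  zero (this drives the default reconstruction mask). Per subject, the
  fiber axis is jittered (~5° s.d.) and the anisotropic volume fraction f
  (baseline 0.65) is jittered with s.d. 0.03 — a crude stand-in for
  biological variability that makes the null task genuinely uninformative
  rather than degenerate.
- **Effect injection** SI (and by default SA) subjects have f reduced by
  `effect_delta` (default 0.4) inside a central cube covering one third of
  each axis. Ground truth (per-subject axis, f, in-ROI mean f) is attached
  to every generated subject.

What the generator does **not** emulate: spatially varying fiber
orientation fields, crossing-fiber anatomy at cohort scale, partial-volume
cortex/CSF gradients, eddy/motion/susceptibility artifacts, scanner drift,
and demographic covariates (age/sex/education). Passing tests therefore
demonstrate the pipeline's mechanics and sensitivity under a known,
localized microstructural effect — not clinical performance on real data.

## GQI reconstruction

`ψ(û) = Σᵢ Sᵢ sinc(σ √(6 D bᵢ) (ĝᵢ·û))` with unnormalized sinc. Constants
σ = 1.25 and D = 2.5×10⁻³ mm²/s are the conventional choices for this
reconstruction and are exposed in `GQIConfig`; the ODF direction set is
the antipodally deduplicated hemisphere of a k-times subdivided
icosahedron ((10·4ᵏ + 2)/2 directions), default k = 3 (321 directions,
nearest-neighbor spacing ≈ 9.1°). Negative ψ values are truncated to zero
before any index is computed (the SDF is a density). Indices:

- GFA uses the population standard deviation (divide by N), so the
  one-hot bound is √((N−1)/N) → 1 as N grows, matching the FA analogue;
  an all-zero ODF maps to GFA 0 by convention.
- QA takes the per-voxel **global** maximum over the direction set; no
  local-peak search is needed because only the dominant orientation feeds
  the scalar indices.
- NQA normalizes QA by the maximum over that subject's masked field, so
  NQA ∈ [0, 1] per subject.
- The default brain mask keeps voxels with positive mean b = 0 signal;
  all maps are zero outside it.

## Autoencoder

Encoder: 3 × [3³ same-padded convolution (ReLU) → 2×2×2 max-pool] with
channels (32, 16, 16); decoder: 3 × [2× nearest-neighbor upsample →
convolution] with channels (16, 16, 1), sigmoid output. Only the
bottleneck channel count (16) is fixed by the architecture contract; the
(32, 16, 16)/(16, 16, 1) taper and kernel size 3 are this package's
choices of a conventional taper ending at 16. Hidden ReLU + sigmoid output
are forced by the binary cross-entropy loss on [0, 1] intensities, which
in turn motivates per-volume min-max normalization (a constant volume maps
to zeros). Pruning (91, 109, 91) → (88, 104, 88) removes (1, 2)/(2, 3)/
(1, 2) voxels from the (low, high) sides of x/y/z; only the before/after
shapes are contractual, the low-side-light asymmetry is a convention.

Training: Adadelta (ρ = 0.95, ε = 1e−6) with learning-rate multiplier
0.01, BCE loss, one parameter update per volume, 50 epochs by default,
float32 throughout; weights initialized He-style from the config seed.
The autoencoder trains unsupervised on **all** subjects' maps (186 at
reference scale, including the 33 SA subjects that classification later
excludes), one autoencoder per index type. Bottleneck flattening is
Fortran-ordered over (x, y, z, channel) — x varies fastest.

A practical note on the recipe: with zero-valued inputs every activation
is zero, so only bias chains receive gradient and the loss decreases very
slowly; on structured inputs the loss falls steeply (e.g. 0.68 → 0.22
over 50 epochs at 8³). The recipe is kept as stated rather than tuned.

## Classification protocol

Labels: SI = 1; HC and NS = 0; SA excluded. The 112 non-ideation subjects
are split into two group-stratified halves (odd group counts send the
surplus subject to half 1); each half + all 41 SI subjects forms a task of
97 subjects. Per task and random state: stratified 4:1 train/test split,
then stratified 5-fold CV on the training 4/5 — the rotating CV fold
realizes the validation set, giving the 4:1:1 proportion without a third
fixed partition. Ten random states (0–9) are used; the half assignment is
fixed across iterations (drawn once from the global seed). CV metrics
average over folds first, then over iterations. Decision threshold for
ACC/SEN/SPE is 0.5 on predicted probability; AUC is threshold-free
(sklearn's trapezoidal ROC, equal to pairwise concordance counting with
half credit for ties). Best-iteration selection maximizes test AUC, ties
broken by the lowest random state.

Classifiers: `xgboost.XGBClassifier(max_depth=5, n_estimators=1000)` with
remaining settings at library defaults (plus optional `scale_pos_weight`,
conventionally the 2.73 negative:positive ratio), and
`sklearn.linear_model.LogisticRegression` entirely at defaults.

## Determinism and numerics

All randomness flows from one global seed through `SeedSequence` children
(cohort, autoencoder, half-split); XGBoost runs single-threaded with a
fixed `random_state`, and the autoencoder is pure NumPy — two runs of the
same configuration produce byte-identical metric CSVs, and the
classification stage rerun from saved feature CSVs reproduces them
exactly. Degenerate inputs are defined, not errors: all-zero ODF → GFA 0,
constant ODF field → QA = NQA ≡ 0, constant volume → normalized zeros.

## Problem sizes used in tests and the acceptance script

Full template-grid runs are supported but unnecessary for verification;
the packaged experiments use desk-scale geometry as a deliberate design
choice:

- Unit tests: 8³–24³ grids, tessellation orders 0–2, few-subject cohorts.
- Signal-recovery experiment (tests and `scripts/acceptance.py`): 16³
  grid, the full 58/54/41/33 cohort with the default 3×64-direction
  table, order-2 tessellation (81 directions), 12 autoencoder epochs,
  GFA × half 1 × gradient-boosted trees × 10 iterations. With
  `effect_delta = 0.4` the mean test AUC exceeds 0.85 by a wide margin;
  with `effect_delta = 0` it stays within the chance band [0.35, 0.65].
  Shrinking the grid and epochs relative to the reference geometry leaves
  the protocol arithmetic untouched and only reduces the spatial
  resolution of the features.

## Known limitations

- The synthetic effect is a block reduction of fiber fraction in a known
  ROI — far easier than diffuse clinical effects, so recovery AUCs here
  say nothing quantitative about real-cohort accuracy.
- One fiber population per voxel in the generator; crossing fibers are
  exercised only in targeted reconstruction tests.
- The NumPy autoencoder is CPU-bound and trains at one volume per update;
  it is meant for reproducibility and desk-scale grids, not for
  large-scale training throughput.
- Logistic regression at library defaults may stop at its iteration cap
  on 25k-dimensional features; this mirrors the reference protocol and is
  deliberately not tuned.
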