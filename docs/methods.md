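# Methods

This note documents the models, conventions and numerical choices behind
`desire-rt`: a self-contained implementation of progressive dual-UNet dose
prediction for VMAT head-and-neck planning, together with the synthetic
phantoms and the dosimetric evaluation suite used to exercise it.

## The prediction task

Given a CT volume, binary masks for three nested planning target volumes
(PTV70 ⊆ PTV60 ⊆ PTV55, prescribed 70/60/55 Gy) and organ-at-risk (OAR)
masks, predict the 3-D dose distribution a clinically acceptable VMAT plan
would deliver. Doses are regressed in normalized units (divided by the 70 Gy
reference prescription); predictions are **not** clipped to [0, 1] because
real plans contain supra-prescription hot spots (D2 of a 70 Gy target
typically sits near 75 Gy).

### Input encoding

Five channels: normalized CT; the three PTV masks scaled by
prescription/70 Gy (1.0, 0.857, 0.786) — an ordinal encoding of the dose
target; and the union of all OAR masks. Merging the OARs keeps the channel
count fixed across cases with different OAR inventories; per-OAR channels
are available via `PreprocessConfig(per_oar_channels=True)`. CT is clipped
to (−1024, 2048) HU and mapped linearly onto [0, 1].

## Architecture

Two progressive 3-D UNets (all convolutions followed by instance
normalization + ReLU, except the final head):

* **UNet-1** (4 levels, widths b/2b/4b/8b, default b = 16): plain two-conv
  encoder blocks, stride-2 convolutions for downsampling, trilinear
  upsampling, residual fusion blocks in the decoder.
* **UNet-2** (5 levels, widths 2b/…/32b — twice UNet-1's width at every
  shared level): the encoder uses residual-dense (RD) blocks — a stride-2
  downsampling convolution feeding (i) an upper branch of three densely
  concatenating 3³ stages of `rd_growth` channels each, projected back by a
  1×1×1 convolution ("global" features) and (ii) a 1×1×1 lower branch
  ("local" features), summed and fused by a final 1×1×1 convolution. At each
  shared resolution the corresponding UNet-1 decoder feature is concatenated
  into the UNet-2 stream (encoder side) and a squeeze-excitation channel
  attention computed **from** the UNet-1 decoder features (global average
  pool → bias-free bottleneck 1×1×1, reduction 4 → ReLU → bias-free
  expansion 1×1×1 → sigmoid) gates the matching UNet-2 decoder channels.
  Bias-free attention makes `sigmoid(0) = 0.5` exact for all-zero features,
  a property the tests rely on.
* **Head**: a single linear 1×1×1 convolution (bias, no norm, no
  activation) shared between the main output and the dropout branch.

Where the block diagrams admit more than one wiring (attention formula,
fusion order), the implementation keeps each choice behind a narrow class so
alternates can be swapped; the choices above are the conventional readings.

### Dropout outputs for difficult-region learning

In training mode the shared penultimate feature map is perturbed by four
channel-dropout layers with distinct rates (0.1, 0.2, 0.3, 0.4, strictly
increasing, configurable) and pushed through the shared head — four diverse
predictions d1..d4 from a single forward pass. Rates are fixed, not
scheduled.

## Losses

With ŷ the prediction, y the normalized ground truth, and VarD/MeanD the
voxelwise variance/mean of d1..d4:

* `f1 = VarD / (α + VarD)`, `f2 = |MeanD − y| / (β + |MeanD − y|)` — both in
  [0, 1); α = 0.5, β = 0.05.
* Difficult-region loss `L_DR = mean((f1 + f2)·(y − ŷ)²)` over the voxels of
  the batch. **f1/f2 are detached**: gradients flow only through (y − ŷ)²,
  so the optimizer cannot shrink the loss by saturating the weight maps.
  The mean is per voxel, matching the per-voxel MAE convention.
* Auxiliary segmentation loss: the GT dose is thresholded at each
  prescription level (≥ 1.0, 60/70, 55/70 in normalized units); empty
  regions are dropped (k = number retained, `L_seg = 0` when k = 0). The
  predicted occupancy is a temperature-softened logistic
  `σ((ŷ − level)/τ)` with τ = 1 Gy/70 (no dedicated segmentation head; one
  is stubbed behind a config flag). Each region contributes
  `0.5·BCE + 0.5·Dice` (Dice smoothing ε = 1e-5, BCE probability clamp
  1e-7); `L_seg` is the mean over the k regions.
* Final objective `L_final = L_MAE + L_DR + γ·L_seg` with γ = 0.1. The MSE
  is computed as a logged diagnostic only — it enters no objective.

All loss code accepts plain numpy arrays (pure evaluation) or autodiff
tensors (training); the test suite pins both against naive per-voxel loop
transcriptions to 1e-6 relative and against central finite differences.

## Training

Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8), batch size 1, initial learning rate
3e-4, cosine annealing with warm restarts. The cycle structure is
T0 = 25 epochs, Tmult = 2, eta_min = 1e-6 (25 + 50 + 75 spans a 150-epoch
run); the learning rate at any fractional epoch follows the closed form
`eta_min + (lr0 − eta_min)(1 + cos(π t/T_i))/2` and the recorded trace is
asserted against it exactly. Weights are Kaiming-initialized
(normal, std = √(2/fan_in)) from the config seed; one run seed drives case
shuffling and dropout, so a simulate→train→predict run is bit-reproducible
on one machine. No validation split or early stopping: fixed epochs with
best-running-training-loss checkpointing. A seeded `train_test_split`
utility exists but no particular split is prescribed.

### Numerical engine

The network runs on a purpose-built tape-based reverse-mode autodiff engine
over numpy (float32 parameters by default; losses on numpy inputs evaluate
in float64). 3-D convolution is evaluated as one GEMM per kernel offset
(k³ products of (Cout, Cin)×(Cin, N)), which keeps peak memory flat and
maps onto single-threaded BLAS. Every backward rule is verified against
finite differences in the test suite.

## Synthetic phantoms

The generator emulates the statistical structure the method assumes, not
anatomy:

* **Geometry**: body = elliptical cylinder (cross-section 88% of the
  axial extent); PTVs = concentric ellipsoids sharing a randomized centre
  (jitter ±4 mm) with PTV70 semi-axes drawn from 10–14 mm and fixed 6 mm /
  12 mm margins to PTV60 / PTV55, so nesting holds by construction; OARs =
  ellipsoids (5–9 mm semi-axes) rejection-sampled outside PTV55 with a
  2-voxel clearance. Infeasible geometry (targets cannot fit the grid with
  clearance) raises an explicit error.
* **Dose**: `dose(v) = max_L A_L · σ((m − d_L(v))/w)` where `d_L` is the
  Euclidean distance (mm) to target L, σ the logistic, w = 5 mm the falloff
  width and m = 20 mm a plateau margin. The amplitude `A_L = 1.04·P_L`
  places the in-target plateau at ≈ 1.02·P_L, so D95 ≥ prescription holds
  with realistic (< 3%) headroom while the in-target dose never approaches
  107% of the 70 Gy prescription; additive Gaussian noise (default
  sd 0.5 Gy) emulates plan texture; dose is zeroed beyond 15 mm outside the
  body and capped at 78 Gy (< 1.15 × 70 Gy). With amplitude exactly P_L a
  logistic plateau could never reach the prescription, which is why the 4%
  headroom factor exists.
* **CT**: body 40 ± 10 HU, +30 HU inside the targets, −20 HU (minus 2 HU
  per index) in OARs, −1000 HU air — arbitrary but learnable contrast.

What the phantoms do **not** emulate: heterogeneous tissue densities, beam
geometry or deliverability physics (no Monte-Carlo/pencil-beam transport),
inter-patient anatomical variability, or OAR-sparing trade-offs. Passing
tests therefore demonstrate that the architecture, losses, trainer and
metrics are implemented correctly and can fit dose distributions with the
assumed smoothness — not that the model reaches clinical accuracy on real
patients.

Default grids: 48×64×64 voxels at 3×2.5×2.5 mm for simulation, 32×48×48 for
the training demonstrations (the clinical configuration, 96×128×128, is
available by config but is not a desk-scale workload).

## Dosimetric evaluation

* **Dx**: minimum dose to the hottest x% = the (100−x)th percentile of the
  structure's voxel doses with linear interpolation (standard ICRU
  reading); `Vx` = % of structure volume ≥ x Gy; `Dmax` is reported as the
  maximum voxel dose (configurable to D1 semantics); `Dmean` the mean.
* **CI** = (Vref/Vptv)·(Vref/Vpres) on voxel counts; Vref = PTV ∩
  {dose ≥ prescription}, Vpres = body ∩ {dose ≥ prescription}; CI = 0 with a
  logged notice when the isodose region is empty. **HI** = (D2 − D98)/D50.
* **Gamma** (global 3-D): reference = ground truth, evaluated = prediction.
  Voxels with GT < 10% of the 70 Gy reference are excluded. For each
  evaluated voxel the minimum over a displacement lattice (step = DTA/3,
  ball radius = 3·DTA, trilinear interpolation of the predicted dose) of
  `sqrt((|Δ|/DTA)² + (ΔD/(3% × 70 Gy))²)`; pass if ≤ 1. Offsets are visited
  in order of increasing |Δ| and a voxel leaves the search once its distance
  term alone exceeds its running minimum — a pruning that provably cannot
  change the minimum, and the tests assert exact agreement with an
  exhaustive full-lattice oracle. A single 70 Gy global normalization is
  used for all structures (configurable). The L35 report region is the GT
  ≥ 35 Gy isodose.
* **Mann–Whitney U** (two-sided, midrank ties): exact enumeration of all
  C(n1+n2, n1) labelings when both samples have ≤ 8 values, otherwise the
  tie- and continuity-corrected normal approximation; p = 1 when all pooled
  values are identical. A plain normal approximation is 0.02–0.13 off the
  exact tail at n ≤ 3, which is why the exact path exists at small n.

## Problem sizes and tolerances in the tests

Loss-oracle checks use ≤ 8³ grids at 1e-6 relative; gamma-oracle checks use
≤ 12³ grids at 2.5 mm spacing with exact pass-set equality; Dx checks use
1e-9 absolute; the end-to-end demonstration trains the base-8 model for 200
steps on one 32×48×48 phantom and requires body MAE < 2 Gy and a 3%/3 mm
gamma pass rate > 95% against the phantom's ground truth. The acceptance
script (`scripts/acceptance.py`) runs the same workflow and reports its
measured quantities, predicting from the best-training-loss checkpoint.

## Known limitations

* At desk-scale step counts (a few hundred, versus tens of thousands in a
  clinical training regime), each warm restart re-energizes the optimizer
  and can transiently overshoot the dose in the smallest high-dose region
  (PTV70 is ~0.5% of the voxels); the final weights may therefore be worse
  there than the best-loss checkpoint, which samples the settled end of an
  annealing cycle. This is why prediction workflows default to the best
  checkpoint rather than the final weights.
* Batch size > 1 is implemented as gradient accumulation over cases within
  a step (the published recipe uses batch 1 throughout).
* The attention/fusion wiring follows the conventional reading of the block
  diagrams; alternates would need only local changes but are not provided.
* CPU-only: the engine is single-threaded BLAS; the full 96×128×128,
  150-epoch clinical regime is out of desk scope by design.
* DICOM-RT import/export is out of scope; volumes are exchanged as NIfTI
  plus a JSON manifest.
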