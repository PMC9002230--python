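# Methods

This note records the modelling and numerical choices behind the package, in
particular those the architecture description leaves open.

## Model

A feature map is a real tensor `x ∈ R^(N,C,H,W)` (batch, channel, row,
column; row-major, 0-based, masks and images share the convention
everywhere). The TGMLP block combines three paths:

**Triple MLP (TM).** Three single-full-connection mixing steps applied in
channel → height → width order. Each step is
`y = g · FC_axis(LN(x)) + x`, where:

* `LN` normalises over the channel axis at every spatial site (the
  convolutional-network convention; the formula names no axis, and per-site
  statistics are consistent with the 1×1 convolutions downstream),
  `eps = 1e-5`;
* `FC_axis` is one square full connection with bias along one axis (weight
  side = that axis's extent), applied independently at every position of the
  other axes; there is no hidden layer or nonlinearity inside a step;
* `g` is a learnable scalar gate, one gate triple `(g_c, g_h, g_w)` per
  block, initialised to 1.0 so the model starts as the ungated variant and
  training can shrink a gate towards 0 if positional structure is not
  learnable from the data. Gates are unconstrained reals.

**Global perceptron (GP).** `partition(x, h)` re-lays the map as
`(N, W/h, H/h, C, h, h)`: axes 1–2 hold within-partition coordinates, the
trailing two axes the h×h grid of partitions. The tensor is averaged over the
grid axes, passed through BatchNorm and a two-layer MLP
(`length → length → length` with a ReLU between; `length = (W/h)(H/h)C`; the
hidden width equals the output width, the minimal reading of the two-layer
spec, and is symmetric so the parameter count stays predictable), reshaped to
`(N, W/h, H/h, C, 1, 1)`, broadcast onto every partition, un-partitioned and
added to the block input. The broadcast makes the learned offset *shared* by
all partitions — a sparse full connection with tied weights. The `h` in the
re-layout is read as partitions **per side** (the trailing `(h, h)` axes
force this reading). The add of the block input `x` follows the published
formula for the partition path; which tensor the `+x` refers to is ambiguous
there, and we use the block input.

**Local priors (LP).** Four parallel convolutions with kernels 1/3/5/7 and
paddings 0/1/2/3 (resolution preserving), each followed by BatchNorm, applied
to the GP output; their sum plus the TM output is the block output. The
channel-last layout that appears in the published partition formulas is
treated as notation: all public tensors are `(N,C,H,W)` and any re-layout is
internal, which removes a whole class of H/W transposition bugs.

With all gates at zero and the GP second layer, LP kernels and biases zeroed
the block is exactly the identity (the tests assert bit equality) — the safe
starting point the gating narrative relies on.

## Network

Stem: three 3×3 conv + BN + ReLU layers at full resolution. Encoders:
`conv3×3(stride) + BN + ReLU → TGMLP block → 1×1 conv → + residual` (residual
taken at the block input). Decoders: `conv3×3 + BN + ReLU → 2×2 stride-2
transposed conv → + skip`. The global branch has 2 encoders/2 decoders, the
local branch 5/5 applied to a 4×4 grid of patches with shared weights
(implemented by folding patches into the batch axis; in training mode the
batch-norm statistics therefore pool over patches, in evaluation mode patches
are processed fully independently). Branch outputs are added and a 1×1
convolution yields per-pixel scores for 2 classes; the foreground probability
is the class-1 softmax.

Open choices fixed by this package:

* **Channel widths** are not dictated anywhere; the reference configuration
  (stem 24; global 32, 80; local 24, 48, 64, 64, 64) was fixed **once**
  against the published compute budget of the model — 3.03 M parameters and
  1.9 G MACs at 128×128 — which is the only width evidence available. The
  accountant reproduces 3,033,999 parameters and 1.894 G MACs.
* **Local pyramid schedule**: stride-2 in the first four local encoders and
  stride 1 in the fifth (patch extent 32 → 2 at 128×128 input). Five
  halvings would leave nothing to halve at the 64×64 desk-scale input this
  package trains at; the chosen schedule lets one default topology run at
  both sizes.
* **Partition counts** are set per stage so partitions are 2×2 at the
  128×128 operating point (clamped to the extent at smaller inputs). Larger
  partitions make the GP's `length²` MLP the dominant parameter cost.
* **TGMLP placement**: every encoder of both branches carries one block;
  decoders carry none.
* **Ablation switches** (`use_tm`, `use_lgp`, `use_gate`) per stage give the
  backbone / +TM / +TM+LGP / +TM+LGP+GM lattice; disabling the gates freezes
  them at 1.0 (non-learnable) rather than removing the TM path.

Axis-MLP weight sides and GP lengths depend on the stage extents, so a model
is built for a stated `input_size`; the parameter count is quoted at the
128×128 reference point.

## MAC accounting

One MAC per scalar multiply inside convolutions (`k²·c_in·c_out·H_out·W_out`),
transposed convolutions (`k²·c_in·c_out·H_in·W_in`) and full connections.
Biases, normalisation, activations, pooling and residual adds are excluded —
a convention that must be fixed for the count to be well-defined; figures in
G use 1 MAC = 1 FLOP, the convention of the published comparison table. The
closed forms for the mixing blocks are `HWC²` (channel), `CWH²` (high),
`CHW²` (wide) and `2·C·hidden·HW` for the two-FC spatial mixer (hidden
defaults to `HW`). Note the per-axis total `HWC(C+H+W)` is linear in each
extent but not literally `O(HWC)`; the substantive separation — quartic
versus cubic growth in the side length, a ratio that grows linearly — is what
the accountants and tests assert.

## Losses and metrics

Probabilities are clipped to `[1e-7, 1-1e-7]` before logarithms. The
cross-entropy is the standard per-pixel binary form averaged over the image.
The published focal-loss formula modulates by the *label* (which degenerates
to a hard mask for binary labels) and carries a stray log base; we implement
the standard prediction-modulated binary focal loss with natural logarithms,
`α = 0.25`, `γ = 2` by default. The Dice loss is `1 − (2Σpp̂+s)/(Σp+Σp̂+s)`
with smoothing `s = 1`, so empty-on-empty scores zero.

Rates come from exact pixel confusion counts; an overlap rate with a zero
denominator is 1 when both masks agree on emptiness and 0 otherwise.
Predictions are thresholded at 0.5 foreground probability. The Hausdorff
distance is the full (not 95th-percentile) symmetric boundary-to-boundary
maximum with Euclidean pixel distances, normalised to percent of the image
diagonal — the "%" reporting of HD is otherwise undefined; both choices are
configurable at the call site. One mask empty → 100, both empty → 0.

## Training

Adam (β = 0.9/0.999, no weight decay — unstated in the protocol, standard
defaults), batch size 10, 400 epochs, lr 1e-3 → 1e-5 with cosine annealing
after a 100-epoch warmup; warmup shape is linear from `lr_min` (only its
length is specified). The cosine uses `T = epochs − 1 − warmup`, so the final
epoch lands exactly on `lr_min`. BatchNorm uses `eps = 1e-6`,
momentum 0.1. No data augmentation. The train/validation split is 80/20 by
seeded permutation of manifest order; the checkpoint keeps the
best-validation-Dice weights. Training is deterministic for a fixed seed on
one platform. Train Dice is aggregated from the training-pass forward
outputs (batch-statistics BN), which avoids a second forward per epoch.

Desk-scale runs (the tests and the acceptance script) use 8 synthetic lesion
samples at 64×64, 200 epochs with a 50-epoch warmup — the same warmup
fraction as the full recipe — no held-out split, and stop once training Dice
reaches 0.95; the reference model typically crosses it within ~25–35 epochs
(one to two minutes on one CPU core).

## Synthetic data

The generator is a pure function of `(spec.seed, index)`. Objects are random
ellipses: lesion unions 3–8 overlapping mid-sized ellipses (radii 6–16 % of
the image side); polyp draws one large ellipse (22–34 %) with a low-order
sinusoidal radial perturbation of the boundary; nuclei places 8–20 small
ellipses (2–4.5 %) kept disjoint with a ≥2 px gap (checked by dilation), so
the connected-component count equals the object count exactly. The image is
`bg + (fg−bg)·mask` (0.25/0.75 by default) blurred with σ = 1 px plus
Gaussian noise σ = 0.05, clipped to [0,1] — both an intensity and a boundary
cue, with realistic ambiguity at edges. The stored mask is the exact
pre-corruption object union. Placement retries keep the foreground fraction
in (0, 0.6).

What the generator does **not** emulate: CT/endoscopy physics, texture,
anatomy-correlated backgrounds, multi-class labels, annotation noise or
inter-rater variability. Passing the desk-scale trainability check shows the
architecture, losses and optimiser are wired correctly and can fit
segmentation structure; it says nothing about accuracy on real clinical
data, which is out of scope here.

## Numerical choices and limitations

The package runs on an in-package reverse-mode autodiff engine over numpy
(float32 by default; metrics and losses on plain arrays use float64).
Convolutions unroll the kernel window into slice/tensordot pairs rather than
materialising im2col buffers. Oracle-equivalence tests compare against
float64 loop/scipy references at 1e-5-scale tolerances; identity properties
(gate-zero, zero-init collapse, partition bijection) are exact. Known
limitations: single CPU only, no mixed precision, resolution fixed at build
time, no inference-time re-parameterisation of the LP branches, and the 2×2
transposed convolution is the only upsampler.
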