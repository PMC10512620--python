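# Methods

## Problem and model

The package classifies H&E-stained breast-tissue tiles into the four HER2
immunohistochemistry scores (0, 1+, 2+, 3+). The classifier is a
convolutional network derived from InceptionV3, with three structural
changes: a parallel two-line topology operating on two spatial scales,
reduction blocks augmented with a global gating line, and an Eca-CBAM
attention block before every reduction.

**Topology.** A shared stem (five convolutions, two max-poolings, the
classic InceptionV3 schedule: 299 px → 35 px) feeds two unshared lines.
Line P1 runs at stem resolution through
InceptionA×3 → Eca-CBAM → InceptionB → InceptionC×4 → Eca-CBAM →
InceptionD → InceptionE×2; line P2 first halves resolution through the
DownsampleBlock and then runs the same (independently parameterised)
sequence. Each line ends in global average pooling; the pooled
descriptors are concatenated and pass through dropout and a single fully
connected layer to four logits. The wiring lives in one constructor
(`HAHNet.__init__`) so alternative topologies are a one-function change.
The per-block channel counts and kernel sizes follow InceptionV3's
published configuration, scaled by `width_multiplier`; the A/C/E
repetition counts (3/4/2) are configurable.

**Gated reductions.** In InceptionB/D the three standard lines (two
convolutional stride-2 paths and a 3×3/2 max-pool path) are concatenated;
a fourth line computes GAP(x) → 1×1 conv (bias) → sigmoid, a per-channel
gate in (0,1) that multiplies the concatenation (broadcast over space),
followed by SiLU. The gate is spatially uniform by construction — it
follows a global pooling — so it re-weights channels using global
context rather than modulating positions. The DownsampleBlock applies
the same gating to the concatenation of an avg-pool(2×2)/1×1-conv line
and a 3×3/2 conv line, each batch-normalised; an additive fusion mode is
available behind `downsample_fusion="add"` (then both lines produce the
full output width).

**Attention.** Channel attention is ECA: ω = σ(C1D_k(y)) where y is the
per-channel global-average descriptor and C1D_k a bias-free k-tap 1-D
convolution across channels with zero same-padding. k follows the
adaptive rule k = odd(|log2(C)/γ + b/γ|) with γ=2, b=1 (truncate, then
round up to odd), overridable by a fixed k. Spatial attention is CBAM's:
the channel-mean and channel-max planes are stacked and convolved with a
single bias-free 7×7 filter (padding 3), then squashed by a sigmoid.
The composite applies channel attention first (CBAM's sequential order;
the order is a config switch since the composition order is a genuinely
open design choice). Both stages multiply, never add: attention weights
in (0,1) re-scale the feature map, so |output| ≤ |input| elementwise and
shapes are preserved. Non-finite inputs are rejected with an error —
silent NaN propagation through sigmoids would otherwise mask upstream
bugs.

## Resolution and normalisation conventions

* Stride-2 convolutions and poolings inside reduction blocks pad so the
  output is exactly ⌈H/2⌉×⌈W/2⌉ (3×3 kernels use symmetric padding 1;
  the 2×2 average pool pads bottom/right by one only for odd sizes).
  The stem keeps InceptionV3's valid-padding schedule because the
  35×35 stem output at 299 px input is part of the architecture's
  definition; minimum input size is therefore 75 px.
* Convolutions followed by batch normalisation are bias-free (standard
  practice). Batch norm uses eps 1e-5, momentum 0.1, affine parameters,
  biased batch variance for both normalisation and the running-statistic
  update; eval mode uses running statistics and is deterministic.
* Average pooling uses a constant divisor (padding counted), so the
  zero-gate closed forms in the tests are exact.
* Max pooling pads with −inf; padding can never win the max.

## Training

Adam with learning rate 5e-4 and weight decay 1e-5 (classic L2 folded
into the gradient — weight decay acts as a coefficient on the
regularisation term; a decoupled AdamW-style variant is a flag), batch
size 64, cross-entropy on the logits, 250 epochs by default. Dropout
(default rate 0.5) precedes the fully connected layer. After each epoch
the model is evaluated in eval mode and the checkpoint with the highest
eval accuracy is retained (earliest epoch on ties); macro precision can
be selected as the retention metric instead. No learning-rate schedule
and no augmentation by default. A non-finite loss aborts with a
diagnostic. Weight init is He-normal per layer, drawn from a generator
seeded by `ModelConfig.seed`, so a config fully determines the parameter
vector and two same-seed runs produce bitwise-identical weights.

Checkpoints are single `.npz` containers: every parameter and buffer
plus a JSON header (format version, config echo, history, best epoch),
so any run is reproducible from its own artifacts.

## Synthetic data

The generator emulates only the statistical structure needed for
training and testing the pipeline offline: four separable texture
classes at tile scale. Each tile is a background colour interpolated
between an eosin-like pink and a hematoxylin-like purple (hematoxylin
fraction 0.15/0.35/0.60/0.85 for classes 0…3+), overlaid with dark
nucleus-like disks whose expected count per tile is 5/15/30/60
(Poisson), radius ≈3.5 % of the tile side, plus Gaussian pixel noise
(σ=0.02). Both the mean colour and the dark-pixel fraction are monotone
in the class index, mimicking how increasing HER2 expression correlates
with cellularity changes in real H&E tiles — a logistic probe on those
two summary features already separates the classes, which is what makes
the end-to-end training tests meaningful.

The generator deliberately does **not** model nuclear morphology, stain
variability between labs, tissue architecture, or the genuinely hard
ambiguity of real HER2 scoring (especially 2+). Passing tests therefore
demonstrate that the architecture, gradients, training loop and metrics
are correct and that the network can fit a learnable four-class image
task — not that it reaches any particular accuracy on real
histopathology.

## Problem sizes used by the test and acceptance runs

Reduced-width configurations are first-class: the acceptance run trains
the full variant at width multiplier 0.25 and 96 px input (≈2.9 M
parameters) on 200 synthetic tiles with a 40-tile held-out split,
stopping early once training accuracy reaches the target; construction
and forward/backward checks of all four ablation variants run at width
0.25 and 299 px. These sizes exercise every code path of the full-width
model — channel counts scale uniformly and the topology is identical.

## Numerical and design notes

* Attention/block oracle tests compare against explicit-loop
  reimplementations at 1e-5/1e-6; AUC matches a brute-force
  concordant-pair count to 1e-12.
* Multi-class aggregation is macro by default (per-class values are
  reported separately, so the unweighted mean is the natural summary);
  `average="weighted"` is available. The multi-class MCC is the
  covariance-form generalisation from the K×K confusion matrix, which
  reduces exactly to the binary formula at K=2.
* Zero denominators (e.g. precision with no predicted positives, MCC
  with an empty marginal) uniformly return 0 with a `UserWarning`.
* AUC ties receive half credit (average ranks); ROC curves are built
  from observed score thresholds only, areas by trapezoid.
* Tiles are resized bilinearly (the resize method is a free choice),
  scaled to [0,1]; optional per-channel standardization with
  ImageNet-style statistics applies last and is off by default.
* Labels serialize as the strings "0", "1+", "2+", "3+" and map to
  integers 0–3 internally; manifests are CSV (id, filepath, label[,
  split]) and a predefined split column is honoured.

## Known limitations

* No GPU path; full-width training at 299 px is out of CPU reach. The
  package targets correctness and CPU-scale experiments, not benchmark
  throughput.
* BatchNorm running statistics make eval outputs depend on training
  history; two differently-shuffled runs converge to different (equally
  valid) parameters unless seeds match.
* The synthetic classes are far easier than real HER2 scoring; reported
  synthetic-task metrics say nothing quantitative about clinical data.
* The exact wiring of the original parallel topology and the
  DownsampleBlock line widths are under-determined; the choices above
  (late fusion of pooled descriptors, equal line widths summing to the
  input channel count) satisfy the structural constraints and are
  isolated so alternatives are cheap to try.
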