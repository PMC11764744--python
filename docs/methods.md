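# Methods

This note records the model as implemented, the conventions behind the
complexity figures, what the synthetic phantoms do and do not emulate, and
the numerical choices made where the design was open.

## Architecture

Five encoder stages with channel widths (32, 64, 128, 160, 256); each stage
is a DLKA block followed by an MSGP block, with 2×2 max pooling (stride 2)
after stages 1–4. Four decoder stages produce widths (160, 128, 64, 32);
each consumes the bilinear ×2 upsampling of the previous stage concatenated
with the same-stage encoder skip. A pointwise head maps the final
32-channel map to one logit per foreground class; each class gets an
independent sigmoid, background is implicit, and overlapping
above-threshold classes are resolved by the larger probability.

Choices the published description leaves open, fixed here:

- **Pooling** is max pooling (parameter-free, UNet convention);
  **upsampling** is bilinear with half-pixel centres (parameter-free;
  learned upsampling would change the parameter total).
- **Bias terms.** Every convolution that feeds a batch norm is bias-free
  (the BN shift subsumes it); only the prediction head keeps a bias. This
  is also what lands the parameter count on the printed figure.
- **DLKA gating** is `F = PW(Att ⊙ X') + X'`: the output pointwise
  convolution wraps the gated product and the residual is added outside.
  The block carries exactly two batch norms — after the expansion
  pointwise and after the attention pointwise; the depthwise pair in
  between is raw.
- **MSGP adders** use the *raw* neighbouring split, `k_i =
  ReLU(BN(D_rate(f_i + f_{i−1})))`. The processed-neighbour (Res2Net)
  wiring is available behind `MSGP(adder="processed")`; the two have
  identical parameter counts and we default to the literal reading.
- **Spatial shift**: channels split into eight contiguous equal groups,
  displaced by (−1,0), (1,0), (0,−1), (0,1), (−1,−1), (−1,1), (1,−1),
  (1,1) in that fixed order with zero fill; remainder channels (count not
  divisible by 8) pass through unshifted. Any fixed assignment is
  equivalent at initialisation; a deterministic one makes runs
  reproducible.
- **Decoder activations** (the stage equations are silent): every
  aggregation-path convolution is BN+ReLU; the first trailing SPPW is
  BN+ReLU, the second is BN only, then the residual addition, then ReLU —
  the standard pre-residual convention.
- **Input is 3-channel**: grayscale is replicated and normalized with the
  ImageNet channel statistics, so pretrained-style preprocessing applies
  unchanged.
- **Padding** is always zero "same": a k×k convolution at dilation d pads
  by d(k−1)/2.
- **Initialisation**: He normal with fan-out for convolution weights, BN
  scale 1 / shift 0, head bias 0; a single seeded generator orders all
  draws, so two models built from the same config and seed are identical.

### Decoder ablation variants

`decoder_variant="conv3x3_mod"` replaces every SPPW (the aggregation path
and both trailing operators) with a plain 3×3 convolution at identical
channel budgets — the variant whose parameter total (2.25 M) corroborates
the decoder interpretation. `decoder_variant="conv3x3"` is the all-3×3
baseline (two 3×3 conv+BN+ReLU with a pointwise-projected residual); its
published composition is under-specified, so it is provided for
completeness and not verified against printed figures.

## Complexity accounting

`count_parameters` enumerates every learnable tensor (conv weights, the
head bias, BN scale+shift) and is asserted equal to the registry
enumeration. `count_macs` records, during a real batch-1 forward pass:

| operation | ops per output element |
| --- | --- |
| convolution | (in_channels / groups) × k² multiply–accumulates |
| batch norm | 2 (scale, shift) |
| ReLU | 1 |
| 2×2 max pool | 4 (one per kernel tap) |
| bilinear ×2 upsample | 1 |
| elementwise add / Hadamard / spatial shift | 0 |

Bias additions are not counted. Totals are quoted as "FLOPs" in G, the
naming convention of the lightweight-segmentation literature. Under this
convention the default model measures 3.82 G at 3×256×256 and the
conv3x3_mod variant 9.95 G; counting convolutions alone would give 3.75 G
and 9.88 G (the `ComplexityReport.conv_macs()` subtotal keeps that number
visible). Zero-padding savings at borders are not modelled — every kernel
tap counts — matching the closed form out_elems × cin/g × k².

## Loss, schedule, metrics

Training minimises `0.5·BCE + Dice` per class, averaged over classes; a
batch is treated as one pixel population. The trainer evaluates BCE on
logits through the softplus identity (stable for saturated activations);
the public `bce_loss(P, G)` operates on probabilities clipped to
[1e−7, 1−1e−7]. Dice uses squared-magnitude normalisation with smoothing
ε = 1e−5 (configurable), so empty-vs-empty costs 0. The learning rate
follows `η(e) = η₀ (1 − e/E)^0.9` per epoch with η₀ = 1e−3, E = 150,
Adam with weight decay 1e−4 (classic L2-in-gradient form), batch size 8.
The checkpoint with the lowest validation loss is selected; no early
stopping in normal training. Augmentation (training split only):
independent 0.5-probability horizontal/vertical flips and a rotation
uniform in ±15° (the published recipe says only "random rotation"; ±15°
keeps retinal geometry plausible), nearest-neighbour for masks.

Evaluation reports IoU, DSC, precision and sensitivity from per-class
pixel confusion counts, with the empty-vs-empty convention scoring 1, and
HD95 — the 95th percentile (linear interpolation) of Euclidean distances
between boundary sets, maximised over the two directions. Boundaries are
foreground pixels with at least one background 4-neighbour; the image
border counts as background. One empty mask yields +inf, two empty masks 0.
Whether published HD95 values were computed on boundary or full masks is
unstated; boundary is the common medpy-style choice and is noted for
comparability.

## Numpy execution stack

No deep-learning framework is assumed: a minimal reverse-mode autograd
(`lkmu.nn`) provides exactly the primitives the network needs.
Convolutions are evaluated stride-1 "same" as a sum over kernel taps of a
pointwise product on a shifted frame — one BLAS GEMM per tap per group,
no im2col buffer; taps displaced beyond the feature map (possible for the
dilated 7×7 at the 8×8 bottleneck) contribute nothing and are skipped,
which is exactly zero padding. Gradients of every primitive are verified
against central differences, and conv forward against scipy's
`correlate2d`.

Batch-norm running statistics use momentum 0.3 (not the common 0.1):
the intended datasets here are small and in-memory, an epoch contributes
few batches, and evaluation-mode statistics must track the training
distribution within a few epochs — with one batch per epoch, momentum m
converges the running estimates as (1−m)^epochs. Training-mode behaviour
is unaffected.

## Synthetic phantoms

`generate_phantom` renders: 6–10 curved reflective bands (sinusoidal
vertical displacement) with depth-sorted mean intensities in [0.2, 0.8]
over a dark background; fluid regions as randomly deformed ellipses
darkened by an `intensity_drop` fraction (default 0.35) — class 1 rounded
intraretinal pockets, class 2 lens-shaped pockets hanging under a layer
boundary, class 3 dome-shaped bumps on the bottom band, all clipped to the
retinal band; Gaussian edge blur (σ = 1); multiplicative gamma speckle
(mean 1, shape 60 by default). Device profiles A/B/C scale contrast
(1.0/0.85/0.7) and speckle shape (×1.0/0.6/0.35), so C is measurably
noisier than A — a stand-in for multi-vendor variation. Everything derives
from one seeded generator: identical (spec, seed) pairs give bit-identical
samples and dataset files.

What the phantoms are not: clinically realistic OCT. There is no A-scan
physics, no shadowing, no vessel artefacts, and fluid boundaries are
smoother than real lesions. A green training or capacity test therefore
establishes that the architecture, gradients, optimizer and data plumbing
work end to end — not that the published clinical accuracy is reproduced,
which would require the proprietary datasets and GPU-scale training that
are explicitly out of scope.

## Known limitations

- CPU-only numpy execution: roughly seconds per 8-image 128² training
  step; suitable for the bundled capacity checks, not for 150-epoch runs
  on thousands of images.
- The all-3×3 decoder baseline is a best-effort reconstruction (see
  above).
- Checkpoints are numpy `.npz` plus a JSON architecture sidecar; no
  interchange format is provided.
- Multi-class prediction uses independent sigmoids with implicit
  background; softmax-with-background is not implemented.
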