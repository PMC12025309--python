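# Methods

## Problem and model

The package segments the synovium — the hypoechoic soft-tissue recess lying
on the bone surface of a finger joint — in 3D B-mode ultrasound volumes.
The segmentation network combines two ideas:

1. **A hierarchical shifted-window transformer encoder.**  The volume is cut
   into non-overlapping 2×2×2 voxel patches, linearly embedded into C
   channels (the *feature size*), and processed by four stages of window
   attention blocks.  Each block is the standard pre-norm pair

       ẑ = W-MSA(LN(z)) + z,   z' = MLP(LN(ẑ)) + ẑ,

   where W-MSA computes multi-head self-attention inside local windows of
   `window³` tokens with softmax(QKᵀ/√d + B)V (B a learned relative-position
   bias), and consecutive blocks alternate between the regular partition and
   one cyclically shifted by ⌊window/2⌋ so neighbouring windows exchange
   information.  Between stages, patch merging concatenates 2×2×2 token
   neighbourhoods, layer-normalises and projects them, halving extents and
   doubling channels.  The result is a four-level feature pyramid at scales
   1/2 … 1/16 with channels C … 8C.

2. **Deep attentive feature fusion.**  Every pyramid level is projected to a
   common width (single-layer features, SLF) and upsampled to the level-1
   grid; their concatenation is fused into multi-layer features (MLF).  Per
   level, an attention module maps (SLF_i, MLF) through three 3×3×3
   convolutions to sigmoid weights A_i ∈ (0,1)^C, the gated MLF' = A_i ⊙ MLF
   is merged back with SLF_i (two 3×3×3 plus one 1×1×1 convolution), and the
   four refined features pass through a dilated-convolution pyramid (ASPP)
   before the 1×1×1 segmentation head.  Deep supervision attaches a head to
   every SLF and every refined feature: 4 + 4 auxiliary probability maps next
   to the main output.

The training objective per map is Dice + voxel-mean binary cross-entropy;
the deeply supervised total weights the SLF and attentive auxiliaries with
the empirical coefficients (0.4, 0.5, 0.7, 0.8) each and adds the unweighted
output loss.  Optimisation is Adam (lr 1e-4, weight decay 1e-4), batch size
one, 50 epochs, model selection by highest validation Dice — the
clinical-scale protocol; desk-scale runs shrink epochs/steps, not the rules.

## Numerical core

No deep-learning framework ships in the dependency set, so the package
carries a minimal reverse-mode autodiff engine over float32 NumPy arrays
(`swindaf3d._autodiff`): a tape of vector-Jacobian closures with exactly the
primitives the networks need (GEMM-based 'same' 3D convolution, window
partition/roll/pad, softmax with −∞ masking, fused normalisation, separable
trilinear ×2 upsampling, max-pooling, PReLU/GELU/sigmoid, Adam).  Every
primitive is validated against central finite differences in the test suite;
windowed attention is additionally validated against a dense brute-force
attention oracle.  The tape releases its buffers as the backward sweep
progresses, keeping a training step's footprint below ~1 GB at desk scale.

## Choices the sources leave open

* **Intensity normalisation** — per-volume min–max to [0, 1] (matches B-mode
  display conventions and keeps BCE inputs bounded); constant volumes map to
  zeros.  Crop centring uses floor offsets; mask resizing is nearest-
  neighbour so masks stay binary; masks binarise at 0.5 on read and the
  probability threshold is 0.5.
* **Encoder layout** — depths (2,2,2,2), heads (3,6,12,24), MLP ratio 4,
  GELU, relative-position bias on (toggleable), truncated-normal (σ = 0.02)
  initialisation: the standard small-variant configuration of hierarchical
  window-attention encoders.  Border handling is zero-padding plus attention
  masking, with padded query rows zeroed, so partition→reverse is exact for
  any extents.
* **Fusion head widths** — fusion at the level-1 grid (half input
  resolution), SLF width 64 (MLF 256) at clinical scale.  The attention
  module's two hidden convolutions run at the SLF width (a bottleneck) with
  the final convolution mapping to the MLF width for gating; attention and
  refinement parameters are per-level (unshared).  Group norm (8 groups) +
  PReLU follow every head convolution — batch size one rules out batch norm.
  ASPP rates (1,2,3,4); a rate whose offset would leave the grid is clamped
  with a warning.  Auxiliary losses are computed at full input resolution
  (logits upsampled before the sigmoid/loss) rather than against a label
  pyramid.
* **Loss conventions** — BCE is the standard negative log-likelihood
  averaged over voxels (resolution-independent magnitudes), probabilities
  clipped at 1e-7.  Dice smoothing ε = 1e-5 appears in numerator and
  denominator so the empty-vs-empty case yields loss 0 while P = G remains
  exactly 0.  A `reduction="sum"` switch exists for the BCE.
* **Statistics** — fold summaries use the population (divide-by-n) standard
  deviation: recomputing the bundled benchmark table's per-fold values
  reproduces its printed Std rows only under this convention.  The Wilcoxon
  signed-rank test enumerates all 2ⁿ sign assignments exactly (midranks on
  ties, zeros dropped) up to n = 20 and falls back to the normal
  approximation beyond; two-sided by default with one-sided options, and
  Bonferroni correction multiplies p by the comparison count.  With n = 6
  folds the smallest achievable two-sided exact p is 2/64 ≈ 0.031, so
  five-way Bonferroni-corrected significance at 0.05 is unreachable
  two-sided — the harness therefore reports raw and adjusted values for both
  sidednesses rather than guessing a convention.
* **Cross-validation** — seeded shuffle + round-robin assignment; an
  optional case→group mapping (e.g. patient id) keeps whole groups in one
  fold.  Per fold, the checkpoint with the highest validation DSC is kept
  and all metrics are reported at that checkpoint.

## Synthetic phantoms

Clinical volumes cannot be shared, so a generator stands in.  Each phantom
composes, top to bottom: a bright skin band (5% of depth), speckled soft
tissue with a low-frequency echogenicity field (intensity inhomogeneity), a
curved hyperechoic bone interface at 55–75% depth (parabolic recess plus
smooth perturbation), depth-wise exponential attenuation below the bone
(acoustic shadow, strength 0.6), and the synovium: a union of 2–4 random
ellipsoids hugging the bone interface, its implicit function perturbed by a
smooth random field (ambiguous boundary), rendered hypoechoic at half the
background echogenicity (contrast gap 0.5).  Fully developed speckle is
approximated by unit-mean multiplicative gamma noise with relative standard
deviation 0.3.  The mask fraction is steered into the configured range
(2–10% of voxels by default) by thresholding the implicit function at the
order statistic matching a target fraction drawn inside the range — by
construction, not rejection.  Per-case seeds derive from
`SeedSequence(global_seed, spawn_key=(index,))`, so datasets are bit-
reproducible and stable under reordering.

What the phantoms do *not* model: wave-propagation physics, probe geometry,
scan conversion, anisotropic voxel spacing, real anatomical shape priors.
Passing the capacity and contract tests therefore demonstrates that the
implementation can learn and measure what it is supposed to at desk scale —
it does not certify clinical accuracy, which the original study established
on data this package cannot access.

Augmentation emulates probe repositioning and gain changes: lateral/
elevation flips, ≤15° rotation about the elevation axis (trilinear for the
volume, nearest for the mask), brightness/contrast scaling, Gaussian blur,
additive noise; each applied with probability 0.5, photometric transforms on
the volume only, outputs clipped to [0,1].  Offline augmentation appends a
configurable number of augmented copies.

## Problem sizes used by tests and the acceptance script

CPU-scale sizes are the package's declared experiment design:

* overfit capacity check: feature size 12, window 3, depths (1,1,1,1),
  heads (2,4,4,8), SLF width 16; four phantoms of 64×64×32; Adam lr 1e-3
  (the scaled-down run converges in a few hundred updates at this rate;
  the clinical protocol's 1e-4 belongs to the 50-epoch regime), weight decay
  1e-4, ≤300 updates, seed 0, success at train DSC ≥ 0.90;
* phantom contracts: 1000 phantoms at 32×32×16 (tests) and 300 in the
  acceptance script;
* metric oracle: 200 random 12³ mask pairs (tests), 100 in the script;
* sweep smoke: feature sizes (24,36,48,60) × window 7 and windows (3,5,7,9)
  × feature 48, forwarding 32×32×16 volumes in shape-check mode.

## Known limitations

* CPU-bound: clinical-scale volumes (256×256×64, C = 48) forward correctly
  but training at that scale is impractical without an accelerator.
* BCE gradients vanish where predictions saturate against the clip bounds;
  the Dice term keeps optimisation moving.
* The exact Wilcoxon enumeration is exponential in the number of non-zero
  differences (capped at 20 before the normal approximation takes over).
* `batch_size > 1` is gradient accumulation over single volumes, not true
  batching; normalisation statistics are always per-volume.
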