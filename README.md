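# swindaf3d

Automated segmentation of the **synovium** — the joint-lining membrane whose
inflammation marks early rheumatoid arthritis — in 3D B-mode ultrasound
volumes of finger joints.  The synovium appears as a hypoechoic recess above
the bone surface with ambiguous boundaries, variable shape and inhomogeneous
intensity, which makes manual delineation slow and observer-dependent.

The package is aimed at researchers in ultrasound image analysis who need a
fully inspectable, CPU-runnable reference implementation of the method, a
synthetic phantom generator standing in for unshareable clinical data, and
the evaluation/statistics harness that goes with cross-validated
segmentation studies.

## The model

A hierarchical shifted-window transformer encoder feeds a deep attentive
feature fusion head:

* **Encoder** — 2×2×2 patch embedding into C channels, four stages of
  window-attention blocks (`ẑ = W-MSA(LN(z)) + z`, `z' = MLP(LN(ẑ)) + ẑ`,
  attention `softmax(QKᵀ/√d + B)V` inside `window³` token cubes, alternating
  regular and shifted partitions), patch merging between stages: a feature
  pyramid at scales 1/2 … 1/16 with channels C, 2C, 4C, 8C.
* **Head** — per-level lateral projections to single-layer features (SLF),
  concatenated into multi-layer features (MLF); per level an attention
  module computes `A_i = σ(f_a(SLF_i, MLF))`, the gated `A_i ⊙ MLF` is
  refined back with SLF_i, and the fused result passes through 3D ASPP to
  the segmentation head.
* **Deep supervision** — hybrid Dice + BCE loss on the main map plus 4 SLF
  and 4 attentive auxiliary maps, weighted (0.4, 0.5, 0.7, 0.8) per group:
  `L_total = Σ w_i L_i,slf + Σ w_j L_j,attn + L_out`.
* **Metrics** — Dice `2|A∩B|/(|A|+|B|)`, IoU `|A∩B|/|A∪B|`, and surface
  Dice at tolerance d = 1 voxel; fold summaries (mean ± population std) and
  exact Wilcoxon signed-rank comparison with Bonferroni correction.

The networks run on a small reverse-mode autodiff engine over NumPy that is
part of the package (`swindaf3d._autodiff`), so everything trains and
evaluates on a plain CPU at desk scale.

## Worked example

Train the scaled-down network on four synthetic phantoms until it overfits
them, then evaluate (this is the package's built-in capacity check):

```python
import numpy as np
from swindaf3d.estimators import SwinDAF3DSegmenter
from swindaf3d.phantom import PhantomConfig, generate_dataset
from swindaf3d.metrics import evaluate_masks

cases = generate_dataset(PhantomConfig(shape=(64, 64, 32), seed=0), 4)
X = [c.volume.data for c in cases]
y = [c.mask.data for c in cases]

est = SwinDAF3DSegmenter(embed_dim=12, window=3, depths=(1, 1, 1, 1),
                         heads=(2, 4, 4, 8), lateral_channels=16,
                         groupnorm_groups=4, lr=1e-3, epochs=75,
                         max_steps=300, eval_every=2, stop_at_val_dsc=0.90,
                         seed=0)
est.fit(X, y)
print(f"steps: {est.n_iter_}  train DSC: {est.best_val_dsc_:.3f}")

m = evaluate_masks(est.predict(X[:1])[0], y[0])
print(f"case 0: dsc={m.dsc:.3f} iou={m.iou:.3f} sdsc={m.sdsc:.3f}")
```

which prints

```
steps: 92  train DSC: 0.925
case 0: dsc=0.949 iou=0.903 sdsc=0.978
```

i.e. the 0.9M-parameter desk-scale model memorises the four phantoms to a
Dice of 0.92 within 92 optimiser updates; the surface Dice of 0.98 says the
predicted boundary sits within one voxel of the truth almost everywhere.

The statistics harness reproduces cross-validation summary rows from
per-fold values:

```python
from swindaf3d.stats import load_benchmark_folds
table = load_benchmark_folds()
s = table.summarize("swindaf3d", "dsc")
print(f"{s.mean:.3f} +/- {s.std:.3f}")        # 0.838 +/- 0.013
r = table.compare("swindaf3d", "unet3d", "dsc", m=5)
print(f"p={r.p_raw:.4f} (Bonferroni x5: {r.p_adjusted:.4f})")
# p=0.0312 (Bonferroni x5: 0.1562)
```

A `swindaf3d` command-line tool covers the same ground from a shell
(`swindaf3d phantom|train|evaluate|cv|sweep --help`).

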