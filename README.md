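# bemseg

Distinct bone segmentation from CT with **binary-prediction-enhanced
multi-class (BEM) inference**.

Distinct bone segmentation labels every voxel of a CT scan as background or
as one particular bone (each vertebra, each rib, …) — as opposed to binary
bone-tissue segmentation, which only separates bone from everything else.
3D U-Nets handle the multi-class task well, but their dominant error is
mistaking bone for background rather than one bone for another. `bemseg`
implements the inference-time fix: let a binary bone-tissue prediction
decide *where* bone is, and restrict the multi-class decision to foreground
classes there. With softmax probabilities `p(c|v)` over classes
`c ∈ {0, …, N−1}` (0 = background) and a binary guide mask `y_bg/bt`,

    ŷ(v) = 0                          if y_bg/bt(v) = 0,
    ŷ(v) = argmax_{c≥1} p(c|v)        otherwise.

Unlike masking a finished prediction, this repairs false negatives as well
as false positives: the output is nonzero exactly where the mask says bone.

The package contains the full pipeline around this idea:

- `bemseg.synthetic` — procedural skeletal CT phantoms: 41 stick-figure
  bones in 128×128×256 voxels, four tissue HU regimes plus uniform noise,
  with a 7-bone miniature for fast runs;
- `bemseg.models` — a baseline 3D U-Net and four dual-segmentation-head
  variants (shared heads, per-head conv blocks, sequential heads, separate
  decoders), the combined cross-entropy + soft-Dice loss, patch sampling
  and an Adam training loop, all on a compact numpy autodiff core
  (`bemseg.nn`);
- `bemseg.inference` — padded sliding-window probability assembly, standard
  argmax and BEM inference;
- `bemseg.label_correction` — connected-component post-processing that
  absorbs stray fragments into adjacent anchor components within confusion
  sets;
- `bemseg.evaluation` — per-class Sørensen–Dice, `median_{−σ}^{+σ}`
  summaries with detected-class fractions, row-normalized confusion
  matrices;
- `bemseg.cli` / `bemseg.experiment` — a `bemseg` command with
  `generate` / `train` / `infer` / `correct` / `evaluate` / `experiment`
  subcommands wiring everything into reproducible runs.

With the pinned default widths `(26, 52, 104, 176, 444)` and 126 output
classes, the baseline network has 14 565 900 trainable parameters
(1.46·10⁷) and the separate-decoder variant `dual_d` has 19 794 006
(1.98·10⁷); the dual variants A–C stay at 1.46·10⁷ to three significant
figures.

## Worked example

Generate a miniature phantom, fabricate the failure mode BEM targets (a
softmax whose background score was inflated inside bones), and compare
standard inference with BEM guided by the ground-truth mask:

```python
import numpy as np
from bemseg import (AnatomyParams, generate_volume, binarize_labels,
                    ProbabilityVolume, standard_argmax, bem_combine,
                    dsc_per_class, summarize)

ct, gt = generate_volume(AnatomyParams.mini(seed=42))

rng = np.random.default_rng(0)
n = gt.n_classes
probs = np.full((n,) + gt.shape, 0.3 / (n - 1), dtype=np.float32)
idx = tuple(np.indices(gt.shape))
probs[(gt.labels.astype(int),) + idx] = 0.7      # true class favoured...
hit = (gt.labels > 0) & (rng.random(gt.shape) < 0.4)
probs[0][hit] = 0.8                              # ...but background wins at 40% of bone
probs /= probs.sum(axis=0, keepdims=True)
P = ProbabilityVolume(probs)

print("standard :", summarize(dsc_per_class(standard_argmax(P), gt)).format())
print("bem-gt   :", summarize(dsc_per_class(
    bem_combine(P, binarize_labels(gt)), gt)).format())
```

prints

```
standard : 0.77_{-0.05}^{+0.01}, (1.00)
bem-gt   : 1.00_{-0.00}^{+0.00}, (1.00)
```

i.e. the class-median Dice over true-positive classes, its 16/84-percentile
spread, and the fraction of detected classes in brackets. Standard argmax
loses ~40 % of every bone to the background class; BEM with a correct
bone-tissue mask recovers all of it, because inside the mask only
foreground classes compete.

The same comparison end-to-end — train a tiny dual-head network on phantom
scans, then evaluate standard vs BEM inference with and without label
correction:

```
bemseg experiment --config my_experiment.yaml
```

where the YAML sets volumes, split, variants, iterations and modes (see
`bemseg.experiment.ExperimentConfig` for all keys and defaults).

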