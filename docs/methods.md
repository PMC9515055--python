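# Methods

## Problem setting

Distinct bone segmentation assigns every voxel of a CT scan either to the
background or to one of N−1 individual bones (each vertebra, each rib, …),
in contrast to binary bone-tissue segmentation, which only separates bone
from everything else. 3D U-Nets solve this task reasonably well, but their
dominant error mode is not confusing one bone with another — it is confusing
bone with background. `bemseg` implements an inference-time remedy: use a
binary bone-tissue prediction as a guide and restrict the multi-class
decision to foreground classes wherever the guide says "bone".

## BEM inference

Let `p(c | v)` be the softmax output of a multi-class network over classes
`c ∈ {0, …, N−1}` (0 = background) and `y_bg/bt(v) ∈ {0, 1}` a binary
bone-tissue mask. Standard inference predicts `argmax_c p(c | v)`. BEM
(binary-prediction-enhanced multi-class) inference predicts

    ŷ(v) = 0                             if y_bg/bt(v) = 0
    ŷ(v) = argmax_{c ≥ 1} p(c | v)       otherwise.

The output support therefore equals the guide-mask support exactly. Unlike
masking a finished multi-class map (which can only delete false positives),
BEM also repairs false negatives: a voxel whose background score narrowly
won the softmax is reassigned to its best foreground class. The guide mask
can come from a second head of the same network, from a separately trained
binary network (two-stage), or — as an upper bound — from the binarized
ground truth. Ties in any argmax go to the lowest class index, which makes
inference deterministic.

## Network family

All variants share one trunk recipe: an encoder/decoder with skip
connections; two 3×3×3 convolutions per resolution level, each followed by
affine instance normalization (ε = 1e−5) and a leaky ReLU (slope 0.01);
parameter-free 2× max-pooling between encoder levels; trilinear upsampling
in the decoder; 1×1×1 convolution heads. Batch size is 1 (a practical
constraint of 3D patches with many classes), which is also why instance
normalization is used rather than batch normalization.

The binary head is attached in four ways:

| variant | wiring |
|---|---|
| dual A | shared trunk, two 1×1×1 heads |
| dual B | shared trunk, each head behind its own full-resolution conv block |
| dual C | binary head on the decoder output; multi-class head after one more conv block |
| dual D | shared encoder, two separate decoders |

Dual C's extra block consumes the decoder output, not the binary logits;
feeding the binary prediction into the multi-class branch would make the
heads truly sequential, but the branching-from-the-trunk wiring is the
simpler reading and is what is implemented.

Exact depths and widths are a free choice in this family; what the package
pins down are the trainable-parameter totals (1.46·10⁷ for the baseline
and the dual A–C variants, 1.98·10⁷ for dual D, at 126 classes). The
default channel widths `(26, 52, 104, 176, 444)` were chosen once, by a
closed-form search over increasing width lists under the trunk recipe
above, to reproduce those totals to three significant figures.
The search has two effective degrees of freedom beyond the doubling
pattern (the break at level 3 and the bottleneck width); the published
totals pin both. `count_parameters` counts every trainable scalar
(convolution weights and biases, normalization gains and shifts).

## Training

The loss is the unweighted sum

    L_total = L_XEnt(multi) + Σ_{c ∈ C} L_Dice^c(multi)
            + L_XEnt(binary) + Σ_{c ∈ {bg, bt}} L_Dice^c(binary)

with the binary terms present only for dual-head networks; the binary
target is derived on the fly as `labels > 0`. Cross-entropy is averaged
over voxels. The per-class soft Dice loss on softmax probabilities p and
one-hot targets g is `1 − (2Σpg + ε)/(Σp + Σg + ε)` with ε = 1e−5, summed
over all classes including those absent from the patch (an absent class
with negligible predicted mass contributes ≈ 0 through the ε terms).

Optimization uses Adam at learning rate 0.001 with one randomly cropped
64³ patch per iteration — random cropping is the only data augmentation.
The reference regime is 75 000 iterations; the test suite and the
acceptance script instead run a few hundred iterations on miniature
phantoms (32×32×64, 7 bones, 16³ patches, widths (6, 12)), which is enough
to verify that the loss decreases and that the full pipeline holds
together, but makes no claim about converged segmentation quality.

Networks, autodiff and Adam are implemented directly on numpy arrays in
`bemseg.nn`: a small reverse-mode tape with the seven ops the U-Net family
needs (3D convolution, 2× max-pool, trilinear 2× upsampling, instance
norm, leaky ReLU, concatenation, and joint multi-head backward). Gradients
are verified against central finite differences op-by-op in the test
suite. Activations are float32; loss accumulation is float64. Input HU
values are divided by 1000 before entering the network.

## Sliding-window inference

Whole volumes are predicted patchwise: the scan is padded by 20 voxels of
air (−1024 HU), tiled with 64³ windows at stride `patch − overlap`
(overlap 20), with the last window per axis shifted flush to the volume
end so coverage is complete for any extent. Softmax probabilities of
overlapping windows are averaged with uniform weights; the average of the
probabilities is then cropped back to the original grid. Center-weighted
(e.g. Gaussian) fusion is a known alternative; uniform averaging is used
because it keeps the assembly exactly equal to a per-voxel
accumulate-and-normalize reference, and the overlap already gives interior
predictions more context than border ones.

## Connected-component label correction

Within each confusion set L (a hand-chosen group of mutually confusable
classes), all connected components of every class are enumerated under
26-connectivity, sorted by size (ties by smallest flattened voxel index),
and capped at the u = 100 largest per class — the cap is purely a runtime
safeguard bounding the pairwise adjacency work by |L|²·u per set, and
components beyond it are simply left untouched. The largest component of
each class is its anchor. Every non-anchor component adjacent
(26-neighbourhood) to an anchor of a *different* class in the set is
relabeled to that anchor's class; with several adjacent anchors, the one
with the most touching voxel pairs wins, ties going to the lowest class
id. Reassignment is computed from the input labeling and applied
atomically per set — no fixpoint iteration — and fragments touching no
anchor are kept, not deleted, so the foreground voxel set is conserved
exactly. Sets are disjoint and independent, hence trivially
parallelizable; the implementation processes them sequentially.

Default sets ship for the 42-class synthetic skeleton (vertebral column,
left/right rib cage, shoulder girdles + arms, pelvis + legs) and follow
the generator's bone families. For other class counts a consecutive-run
grouping of size 4–12 is provided as an editable placeholder; real use
should replace it with sets derived from anatomy and from the validation
confusion report (`confusion_report`).

## Synthetic phantoms

The generator emulates a public synthetic dataset regime: 50 scans of
128×128×256 voxels with 41 distinct bones in a stick-figure layout, split
17/7/26 into train/validation/test. The bone inventory — head sphere, 12
identical squashed-cylinder vertebrae, 8 rib pairs as curved tubes, 2
clavicles, humerus + forearm rods per arm, sternum plate, pelvis block,
femur + lower-leg rods per leg — was designed so that bones within a
family share geometry and differ chiefly in position, forcing a model to
use relative position rather than shape alone. Per-bone uniform jitter
(±2 voxels translation, ±8 % scale) randomizes each scan; a draw that
would push a bone out of the volume, erase it, or disconnect it is
rejected and retried (budget 10, then an error).

Soft tissue is the union of per-compartment convex hulls (head, torso,
each limb) of the bone voxels — per-compartment rather than global so the
space between limbs stays background. Rendering assigns −1000 HU outside
the hull, +40 HU to soft tissue, +300 HU to bone interiors (cancellous)
and +1200 HU to the one-voxel cortical shell (bone voxels with a
6-neighbour outside their own bone), then adds i.i.d. uniform noise in
±50 HU. The four HU levels are standard tissue values; the noise bounds
are a free parameter of the model. Per-volume seeds are derived from
(master seed, volume index) with numpy's `SeedSequence`, so any volume
regenerates bit-identically in isolation.

What the phantoms do *not* model: anisotropic acquisition, partial-volume
effects, scanner noise spectra, soft-tissue contrast variation, pathology,
or anatomically accurate shapes. Passing tests on phantoms therefore
demonstrates the mechanics of the pipeline (BEM support identity,
label-correction conservation, metric correctness, trainability), not
clinical segmentation accuracy.

## Evaluation

Per class c ≥ 1, `DSC_c = 2|X_c ∩ Y_c| / (|X_c| + |Y_c|)`. A run is
summarized by the median and the 16th/84th percentiles (≈ ±1σ, linear
interpolation between order statistics) over classes with at least one
true-positive voxel, reported as `median_{−σ}^{+σ}`, together with the
fraction of ground-truth-present classes with DSC_c > 0 in brackets.
Classes absent from the ground truth are excluded from that denominator —
a detection fraction over classes that cannot be detected would be
meaningless. Confusion matrices are indexed by ground-truth class along
rows, so row-normalization yields per-class recall profiles and the first
column shows bone→background errors — the error mode BEM removes wherever
the guide mask is correct.

## Numerical and degenerate-input choices

- Argmax ties: lowest class index, everywhere.
- `mask_to_binary` maps a 2-class probability tie (0.5/0.5) to bone.
- Nearest-neighbour resampling ties round half toward the origin.
- Stored float labels must be within 1e−3 of an integer, else an error.
- A summary over zero true-positive classes raises rather than returning
  a fabricated number.
- Instance norm of a constant channel returns the (shifted) zero map via
  its ε; no special casing.

## Known limitations

- Training at the reference scale (75 000 iterations, 64³ patches, full
  widths) is far outside what the numpy backend does in reasonable time;
  the backend is meant for desk-scale verification and small studies.
- Uniform patch fusion and the 26-connectivity/strongest-contact choices
  in label correction are defensible defaults, not validated optima; both
  are configurable.
- The stand-in confusion sets for class counts other than 42 group labels
  by numeric adjacency only.
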