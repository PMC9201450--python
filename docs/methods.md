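# Methods

## Model

The model is an image classifier whose internal patch-probability grid is
read out as a segmentation map, trained with image-level labels only
(multiple-instance learning: the image is a bag of patch instances).

**Backbone.** A grouped-convolution residual network in the
split-transform-merge style: a 7×7 stride-2 stem, then four stages of
bottleneck blocks (1×1 reduce → grouped conv → 1×1 expand, with an
identity shortcut, or a 1×1 projection with the block's stride in each
stage's first block; batch normalization and a rectifier after every
convolution, post-activation order). The canonical configuration has block
counts 3/4/6/3, cardinality 32, stage outputs 256/512/1024/2048, grouped
widths equal to half the stage output. In the *restricted* layout exactly
four grouped convolutions keep a 3×3 kernel — the stride-1 conv in stage
1's first block and the stride-2 downsamplers entering stages 2–4 — and all
other convolutions are 1×1. There is no pooling layer; stage resolutions
are strides 2/4/8/16. Composing `rf_l = rf_{l−1} + (k_l − 1)·j_{l−1}`,
`j_l = j_{l−1}·s_l` over this sequence gives a receptive field of exactly
39 pixels at total stride 16: 7×7/2 → 7, +3×3/1 at jump 2 → 11, then the
three 3×3/2 downsamplers at jumps 2/4/8 → 15, 23, 39. A max-pool after the
stem is incompatible with reaching 39 under this composition rule with any
3×3/1×1 assignment, which is why the stem is pool-free. The empirical
check backpropagates a unit gradient from every channel of one interior
output cell in evaluation mode (training-mode batch-norm statistics couple
all spatial positions and would smear the footprint) and unions the
footprints over two random inputs so rectifier dead paths cannot shrink
the measurement.

With `restricted=False` every grouped convolution is 3×3 (receptive field
215 px); stage strides are unchanged, so the output grid stays h/16 and
ablation metrics remain comparable.

**Patch-centred alignment.** With symmetric convolution padding, output
cell (i, j) has its receptive field centred on input pixel (16i, 16j) —
the *corner* of the 16×16 patch the cell is read out as. Since the weak
objective never says *which* patch should fire, a model trained this way
localizes evidence around receptive-field centres, and the segmentation
readout inherits a systematic half-patch offset (measured directly: on a
trained desk model, shifting the predicted mask by (−8, −8) raised mean
abnormal-image IoU from 0.29 to 0.41). The extractor therefore shifts its
input by half a patch (`patch_centered`, on by default) so every cell's
receptive field is centred on its patch centre; the receptive-field size,
stride and grid geometry are unchanged.

Initialization is fan-in-scaled normal everywhere; imported pretrained
weights are out of scope because the 1×1 replacement changes kernel shapes.

**Position attention.** The h′×w′×c′ grid is flattened row-major (row
index varies slowest; this convention is fixed everywhere) and embedded as
`z₀ = x_p E + E_pos` with a learned positional table initialized from
N(0, 0.02²). Two pre-norm residual layers follow: multi-head scaled
dot-product attention (canonically M = 12 heads), then a one-hidden-layer
MLP. Since d = 1024 is not divisible by 12, each head uses the
conventional width 64; the concatenated 768-wide context is projected back
to d, so the choice only affects the inner width. The MLP hidden width is
d (not the usual 4d — the per-token perceptron is deliberately small), its
nonlinearity the Gaussian-error linear unit. No class token, no dropout.
The positional table is size-locked: a grid with a different token count
is a configuration error, never interpolated.

**Head, voting, loss.** Two pointwise convolutions (hidden width 256,
rectifier) and a sigmoid produce per-patch, per-class probabilities —
channels are independent sigmoids, not a softmax, so co-occurring diseases
do not compete. Image-level probabilities come from one of four
aggregators: average, max, LSE with smoothness r, or adaptive LSE with
threshold fraction t. LSE is evaluated by factoring the grid maximum out
of the exponentials (algebraically identical, overflow-proof; verified
against the naive summation to 1e−6 over random grids up to r = 50).

Two adaptive-LSE choices deserve note. The normalizer is kept at the full
patch count h′·w′ even when patches are gated out; dividing by the
included-patch count may look more natural, but the full-grid form is the
one implemented, and its consequence is documented and tested: a grid with
n of N patches included is depressed by up to ln(N)/r below the patch
range, so the "probability" can be slightly negative (the loss clamps to
[1e−7, 1−1e−7] before logarithms). Second, the inclusion indicator is
held constant during gradient computation — a hard gate, no straight-
through relaxation — so excluded patches receive exactly zero gradient.

The weak loss is the α-balanced focal loss summed over classes and
averaged over the batch (the batch reduction is a choice; summation would
only rescale the learning rate). At γ = 0 it reduces exactly to the
α-weighted cross-entropy. Under mixed supervision, samples with pixel
masks contribute patch-level binary cross-entropy plus soft Dice
(smoothing ε = 1) against the mask downsampled to the patch grid — a patch
is positive when ≥ 50% of its 16×16 pixels are — and the masked and
unmasked populations are averaged separately, then summed, so a scarce
masked minority is not drowned out.

## Training protocol

SGD with momentum 0.9, batch 8, initial learning rate 0.001, multiplied by
0.3 when the training loss plateaus (relative improvement < 1e−4 for more
than 10 epochs; floor 1e−6). Model selection keeps the best-validation-AUC
checkpoint; because AUC saturates within a few epochs on easy synthetic
data, exact AUC ties break in favour of better validation IoU, then
recency — otherwise the retained checkpoint would be the first epoch that
classifies well, long before localization has formed. Data order and
initialization derive from one seed, so runs are bit-reproducible. At the
desk scale used throughout the tests (see
below) the initial rate is 3e−4: with quarter-width channels and 16-patch
grids, 1e−3 reliably drives the sigmoid head into saturation (every image
voted ≈ 1, vanishing gradients) before the voting signal forms.

Classification metrics: rank-based AUC (ties ½), and
sensitivity/specificity/F1 at a 0.5 operating point on the voted
probability. Segmentation: the patch grid is upsampled ×16
nearest-neighbour, binarized at 0.5 (≥ convention), and compared with the
pixel mask by IoU, averaged over abnormal test images only — against an
empty ground truth the empty∩empty convention would swamp the mean.

## Synthetic phantoms

The generator emulates the two structural properties the method is built
around, at 64×64 grayscale: (i) *bilateral symmetry* — two mirrored bright
elliptical fields (exact mirror symmetry up to additive noise; a
distractor-only scene flipped horizontally is pixel-identical when noise
is off); (ii) *position-dependent lesions* — abnormal scenes (probability
0.5) carry 1–3 soft-edged bright blobs, radius 7–13 px, centred at draws
from an upper-field-biased prior restricted to one field and guarded one
maximum radius away from the midline, so lesions are never mirrored.
Optional mirrored distractor blobs (1–2 pairs, radius 2–4 px) appear in
both fields of any scene and carry no label information. Additive Gaussian
noise (σ = 0.02) and [0,1] clipping finish the render. Labels equal mask
non-emptiness by construction; datasets are written as 8-bit PNGs with a
CSV manifest and a seeded 7:1:2 train/validation/test split.

The radius range was fixed by a quantization analysis, not by tuning: with
a 16-px patch grid, an *ideal* patch-level detector on 7–13 px blobs
attains mean pixel IoU ≈ 0.45–0.53 (the patch lattice cannot trace blob
boundaries), leaving clear headroom above the 0.30 acceptance bar while
keeping lesions small relative to the field.

What the phantoms do *not* emulate: anatomy (ribs, mediastinum,
diaphragm), intensity statistics of radiographs, therapeutic equipment,
multi-disease label structure, or annotation noise. Passing the recovery
experiment therefore shows that the mechanism works — localization emerges
from weak labels when lesions are local, bright and position-biased — not
that clinical-grade performance would follow on real data.

## Desk-scale configuration and problem sizes

The library implements the canonical model in full (c′ = 2048, d = 1024;
the geometry tests run it forward), but training experiments use
`desk_config()`: width scale 0.5 with cardinality 16 (grouped widths stay
divisible), one bottleneck block per stage (the kernel layout — and hence
rf 39/stride 16 — is unchanged), attention at d = 128, 4 heads of width
32, MLP hidden 128, head hidden 256. The end-to-end recovery experiment
trains on 400 phantoms (280 train / 40 val / 80 test) for 14 epochs
(validation IoU plateaus near epoch 10); the ablation grid runs six
variants (four aggregators; the unrestricted backbone and the
position-attention architecture under the default aggregator) at 96
phantoms × 4 epochs each. These sizes were chosen so the whole suite runs
on a single CPU in minutes while leaving the optimization non-trivial.

The recovery experiment is attention-free by design. On a 4×4 grid there
are only 16 tokens, and two layers of global self-attention give every
patch a view of the whole image; "all patches vote the image label" then
becomes a zero-loss optimum of any patch-vote objective, and the
segmentation readout collapses (observed: patch grids uniformly at 1 on
abnormal phantoms, IoU ≈ 0.15, while classification stays perfect). The
full-scale method targets 32×32 grids, where memorizing that shortcut is
not available. At desk scale, weak-label localization is carried by the
restricted receptive field; the attention stage is still trained and
measured as an ablation variant.

## Numerical choices and degenerate inputs

- Probabilities are clamped to [1e−7, 1−1e−7] before any logarithm.
- LSE/adaptive-LSE max-shift makes overflow impossible for any r.
- Metrics with zero denominators return missing, never 0; AUC on a
  single-class evaluation set is reported as missing.
- Empty train or validation splits abort training; a mixed-supervision
  batch without any masked sample falls back to the weak loss and logs a
  warning.
- Image dimensions must be divisible by 16; the offending axis is named.
- The empirical receptive-field probe and all voting functions accept
  degenerate 1×1 grids.

## Known limitations

- The NumPy training loop is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not for 512×512 datasets.
- Adaptive-LSE image probabilities can fall below 0 (full-grid normalizer,
  above); downstream consumers should treat them as scores, not calibrated
  probabilities.
- The positional table fixes the grid size at configuration time;
  evaluating at a new resolution requires a new attention configuration.
- Mixed supervision assumes masks agree with labels; inconsistent pairs
  are rejected at load time rather than reconciled.
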