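# Methods

## Model

`drmargin` trains a classifier for diabetic-retinopathy severity jointly
with a contrastive representation objective. Each input image `x` is
augmented twice (`x̂ = Aug(x)`), both views pass through a shared encoder
`r = Enc(x̂) ∈ R^{D_E}`, `r` is L2-normalised onto the unit hypersphere, and
two heads consume it:

* a **projection head** `z = Proj(r) ∈ R^{D_P}` — a 2-layer perceptron
  (hidden width `proj_hidden`, ReLU, output `D_P`, L2-normalised) feeding
  the contrastive loss;
* a **classifier head** — a linear map to class logits feeding
  cross-entropy.

The total loss per step is `L = L_ce + λ·L_a-m`. Training is single-stage:
both heads and the encoder are optimised together, unlike the two-stage
SupCon protocol (contrastive pre-training, then a frozen-encoder linear
probe). The classifier reads `r`, never `z`, so the projection head can be
dropped at inference without changing predictions (tested). Cross-entropy
runs over both augmented views of every source (2N terms per batch).

### Loss family and conventions

The angular-margin loss converts inner products to angles
(`θ = arccos(z_i·z_a)`), adds `m_u` to the sibling-view positive and `m_v`
to same-label positives (negatives get no margin), and evaluates the
SupCon softmax form on `cos(θ + margin)/τ`. Numerical conventions:

* inner products are clamped to `[−1+ε, 1−ε]` with `ε = 1e-7` before
  `arccos` (the gradient of `arccos` diverges at ±1);
* `θ + m` is clamped at `π` before the cosine, keeping the penalised
  similarity monotone in `θ` — without the clamp, a margin pushing the
  angle past `π` would make the penalty non-monotone, which is also why
  the margin ablation caps `m_u` at 3×`m_v`;
* **reduction is the mean over the 2N anchors**, so the loss scale is
  independent of batch size. All oracles, spot values and tests use the
  same convention. (A sum convention would rescale but not reorder
  losses.)
* denominators use the shifted (log-sum-exp) form, so large `1/τ` values
  cannot overflow.

Since the numerator's exponential also appears in the denominator sum,
every per-anchor term is nonnegative and finite; the losses depend only on
inner products, hence are invariant to a common rotation of the embedding
and to consistent permutations of the batch (all property-tested).

The encoder-output normalisation is L2 (projection onto the unit sphere),
the convention required for inner products to be cosines and used by the
SupCon and alignment/uniformity literature this builds on. A per-component
rescaling to [0, 1] would not produce unit vectors and is not used.

### Representation diagnostics

* alignment: `E ‖f(x)−f(y)‖²` over positive pairs (here: the N sibling
  pairs of the current batch);
* uniformity: `log E exp(−2‖x−y‖²)` over i.i.d. embeddings (here: all 2N
  views). The i.i.d. expectation is read literally, so with M points the
  mean runs over all M² **ordered pairs including self-pairs**; the
  double-loop oracle in the tests matches this convention. Values are ≤ 0,
  equal to 0 only for a collapsed set.

## Data handling

Label tables use the APTOS CSV dialect (`id_code`, `diagnosis`, grades
0–4); detection maps grade 0 → 0 and 1–4 → 1. One seeded split per dataset
is reused for both tasks.

The 70/15/15 stratified splitter allocates, per class of size n:
`holdout = round-half-even(3n/10)`, `val = round-half-even(holdout/2)`,
`test = holdout − val`, `train = n − holdout`, computed in exact rational
arithmetic. This rule reproduces every per-class cell of the published
five-grade allocation for class sizes (1805, 370, 999, 193, 295). For the
second reference dataset two rows are off by one under any single
deterministic rounding rule (the original allocation was presumably a
shuffled draw), so those counts are only expected to ±1. Membership within
a class is a seeded shuffle: counts are a function of class size alone;
membership varies with the seed. Classes smaller than 2 go entirely to
train with a warning.

Augmentation operators (crop, horizontal/vertical flip, grayscale, color
jitter, rotation) are implemented on PIL images with all randomness drawn
from a single numpy generator, so a seed fixes the output bit-exactly.
Crop scale (0.8, 1.0) and flip probabilities 0.5 follow the reference
recipe; grayscale p=0.2, jitter strength 0.4 and rotation ±30° are this
package's defaults for the ablation harness (no reference values exist).
Double-view batches stack views as `[firsts; seconds]`, so the sibling map
is `j(i) = (i+N) mod 2N` — the simplest fixed-point-free involution. Only
two views per source are supported; the anchor partition rejects any other
pairing structure.

## Training loop

Defaults mirror the reference protocol: 20 epochs, batch 64, Adam with
lr 2e-4, 224×224 inputs, `τ=0.05`, `m_u=0.2`, `m_v=0.1`, `λ=1`. Batch
alignment/uniformity are logged every 10 steps for the first 1500 steps.
Model selection keeps the epoch with the highest validation accuracy
(earlier epoch on ties); validation selection by AUC or loss would be
equally defensible, accuracy was chosen as the simplest convention.
Encoder weights start from a seeded He initialisation; no pretraining is
assumed (a deliberately conservative default — externally supplied weights
can be loaded through the checkpoint mechanism).

The numerical stack is a small reverse-mode autodiff engine over float64
numpy arrays (`drmargin.autodiff`): broadcasted arithmetic, matmul, an
im2col convolution, average pooling, the elementwise functions the losses
need, and masked log-sum-exp. Gradients of every operation and of the full
loss compositions are verified against central finite differences. The
losses are differentiable in the embedding everywhere except the
measure-zero clamp boundaries, where the clamp gradient is defined as 0.
Pure single-threaded numpy makes runs bit-reproducible given a seed.

The built-in encoder is a 4-block CNN (3×3 conv, ReLU, 2×2 average pool;
widths 8/16/32/64; global average pooling; linear map to `D_E`). It is the
desk-scale default; ResNet-class backbones (`D_E = 2048`, projection
hidden 2048) are an encoder-contract option, not bundled. Input sizes must
be divisible by 16.

## Synthetic data

The image generator emulates exactly the class-conditional structure the
pipeline needs: a reddish circular disc on a dark background with a
grade-dependent number of lesion marks — bright exudate-like spots and
dark hemorrhage-like blobs — plus Gaussian pixel noise. Default lesion
count ranges per grade are (0,0), (1,3), (4,7), (8,11), (12,16):
synthetic values chosen once so the grades are visually distinct and
learnable by the small CNN. Mean lesion load is non-decreasing in grade
(tested over 100 draws per grade). What passing tests on this fixture
show: the losses, splitter, trainer and metrics compose correctly and the
margin mechanism behaves as designed. What they do not show: performance
on real fundus photographs, which have vessel trees, optic discs, camera
vignetting and label noise the generator deliberately omits. Images are
written to disk as PNGs so the file-path code paths are exercised.

The sphere-cluster generator perturbs K unit centroids in the tangent
space by `tan(spread)/√D`-scaled Gaussian noise and re-normalises, giving
double-viewed batches whose within-class angular scatter is controlled by
a single parameter.

## Experiment scales

Desk-scale study conditions used by the tests and the acceptance script:
the alignment comparison trains on 200 synthetic images (40 per grade,
64×64) with the small CNN for 300 steps at batch N=16 (32 views), for each
of 3 seeds and both objectives (SupCon: `m_u=m_v=0`; angular margin:
`m_u=0.2, m_v=0.1`; all other hyperparameters at their defaults). The
per-run summary is the mean batch alignment over the last 50 logged points
(at cadence 10, 300 steps produce 30 points, so all of them). Ablation
harness cells default to short runs with the epoch budget exposed in the
config, so full-scale reruns only need a config change.

## Known limitations

* CPU-only, float64, single-threaded: full-scale (224×224, ResNet, 20
  epochs) training is out of reach here; the package's claims at that
  scale are structural (the code paths exist and are exercised small).
* Multiclass precision/recall/F1 use macro averaging and AUC uses
  unweighted one-vs-rest — the reference reports do not state their
  averaging; macro is the convention most consistent with the reported
  metric spread under class imbalance, and per-class values are always
  included in the JSON report so other averages can be recomputed.
* Per-class precision/recall with a zero denominator report 0 with a
  warning (keeps macro averages defined on sparse toy sets).
* The binary AUC refuses single-class truth; the macro AUC skips absent
  classes with a warning instead, since multiclass evaluation on a subset
  of rows is a legitimate use.
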