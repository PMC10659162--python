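# Methods

## The inference problem

Spatial in-situ hybridization images record where a gene is expressed in the
embryo; genes that regulate each other tend to be expressed in overlapping
spatial domains.  The package infers missing links of a partially known gene
regulatory network (GRN) from a collection of such images, where each gene
owns a *set* of images (one per assayed embryo and view: lateral, dorsal,
ventral) — a multi-instance problem — and only a sparse set of TF→target
interactions is known.

The model is a two-stage pipeline:

**Stage 1 — contrastive image features.**  A siamese convolutional encoder
embeds single images.  Training pairs are same-orientation image pairs drawn
from labeled gene pairs (label 1 for a known interaction, 0 for a sampled
non-interaction), and the encoder minimizes the contrastive loss

    L = 1/2 d²            if y = 1,        d = ‖x_a − x_b‖₂
    L = 1/2 max(0, m−d)²  if y = 0,

with margin m = 1.  Because each gene pair yields the full Cartesian
product of its images per orientation (capped, seeded subsample beyond
`per_pair_cap`), the pair set is much larger than the link set.

**Stage 2 — multi-instance GraphSAGE link prediction.**  Per-gene image
embeddings are aggregated into one node feature x_i (mean pooling, max
pooling, or an LSTM over a randomly re-shuffled sequence, re-shuffled every
epoch so the expected output is order invariant).  A two-layer
GraphSAGE-mean network updates node states over the known graph,

    h_N(i) = mean{ h_j : j ∈ N(i) }          (zero vector if N(i) = ∅)
    h_i'   = σ( W · concat(h_i, h_N(i)) ),

and the decision head scores a pair as ŷ_ij = sigmoid(h_i_out · h_j_out),
symmetric in (i, j).  Training minimizes binary cross-entropy over the
train-partition links; only train-positive edges enter the message-passing
adjacency (an assertion guards against validation/test edges appearing
there).  The LSTM aggregator, when selected, trains jointly with the GNN.

## Split protocol

20% of known links (rounded half away from zero) form the test positives;
the remainder splits 9:1 into training and validation.  Negatives are
sampled uniformly without replacement from unordered non-adjacent pairs,
1:1 with positives per partition and disjoint across partitions.  Sampled
negatives may contain unknown true interactions; this mirrors how such
benchmarks are built in practice.

## Numerical and design choices

* **Autodiff core.**  All models run on a small reverse-mode automatic
  differentiation engine over numpy arrays (`miggri.nn`): dense ops,
  im2col-based convolution and transposed convolution, an LSTM cell, and
  Adam.  Every op's gradient is checked against central finite differences
  in the test suite.  Float64 throughout; deterministic given seeds and
  single-threaded BLAS.
* **Backbones.**  `small_cnn` (default): input block-mean downsampled 4×,
  three stride-2 3×3 conv blocks (8/16/32 channels), then a *flattened*
  linear head — spatial position must survive into the embedding because
  expression patterns differ mainly in where intensity sits; global pooling
  was found to discard exactly the discriminative information.
  `vgg16_modified`: a half-width VGG-style stack truncated after four
  blocks with a linear projection, for larger-scale runs.
* **Feature geometry.**  Aggregated node features are L2-row-normalized
  before stage 2 (`normalize_features`), putting the dot-product head on
  cosine geometry: a raw dot product cannot express the distance structure
  the contrastive loss induces (it lacks the −‖x_i‖²−‖x_j‖² terms), and
  unnormalized features saturate the sigmoid.
* **Signal-preserving initialization.**  GraphSAGE weights initialize as a
  ReLU-pair identity map on the node's own features (relu(x) − relu(−x)
  reassembled in layer two, small random weights elsewhere), so the
  untrained model already scores links by raw feature similarity and
  training *adds* topology terms instead of first scrambling the feature
  signal.  With random init and the reference learning rate the desk-scale
  model first diverges and then collapses to constant 0.5 predictions.
* **Learning rates.**  The package defaults are stage-1 Adam 2e-3 (training
  from scratch) and stage-2 Adam 5e-4 for 150 epochs with
  best-validation-AUC checkpointing.  The reference settings of the two
  real-data networks (stage-1 5e-6, 50/22 epochs, batch 16/32; stage-2
  5e-2, 78/3 epochs) ship as named presets `eye` and `mesoderm`.
* **Features are not trainable by default.**  Mean/max aggregators are
  parameter-free, so image-derived node features stay fixed during stage-2
  training; gradient tuning of feature rows is reserved for featureless
  genes (`tune_feature_genes`, used by the missing-data protocol), and the
  `random_init` topology-only baseline uses the same machinery with
  uninformative features.

## Synthetic benchmark

The generator emulates standardized embryo-image collections: 320×128
8-bit grayscale PNGs, darker = more expressed, an elliptical embryo mask
inscribed with a 6 px margin, and a TSV manifest
(`gene_id orientation stage file_path`, stage fixed at "13-16").  Spatial
patterns come from a pool of archetypes (1–3 isotropic Gaussian "staining"
blobs each, subtracted from the light canvas).  Each gene carries 1–3
archetypes (weights 0.6/0.3/0.1 — most genes one coherent domain).  The
planted signal is pattern sharing: each TF→target edge is flagged with
probability `pattern_share_prob` (default 0.8), and a flagged target's set
is rebuilt to include one archetype from *each* of its flagged regulators
(capped at 3), so overlap survives multiple regulators.  Dorsal images are
the vertical mirror of the lateral pattern; ventral adds an 8 px horizontal
shift; each image gets translation jitter (±3 px) and pixel noise
(sd 0.05), and 1–3 images exist per orientation.  TF out-degrees follow a
truncated power law (exponent 0.8 over 40 TFs among 200 genes) so hub
regulators exist.  Defaults: 200 genes, 600 edges (density 3%; the
generator reaches sub-1% density by configuration), 24 archetypes, seed
fixes every emitted byte.

What the generator does *not* emulate: real anatomical structures and
ontology terms, multi-embryo raw plates, stage dynamics, imaging artifacts,
and the far larger gene universe of a real collection.  Passing tests on
this bench shows the pipeline recovers a planted co-expression signal at
desk scale, not that it reproduces real-data accuracy.

A property of the planted design worth knowing: because the signal *is*
pattern sharing along edges, targets of the same regulator look alike.
Information that distinguishes a gene from its co-regulated siblings does
not exist in the graph alone; this bounds what link-based feature inference
can recover (see below).

## Missing-data protocol

A fraction (default 10%) of genes is declared featureless; their feature
rows are replaced (never mutated in place) by N(0, s²) vectors with s the
per-dimension sd of the observed aggregated features.  Tasks: (I) drop
featureless genes and their links entirely; (II) keep them with random
features — tuned by gradient during training — and test on
featured-featured links; (III) same model, test on links touching
featureless genes.  Tasks share per-repeat splits, so I-vs-II differences
use a paired t-test (textbook formula; the p-value uses the t distribution
from scipy).  Stage-1 embeddings are computed once and reused across
repeats; repeats resample splits for stage 2 only, so absolute values are
slightly optimistic while the paired comparisons remain internally valid.

## Feature inference for unseen genes

`infer_features` attaches new genes to a frozen model, initializes their
feature rows randomly on the observed scale, and runs projected gradient
descent (unit-norm projection each step; step size halved on a loss
increase, at most three times) on the cross-entropy of the training links
incident to the new genes.  Two deliberate choices: supervision links are
excluded from the message-passing adjacency (a label should not also be a
message path — otherwise the gradient inflates the new feature's norm
through its partner's neighborhood instead of aligning its direction), and
the step size (0.5 for 300 steps) is calibrated to unit-norm geometry,
where conventional small steps provably stall.  Inference is averaged over
several random restarts where downstream decoding needs a stable vector.

## Decoder

One decoder per orientation maps a node feature to a 320×128 image: linear
layer to an 8×20 (configurable) spatial seed, four transposed-convolution
blocks (kernel 2, stride 2 — exact non-overlapping doubling) each with an
additive nearest-neighbour-upsample + 1×1-conv residual branch, channels
halving from `base_channels`, sigmoid output (pixels guaranteed in [0,1]).
When the seed is smaller than 8×20 the remaining factor is a parameter-free
nearest upsampling, which trains ~4× faster at desk scale with no loss on
blob-scale patterns.  Loss is MSE against the per-gene mean image of the
orientation (the MSE-optimal single target).  Reference settings (10
epochs, batch 64, lr 2e-4) are the `DecoderConfig` defaults; the synthetic
benchmark uses a longer schedule because it trains from scratch on ~180
genes.

For recovering images of unseen genes, the benchmark workflow trains the
decoder on *leave-out inferred* features of the seen genes (each seen gene's
feature re-inferred from its links with its row hidden), so the decoder
learns exactly the input distribution it will receive for unseen genes;
decoding raw aggregated features of seen genes is supported but generalizes
poorly off its training manifold.

Reconstruction quality on synthetic data is scored by self-vs-other
matching: the decoded image of an unseen gene should correlate (pixel
Pearson) more with its own reference image than with random other genes'
references.  The package reports the comparison against the *average* of
the sampled other genes; the stricter "beats every single one of 20 others"
variant is also computed but is structurally capped on this benchmark
(≈35% even for an oracle that predicts the literal mean of the partners'
reference images), because co-regulated siblings are indistinguishable
given only link information.

## Link explainer

For a target link the explainer learns a weight in [0,1] per
message-passing edge inside the pair's 2-hop receptive field, maximizing
log ŷ under the soft mask with an L1 penalty (0.005) and an entropy penalty
(0.1) over 100 Adam steps at lr 0.05.  The entropy weight is kept small: on
smooth well-trained models the per-edge score gradient is weak, and a
strong entropy term freezes masks at whichever side of 0.5 they start on
instead of letting the score decide.  The masked neighborhood mean reduces exactly to
the ordinary mean at mask 1 (full-mask fidelity is exactly 1) and to the
empty-neighborhood convention at mask 0.  Outputs: per-edge weights, the
top-k subgraph with its fidelity (ŷ under the hard top-k mask ÷ ŷ under the
full graph), importance percentiles over the receptive-field edge set, and
GraphML/DOT exports with a low-weight pruning option.  Exhaustive
single-edge ablation is provided as an independent check and the test suite
verifies rank agreement on constructed toys.

## Problem sizes

The shipped benchmark runs 200 genes / 600 edges / ~1,800 images with the
`small_cnn` encoder (embedding 32, 8 epochs, pair cap 4), stage-2 at 150
epochs, 5 missing-data repeats, and a lateral-orientation decoder at the
2×5 spatial seed; one full pipeline run takes about a minute on a single
CPU core, and the complete acceptance evaluation a few minutes.  Larger
configurations (full-resolution decoder seed, `vgg16_modified`, 20 repeats)
are exposed through the same configs.

## Known limitations

* Absolute metric values on the synthetic bench are not comparable to any
  real-data numbers; only orderings and protocol behaviours are.
* The recurrent aggregator is unidirectional with hidden size = embedding
  size; ports sensitive to this choice should check
  `AggregatorSpec.hidden_dim`.
* The explainer's objective is a reconstruction of a link-level edge-mask
  explainer from its standard form, with constants recorded above, not a
  transcription of a reference implementation.
* Negative "links" are unverified non-edges; some may be real interactions.
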