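# Methods

This note documents the models and procedures implemented in `spongemil`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Problem setting

The Cytosponge-TFF3 test screens for Barrett's esophagus (BE) without
endoscopy: a swallowed capsule sponge collects esophageal cells which are
processed into paired histology slides — a routine H&E stain and a TFF3
immunohistochemistry stain in which goblet cells (the hallmark of
intestinal metaplasia) appear dark brown under the DAB chromogen.  Each
slide carries two adjacent tissue sections.  A pathologist reads both
slides per patient; at screening scale most of that effort is spent on
negatives.  `spongemil` implements a weakly supervised pipeline that
predicts the slide-level BE label directly from the slide image, using only
diagnostic labels (no localized annotations), and quantifies where the
model looks so its predictions can be audited against the TFF3 stain.

## Preprocessing

Optical density is `OD = -log10((I + eps)/255)` per channel with
`eps = 1/255`, so saturated white maps to approximately zero absorbance and
the transform is invertible.  Stain separation solves `OD ≈ c·M` for
per-pixel concentrations by pseudo-inverse, clipping negative
concentrations; `M` is either the standard Ruifrok–Johnston
hematoxylin/eosin/DAB matrix (scikit-image's vectors) or a slide-specific
two-stain matrix estimated by the Macenko percentile-angle method
(percentile `alpha = 1`, OD floor `beta = 0.15`, fallback to the default
H&E matrix below 100 non-white pixels).

TFF3 foreground masks threshold the hematoxylin concentration at its 80th
percentile over the slide (nuclei are hematoxylin-dense), then apply binary
closing and opening with a disk of fixed 60 um physical radius — 8 px at
the 1.25x working scale (7.36 um/px), 65 px at 10x.  Morphology runs at the
coarse 1.25x scale and is resampled back; this is equivalent to running the
same physical disk at full resolution at a fraction of the cost.  The
percentile is computed per slide, not per section.

H&E foreground masks use a fixed summed-OD threshold of 0.15 — a "not
white" test — followed by the same morphology.  Two alternatives are
exposed (`method="otsu"`, `method="percentile"`) but are not the default:
a percentile threshold breaks whenever tissue covers more than
`100 - percentile` percent of the slide, and Otsu's method can latch onto
the nuclei-versus-cytoplasm split instead of the tissue-versus-background
split on lightly stained slides.

Section boxes come from connected components of the mask after dilation
with the same 60 um disk (merging fragmented tissue), keeping the largest
`expected` components and returning tight boxes sorted left to right.
Background is whitened to exactly (255, 255, 255) and section crops are
exported as TIFF at 0.92 um/px (10x) with resolution tags, bilinear for
images and nearest for masks.

## Tiling and bag construction

Slides are tiled on the fly into non-overlapping 224 px tiles (about
200 um at 10x), from a random grid offset during training and zero offset
at inference; partial border tiles are dropped.  Tiles whose mean RGB
intensity exceeds 90% of 255 are background (the slide was whitened
upstream) and are excluded; the mean is taken over the whole tile and all
channels.  Training bags keep the `K` tiles of lowest mean intensity —
dense cellular regions are darker — with ties broken in raster order for
reproducibility.  Augmentation draws uniformly from the 8-element dihedral
group (90-degree rotations and flips), independently per tile.

## Model

The classifier is an attention-MIL transformer trained end to end from
slide labels: a convolutional encoder embeds each tile; four transformer
encoder layers (4 heads, feed-forward width 2x the embedding, dropout 0.1)
model dependencies between tiles in the bag; attention-MIL pooling
(`a_k = softmax(w^T tanh(V h_k))`, hidden width 2048, gated variant behind
a flag) forms the bag embedding as the attention-weighted sum of tile
embeddings; a linear layer produces the slide logit.  There is no
positional encoding, so the model is permutation-invariant in tile order —
an assertable property.  Whole-slide inference encodes all foreground
tiles in chunks and computes attention over the full tile set; chunked and
single-pass encoding agree to numerical tolerance by construction.

The transformer layers are pre-norm.  This matters at desk scale: in a
post-norm stack with uniform initial attention, every layer replaces each
tile embedding by approximately the bag mean, so across-tile variance
decays geometrically with depth and the untrained model is almost blind to
its input; the pre-norm residual path preserves per-tile identity.  For
the same reason the residual-branch output projections are initialized at
0.1x their He scale.

The numeric substrate is a small reverse-mode automatic-differentiation
engine over float64 numpy arrays, written for this package, with an AdamW
optimizer (decoupled weight decay).  All its operators are verified against
finite differences in the test suite.

### The `tiny_cnn` encoder

Configuration accepts the full-scale encoder names (ResNet-18/50,
Swin-tiny, DenseNet-121 with their reference bag sizes 2300/1200/1100/700),
but those require pretrained vision weights that are not bundled;
constructing them raises a clear error.  The bundled encoder, `tiny_cnn`,
is designed for CPU-scale experiments: input tiles are centered
(`x/255 - 0.5`) and average-pooled 8x to 28 px, then passed through three
3x3 conv-relu blocks (16/32/64 channels) with max-pooling, read out as a
spatial max per channel.  Three initialization choices substitute for what
pretraining provides a full-scale encoder:

- centering the input — with all-positive inputs, the ReLU/max-pool stack
  is positively homogeneous and LayerNorm is scale-invariant, making the
  untrained model insensitive to intensity;
- a first layer seeded with the classic luminance/opponent-color basis
  (R-G, R-B, G-B and luminance, each as a 3x3 mean and Laplacian, both
  signs) so color and contrast structure is discriminable from step one;
- near-identity (Dirac) initialization of the deeper convolutions so those
  shallow features survive to the readout at initialization.

All layers remain trainable.  The spatial-max readout keeps a small
goblet-cell blob (a few percent of a tile's area) from being diluted by
the surrounding tissue, and makes the last conv block ("conv3") the
natural Grad-CAM target.

### Training

Class-reweighted binary cross-entropy with weights `n / (2 n_class)`,
batches of 8 slides, AdamW.  Reference defaults follow the full-scale
protocol (lr 3e-5, weight decay 0.1, 50 epochs, encoder-specific `K`); the
desk-scale configuration used by the tests and the reproduction script is
lr 2e-3, 15 epochs, `K = 20` (which covers nearly all foreground tiles of a
synthetic slide).  Bags are resampled with a fresh random offset each
epoch.  Training is bit-deterministic given the seed.

## Interpretability

Attention heatmaps fill each tile footprint with its attention weight and
render under a reversed spectral colormap (red high, blue low) with the
mean marked on the colorbar; the numeric array is the tested surface.
Top-k tiles sort by attention with raster-order tie-breaks.  Normalized
attention entropy is `H = -sum a_k ln a_k / ln N` with `0 ln 0 := 0`,
defined as 0 for a single-tile bag; the normalization makes the logarithm
base irrelevant.  Grad-CAM weights each channel of the target conv
activation by the spatial mean of the slide-logit gradient, rectifies the
weighted sum, bilinearly upsamples to tile size and max-normalizes;
per-tile saliency is computed on a single-tile bag so the logit is driven
by that tile alone.

## Stain–attention correspondence

The TFF3 section is registered onto its adjacent H&E section by fitting,
on the hematoxylin-concentration images (Macenko matrix for H&E, default
HED matrix for TFF3), an affine transform at a coarse scale (7.36 um/px)
followed by a cubic B-spline with a 5x5 control grid (3.68 um/px), both
optimizing Mattes mutual information through SimpleITK.  Transforms are
parameterized in physical coordinates, so the fit applies unchanged at any
resolution; if the B-spline stage fails, the affine-only transform is
returned with a warning.  DAB quantification thresholds hematoxylin and
DAB concentrations independently with Otsu's method (DAB floor 0.15 OD
against stain-free slides), fills holes below 64 px² in the stain mask, and
defines foreground as hematoxylin-positive or DAB-positive — strongly
stained goblet cells can displace the counterstain, and this keeps the
per-tile stain ratio (stained pixels / foreground pixels, over the H&E
tiling grid) in [0, 1].  Correspondence is the Pearson correlation between
per-slide min-max-normalized stain ratios and attention weights
(normalization leaves r unchanged; it is kept for presentation), flagged
undefined when either vector is constant.

## Evaluation

AUROC and AUPR delegate to scikit-learn and equal the Mann-Whitney pair
statistic with ties counted one half (asserted against a brute-force
oracle).  Calls are boundary-inclusive (`score >= threshold`).  The
operating point is the largest threshold whose validation sensitivity
meets the target (0.85 for reporting, 0.95 for workflow analysis), falling
back to the minimum score.  Confidence intervals are 2.5/97.5 percentiles
over 1000 joint resamples of the test set; degenerate single-class
resamples are skipped and counted, not imputed.  Stratified splits draw
the test set per (label, pathway) stratum first, then deal the remainder
round-robin into four folds from a random per-stratum starting fold,
reproducing a 60:20:20 train/validation/test structure.  Model agreement
on failures is the Jaccard index of the two false-prediction sets, defined
as 1 when both are empty.

## Workflow simulation

Fourteen Boolean workflows combine the H&E model, TFF3 model and
pathologist.  Evaluation is short-circuit with the H&E model first: the
pathologist is invoked only when the expression still needs their call,
and TFF3 staining is required when the TFF3 model's call is needed or a
pathologist review occurs (the pathologist reads the TFF3 slide).  Under
these conventions "Pathologist reviews any positives" corresponds to
`(H&E or TFF3) and Pathologist` (100% TFF3 staining) and "Pathologist
reviews H&E model positives" to `H&E and Pathologist` (TFF3 fraction
equals review fraction).  Ground truth equals the pathologist's diagnosis,
so review workflows whose automatic negatives are model-negative have
specificity 1 by construction.  Samples are importance-reweighted to an
8% effective prevalence (`pi_t/pi_s` for positives, `(1-pi_t)/(1-pi_s)`
for negatives), which fixes the weighted prevalence exactly and leaves
within-class metrics unchanged; workload reduction is the reciprocal of
the weighted review fraction, reported to one decimal.

## Synthetic data

The generator emulates the properties the pipeline depends on, not
photorealistic histology: a white 1024x2048 px background at 0.92 um/px
with two elliptical tissue sections side by side; pink eosin-like texture
with small dark hematoxylin nuclei (radius 3 px, one per ~450 tissue
pixels); in positive slides, 4–9 goblet-cell groups of radius 18–36 px
drawn on H&E as a pale low-saturation blue-gray disk (translucent mucin)
with a darker basophilic rim (peripheral nuclei), and on the paired TFF3
image as a disk of pure DAB at concentration 1.2 OD on a pale
hematoxylin-counterstained tissue; an optional global displacement of up
to 6 px between the adjacent sections; additive Gaussian RGB noise
(sd 3).  Blob centers stay well inside the section so every goblet tile
passes background filtering.  Tile-level ground truth marks a zero-offset
grid tile positive iff it intersects a planted disk (closest-point
geometry, verified against per-pixel rasterization).  Cohorts fix the
positive count to `round(n * prevalence)`, assign the patient pathway
uniformly at random, and derive one child seed per slide so any single
pair can be regenerated bit-identically.

Synthetic decision tables draw model calls as Bernoulli with requested
class-conditional sensitivity/specificity, optionally correlated across
the two models through a shared Gaussian factor; the pathologist call
equals the label, mirroring the fact that diagnostic labels are the
pathologists' reading.

What passing tests on this generator do show: the full pipeline —
masking, tiling, end-to-end MIL optimization, attention localization,
registration and DAB quantification — is internally consistent and
recovers planted signal.  What they do not show: performance on real
capsule-sponge slides, whose stain variation, artifacts (pen marks,
bubbles, shadows), pseudogoblet cells and section-to-section tissue
differences are far richer than this model.

## Desk-scale reference experiment

80 synthetic slides at 50% prevalence, a stratified 75:25
development/test split (60 train, 20 test), `tiny_cnn` with `K = 20`,
lr 2e-3, 15 epochs.  This runs in a few minutes on one CPU and reaches
held-out AUROC ≥ 0.9 with attention concentrated on ground-truth goblet
tiles (enrichment about 2x their count share on average) and higher
attention entropy on negatives than positives.  Problem sizes were chosen
so the whole experiment remains an interactive desk run.

## Known limitations

- The H&E foreground substitute is not bit-compatible with the external QC
  tool it replaces; it reproduces only the mask's role (whitening and
  section boxes).
- Full-scale encoders are configuration-compatible but not runnable
  without pretrained weights.
- The B-spline registration stage is validated by recovery and
  non-degradation tests, not against a reference deformable registration.
- Bootstrap resampling is joint (unstratified); with small or very
  imbalanced test sets, single-class resamples are skipped, which can
  narrow intervals slightly.
- The synthetic appearance model has a single texture family per stain; it
  does not emulate scanner artifacts beyond noise.
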