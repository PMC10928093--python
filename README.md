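# spongemil

Weakly supervised screening of Barrett's esophagus (BE) from capsule-sponge
histology slides.

The Cytosponge-TFF3 test collects esophageal cells with a swallowed sponge
and produces two slides per patient: a routine H&E stain and a TFF3
immunostain in which goblet cells — the hallmark of the intestinal
metaplasia that defines BE — appear dark brown (DAB chromogen).  Reading
both slides for every patient limits how far the test can scale, because
pathologists spend most of their time on negatives.  `spongemil`
implements, end to end, a pipeline that learns to flag BE directly from
the slide image using only the slide-level diagnosis as supervision, and
that quantifies *where* the model looks so its behavior can be audited
against the TFF3 stain.  It is written for researchers studying weakly
supervised histopathology screening and for anyone who needs a fully
synthetic, CPU-scale testbed for attention-MIL pipelines.

## The model

A slide is a bag of 224 px tiles sharing one binary label y (multiple
instance learning).  Each tile k is encoded to an embedding h_k, four
transformer encoder layers (no positional encoding, so the bag is an
unordered set) model dependencies between tiles, and attention-MIL pooling

    a_k = softmax_k( w^T tanh(V h_k) ),      z = sum_k a_k h_k

forms the bag embedding z from which a linear layer predicts
p(y=1 | slide).  The whole stack trains end to end with class-reweighted
binary cross-entropy (weights n/(2 n_class), AdamW).  The attention
distribution a is the interpretability signal: stitched into a heatmap,
ranked for top-k tile review, summarized by its normalized entropy
-sum a_k ln a_k / ln N, and correlated per tile with the DAB-positive
fraction of the registered adjacent TFF3 section (affine + B-spline
mutual-information registration).

Around the classifier the package provides the full study workflow:
preprocessing (stain deconvolution with Macenko or standard HED vectors,
foreground masking with a 60 um morphological disk, section detection,
white-background standardization, 10x TIFF export at 0.92 um/px),
on-the-fly tiling with background exclusion and minimum-intensity bag
selection, diagnostic evaluation (AUROC/AUPR, operating points at a target
validation sensitivity, 1000-rep percentile bootstrap, stratified splits),
and a simulator for 14 Boolean ML-assisted screening workflows with
importance re-weighting to a realistic 8% screening prevalence.

Real clinical cohorts are not distributable, so the package ships a
synthetic generator producing paired H&E/TFF3 slides with planted
goblet-cell blobs and exact tile-level ground truth; every stage of the
pipeline is tested against it.  See `docs/methods.md` for the complete
methods description.

## Worked example

```python
from spongemil.pipeline import desk_scale_run, correspondence_for_slide

run = desk_scale_run()          # 80 synthetic slides, trains ~4 min on CPU
print(f"test AUROC          {run.test_auroc:.3f}")
print(f"attention enrichment {run.mean_enrichment:.2f}x")
print(f"entropy neg / pos   {sum(run.entropy_negative)/len(run.entropy_negative):.3f} / "
      f"{sum(run.entropy_positive)/len(run.entropy_positive):.3f}")
res = correspondence_for_slide(run, run.positive_test_indices()[0])
print(f"stain-attention r   {res.pearson_r:.3f}")
```

prints

```
test AUROC          1.000
attention enrichment 2.35x
entropy neg / pos   0.808 / 0.579
stain-attention r   0.673
```

Held-out AUROC of 1.0 means the trained model separates every positive
from every negative synthetic slide.  Enrichment of 2.35x says the
attention mass on ground-truth goblet-cell tiles is more than double those
tiles' share of the bag — the model is looking at the right tissue, which
the positive Pearson correlation with the registered TFF3/DAB stain ratio
confirms independently.  The entropy gap (negatives 0.81 vs positives
0.58) mirrors the qualitative finding that attention is diffuse on
negative slides and concentrated on positives.

The same steps are scriptable from a shell:

```bash
spongemil synth --n 40 --prevalence 0.5 --seed 0 --out data/
spongemil train --labels data/labels.csv --checkpoint model.npz
spongemil infer --checkpoint model.npz --labels data/labels.csv --out preds.csv
spongemil evaluate --predictions preds.csv --labels data/labels.csv
spongemil workflows --decisions decisions.csv --prevalence 0.08
```

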